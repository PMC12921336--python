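"""Region classification against hand-traced transcript models, and
strand-aware 5-mer context extraction with the NGGG signature."""

import numpy as np
import pytest

from morgan5c import (
    GenomeSequence,
    MorganError,
    SiteRecord,
    Transcript,
    TranscriptAnnotation,
    classify_site,
    context_frequencies,
    extract_context,
    region_distribution,
)
from morgan5c.annotation import classify_sites
from morgan5c.types import reverse_complement
import pandas as pd


def _site(chrom, pos, strand, gene=""):
    return SiteRecord(chrom, pos, strand, 20, 10, 0.5, gene)


@pytest.fixture()
def toy_annotation():
    """Plus-strand transcript: exons [1,100],[201,300], CDS [51,100]+[201,250]."""
    tx = Transcript("t1", "G1", "chr1", "+",
                    exons=((1, 100), (201, 300)), cds=((51, 100), (201, 250)))
    return TranscriptAnnotation({"t1": tx})


class TestClassify:
    @pytest.mark.parametrize(
        "pos,expected",
        [
            (25, "five_prime_utr"),   # exonic, upstream of CDS start
            (60, "cds"),
            (150, "intron"),          # between the exons
            (230, "cds"),
            (280, "three_prime_utr"), # exonic, downstream of CDS end
        ],
    )
    def test_hand_traced_plus_strand_regions(self, toy_annotation, pos, expected):
        call = classify_site(_site("chr1", pos, "+"), toy_annotation)
        assert call.region == expected

    def test_minus_strand_utr_orientation(self):
        tx = Transcript("t1", "G1", "chr1", "-",
                        exons=((1, 100), (201, 300)), cds=((51, 100), (201, 250)))
        ann = TranscriptAnnotation({"t1": tx})
        # transcript reads 300 -> 1: genomic left of CDS is the 3'UTR
        assert classify_site(_site("chr1", 25, "-"), ann).region == "three_prime_utr"
        assert classify_site(_site("chr1", 280, "-"), ann).region == "five_prime_utr"

    def test_priority_prefers_cds_over_intron(self):
        tx_a = Transcript("ta", "G1", "chr1", "+",
                          exons=((1, 50), (151, 200)), cds=((10, 50), (151, 180)))
        tx_b = Transcript("tb", "G2", "chr1", "+", exons=((140, 220),),
                          cds=((160, 200),))
        ann = TranscriptAnnotation({"ta": tx_a, "tb": tx_b})
        # pos 100: intronic in ta, outside tb; pos 155: CDS in ta, 5'UTR in tb
        assert classify_site(_site("chr1", 100, "+"), ann).region == "intron"
        call = classify_site(_site("chr1", 155, "+"), ann)
        assert call.region == "cds"
        assert call.transcript_id == "ta"

    def test_opposite_strand_and_no_overlap_are_unassigned(self, toy_annotation):
        assert classify_site(_site("chr1", 60, "-"), toy_annotation).region == "unassigned"
        assert classify_site(_site("chr1", 999, "+"), toy_annotation).region == "unassigned"
        assert classify_site(_site("chr9", 60, "+"), toy_annotation).region == "unassigned"


class TestDistribution:
    def test_percentages(self):
        calls = pd.DataFrame(
            {"region": ["cds", "cds", "intron", "three_prime_utr"]}
        )
        out = region_distribution(calls).set_index("region")
        assert out.loc["cds", "percent"] == pytest.approx(50.0)
        assert out.loc["intron", "percent"] == pytest.approx(25.0)
        assert out.loc["three_prime_utr", "percent"] == pytest.approx(25.0)
        assert out.loc["five_prime_utr", "count"] == 0
        assigned = out.drop(index="unassigned")
        assert assigned["percent"].sum() == pytest.approx(100.0, abs=0.01)

    def test_all_unassigned_reported_separately(self):
        calls = pd.DataFrame({"region": ["unassigned", "unassigned"]})
        out = region_distribution(calls)
        assert out.set_index("region").loc["unassigned", "count"] == 2


class TestContext:
    def test_plus_strand_context(self):
        g = GenomeSequence({"c": "AACGGGAT"})
        rec = extract_context(_site("c", 3, "+"), g)
        assert rec.context == "CGGGA"
        assert rec.matches_ngg

    def test_minus_strand_reverse_complement(self):
        g = GenomeSequence({"c": "ATCCCGTT"})
        rec = extract_context(_site("c", 6, "-"), g)
        assert rec.context == reverse_complement("TCCCG") == "CGGGA"

    def test_contig_edge_padded_with_n(self):
        g = GenomeSequence({"c": "ACGT"})
        rec = extract_context(_site("c", 2, "+"), g)
        assert len(rec.context) == 5
        assert rec.context == "CGTNN"

    def test_missing_chromosome_is_hard_error(self):
        g = GenomeSequence({"c": "ACGT"})
        with pytest.raises(MorganError):
            extract_context(_site("zz", 2, "+"), g)

    def test_ngg_signature_examples(self):
        g = GenomeSequence({"c": "CAGGGCGGGGCCAGGCAGAGCGGGA"})
        expected = {
            1: ("CAGGG", True), 6: ("CGGGG", True), 11: ("CCAGG", False),
            16: ("CAGAG", False), 21: ("CGGGA", True),
        }
        for pos, (ctx, flag) in expected.items():
            rec = extract_context(_site("c", pos, "+"), g)
            assert (rec.context, rec.matches_ngg) == (ctx, flag)

    def test_strand_symmetry_on_mirrored_genome(self):
        rng = np.random.default_rng(41)
        seq = "".join(rng.choice(list("ACGT"), 60))
        g_fwd = GenomeSequence({"c": seq})
        g_rev = GenomeSequence({"c": reverse_complement(seq)})
        for pos in (10, 25, 40):
            fwd = extract_context(_site("c", pos, "+"), g_fwd)
            mirrored = extract_context(_site("c", len(seq) - pos + 1, "-"), g_rev)
            assert fwd.context == mirrored.context


class TestFrequencies:
    def _contexts(self, items):
        return pd.DataFrame(
            [{"chrom": "c", "pos": i, "strand": "+", "context": ctx,
              "matches_ngg": ctx[0] == "C" and "GGG" in ctx[1:]}
             for i, ctx in enumerate(items)]
        )

    def test_uniform_contexts(self):
        table, pfm, ngg = context_frequencies(self._contexts(["CGGGG"] * 10))
        assert len(table) == 1
        assert table["percent"].iloc[0] == pytest.approx(100.0)
        assert ngg == pytest.approx(1.0)

    def test_hand_counted_mixture(self):
        table, pfm, ngg = context_frequencies(
            self._contexts(["CGGGA", "CGGGA", "CGGGA", "CAGAG"])
        )
        t = table.set_index("context")
        assert t.loc["CGGGA", "percent"] == pytest.approx(75.0)
        assert t.loc["CAGAG", "percent"] == pytest.approx(25.0)
        assert ngg == pytest.approx(0.75)

    def test_pfm_columns_conserve_site_count(self):
        rng = np.random.default_rng(42)
        items = ["".join(rng.choice(list("ACGTN"), 5)) for _ in range(30)]
        contexts = self._contexts(items)
        _, pfm, _ = context_frequencies(contexts)
        for position in range(1, 6):
            non_n = sum(1 for ctx in items if ctx[position - 1] != "N")
            assert pfm.loc[position].sum() == non_n

    def test_counts_sum_to_number_of_sites(self):
        rng = np.random.default_rng(43)
        items = ["".join(rng.choice(list("ACGT"), 5)) for _ in range(50)]
        table, _, _ = context_frequencies(self._contexts(items), top_k=len(items))
        assert table["count"].sum() == 50


class TestFixtureRecovery:
    def test_planted_regions_and_contexts_recovered(self, site_fixture):
        genome, annotation, tables, truth, meta = site_fixture
        table = tables[0]
        calls = classify_sites(table, annotation).set_index(["chrom", "pos", "strand"])
        for row in truth.itertuples(index=False):
            assert calls.loc[(row.chrom, row.pos, row.strand), "region"] == row.region
        from morgan5c import extract_contexts

        contexts = extract_contexts(table, genome).set_index(["chrom", "pos", "strand"])
        for row in truth.itertuples(index=False):
            assert contexts.loc[(row.chrom, row.pos, row.strand), "context"] == row.context
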