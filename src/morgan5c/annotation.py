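"""Transcript-region assignment and strand-aware sequence-context extraction
for m5C sites.

A site is placed into exactly one of {5'UTR, CDS, 3'UTR, intron, unassigned}
against same-strand transcript models, aggregating across transcripts by a
configurable priority (default CDS > 3'UTR > 5'UTR > intron). The sequence
context is the methylated cytosine plus the 4 downstream bases on the site's
strand — the window in which the G-rich NGGG signature of NSUN2 substrates
lives.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import (
    GenomeSequence,
    MorganError,
    SiteRecord,
    TranscriptAnnotation,
    Transcript,
    reverse_complement,
)

REGIONS = ("five_prime_utr", "cds", "three_prime_utr", "intron")
DEFAULT_PRIORITY = ("cds", "three_prime_utr", "five_prime_utr", "intron")


@dataclass(frozen=True)
class RegionCall:
    chrom: str
    pos: int
    strand: str
    region: str  # one of REGIONS or "unassigned"
    transcript_id: str | None


@dataclass(frozen=True)
class ContextRecord:
    chrom: str
    pos: int
    strand: str
    context: str       # 5-mer, first character the methylated base
    matches_ngg: bool  # C followed by a GGG triplet within 4 downstream bases


def _region_in_transcript(pos: int, tx: Transcript) -> str | None:
    """Region of ``pos`` within one transcript, or None when the transcript
    cannot classify it (no CDS and the position is exonic)."""
    exonic = any(s <= pos <= e for s, e in tx.exons)
    if not exonic:
        return "intron"
    if not tx.cds:
        return None  # noncoding transcript: exonic hit carries no UTR/CDS label
    cds_start, cds_end = tx.cds[0][0], tx.cds[-1][1]
    if any(s <= pos <= e for s, e in tx.cds):
        return "cds"
    # exonic but outside the CDS span boundaries -> UTR in transcript orientation
    if pos < cds_start:
        return "five_prime_utr" if tx.strand == "+" else "three_prime_utr"
    if pos > cds_end:
        return "three_prime_utr" if tx.strand == "+" else "five_prime_utr"
    # inside the CDS genomic span but not in a CDS interval: exonic UTR-free
    # gap can only arise from CDS-interrupting exonic sequence; call it cds
    return "cds"


def classify_site(
    site: SiteRecord,
    annotation: TranscriptAnnotation,
    priority=DEFAULT_PRIORITY,
) -> RegionCall:
    """Assign one region to a site by scanning same-strand overlapping
    transcripts and keeping the highest-priority verdict."""
    if set(priority) != set(REGIONS):
        raise MorganError(f"priority must permute {REGIONS}")
    best_region = None
    best_tx = None
    order = {region: i for i, region in enumerate(priority)}
    for tx in annotation.overlapping(site.chrom, site.pos):
        if tx.strand != site.strand:
            continue
        region = _region_in_transcript(site.pos, tx)
        if region is None:
            continue
        if best_region is None or order[region] < order[best_region]:
            best_region, best_tx = region, tx.transcript_id
    if best_region is None:
        return RegionCall(site.chrom, site.pos, site.strand, "unassigned", None)
    return RegionCall(site.chrom, site.pos, site.strand, best_region, best_tx)


def classify_sites(site_table, annotation, priority=DEFAULT_PRIORITY) -> pd.DataFrame:
    calls = [
        classify_site(rec, annotation, priority) for rec in site_table.iter_records()
    ]
    return pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "pos": c.pos,
                "strand": c.strand,
                "region": c.region,
                "transcript_id": c.transcript_id or "",
            }
            for c in calls
        ]
    )


def region_distribution(calls: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages per region over assigned sites; the unassigned
    count is reported as a separate row with no percentage."""
    if calls.empty:
        raise MorganError("no region calls")
    assigned = calls[calls["region"] != "unassigned"]
    counts = assigned["region"].value_counts()
    total = int(counts.sum())
    rows = []
    for region in REGIONS:
        c = int(counts.get(region, 0))
        if total:
            rows.append((region, c, 100.0 * c / total))
        elif c == 0:
            continue
    df = pd.DataFrame(rows, columns=["region", "count", "percent"])
    n_unassigned = int((calls["region"] == "unassigned").sum())
    df = pd.concat(
        [df, pd.DataFrame([("unassigned", n_unassigned, np.nan)], columns=df.columns)],
        ignore_index=True,
    )
    return df


def extract_context(
    site: SiteRecord, genome: GenomeSequence, down: int = 4
) -> ContextRecord:
    """5-mer (C + ``down`` downstream bases) on the site's strand.

    Plus strand reads genome[pos .. pos+down]; minus strand reads the reverse
    complement of genome[pos-down .. pos]. Out-of-contig positions pad with N.
    """
    if site.strand == "+":
        seq = genome.fetch(site.chrom, site.pos, site.pos + down)
    else:
        seq = reverse_complement(genome.fetch(site.chrom, site.pos - down, site.pos))
    return ContextRecord(site.chrom, site.pos, site.strand, seq, _matches_ngg(seq))


def _matches_ngg(context: str) -> bool:
    """G-rich downstream signature: methylated C with a GGG triplet within
    the 4 downstream bases (covers CNGGG and CGGGN variants)."""
    return context[0] == "C" and "GGG" in context[1:5]


def extract_contexts(site_table, genome: GenomeSequence, down: int = 4) -> pd.DataFrame:
    recs = [extract_context(r, genome, down) for r in site_table.iter_records()]
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "pos": r.pos,
                "strand": r.strand,
                "context": r.context,
                "matches_ngg": r.matches_ngg,
            }
            for r in recs
        ]
    )


def context_frequencies(
    contexts: pd.DataFrame, top_k: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Ranked 5-mer table, position frequency matrix, and NGGG fraction.

    Returns (top-``top_k`` context table with count and percent-of-all-sites,
    5-row PFM with A/C/G/T counts per position excluding N, fraction of all
    sites whose context carries the downstream GGG signature).
    """
    if contexts.empty:
        raise MorganError("no context records")
    total = len(contexts)
    counts = Counter(contexts["context"])
    table = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["context", "count"],
    )
    table["percent"] = 100.0 * table["count"] / total
    k = len(contexts["context"].iloc[0])
    pfm = pd.DataFrame(
        0, index=pd.RangeIndex(1, k + 1, name="position"), columns=list("ACGT")
    )
    for ctx, c in counts.items():
        for i, base in enumerate(ctx):
            if base in "ACGT":
                pfm.loc[i + 1, base] += c
    ngg_fraction = float(contexts["matches_ngg"].mean())
    return table.head(top_k), pfm, ngg_fraction
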