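"""Core in-memory containers shared by every pipeline stage.

Tabular data is held in pandas objects; the thin dataclass wrappers exist to
carry the invariants (value ranges, label uniqueness, coordinate convention)
that plain DataFrames cannot express. Genomic coordinates are 1-based
inclusive throughout, matching GTF and bisulfite-caller output conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

GROUPS = ("cancer", "normal")

SITE_COLUMNS = ["chrom", "pos", "strand", "coverage", "methylated", "meth_rate", "gene"]


class MorganError(ValueError):
    """Base class for input-contract violations reported at parse/compute time."""


@dataclass(frozen=True)
class SampleSheet:
    """Sample → group assignment for a two-group (cancer/normal) cohort."""

    groups: dict[str, str]  # sample_id -> "cancer" | "normal"

    def __post_init__(self) -> None:
        for sid, grp in self.groups.items():
            if grp not in GROUPS:
                raise MorganError(
                    f"sample {sid!r}: group {grp!r} not in {GROUPS}"
                )

    @property
    def samples(self) -> list[str]:
        return list(self.groups)

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == group]

    def subset(self, samples) -> "SampleSheet":
        missing = [s for s in samples if s not in self.groups]
        if missing:
            raise MorganError(f"samples absent from metadata: {missing}")
        return SampleSheet({s: self.groups[s] for s in samples})

    def require_both_groups(self) -> None:
        for grp in GROUPS:
            if not self.samples_in(grp):
                raise MorganError(f"no samples with group {grp!r}")

    def labels(self, samples) -> np.ndarray:
        return np.array([self.groups[s] for s in samples])


class SiteRecord(NamedTuple):
    """One called m5C site in one sample."""

    chrom: str
    pos: int           # 1-based coordinate of the methylated cytosine
    strand: str        # "+" or "-"
    coverage: int
    methylated: int
    meth_rate: float   # methylated / coverage; NaN when coverage == 0
    gene: str          # "" when the site is intergenic / unassigned


@dataclass
class SiteTable:
    """All called sites of a single sample, (chrom, pos, strand)-unique."""

    sample_id: str
    df: pd.DataFrame  # columns SITE_COLUMNS, sorted by (chrom, pos)

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in SITE_COLUMNS if c not in df.columns]
        if missing:
            raise MorganError(f"site table missing columns {missing}")
        dup = df.duplicated(subset=["chrom", "pos", "strand"])
        if dup.any():
            row = df[dup].iloc[0]
            raise MorganError(
                f"sample {self.sample_id}: duplicate site "
                f"({row.chrom}, {row.pos}, {row.strand})"
            )
        bad_strand = ~df["strand"].isin(["+", "-"])
        if bad_strand.any():
            raise MorganError(
                f"sample {self.sample_id}: strand must be '+' or '-', "
                f"got {df.loc[bad_strand, 'strand'].iloc[0]!r}"
            )
        if (df["methylated"] > df["coverage"]).any():
            row = df[df["methylated"] > df["coverage"]].iloc[0]
            raise MorganError(
                f"sample {self.sample_id}: methylated > coverage at "
                f"({row.chrom}, {row.pos})"
            )
        if (df["pos"] < 1).any():
            raise MorganError(f"sample {self.sample_id}: positions must be >= 1")
        self.df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def iter_records(self) -> Iterator[SiteRecord]:
        for row in self.df.itertuples(index=False):
            yield SiteRecord(
                row.chrom, int(row.pos), row.strand, int(row.coverage),
                int(row.methylated), float(row.meth_rate), row.gene,
            )


@dataclass
class ExpressionMatrix:
    """Gene × sample expression values, either raw counts or CPM."""

    values: pd.DataFrame  # index genes, columns samples
    scale: str = "raw_counts"  # or "cpm"

    def __post_init__(self) -> None:
        if self.scale not in ("raw_counts", "cpm"):
            raise MorganError(f"unknown expression scale {self.scale!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise MorganError(f"duplicate gene names: {dups}")
        if self.values.columns.has_duplicates:
            raise MorganError("duplicate sample ids in expression matrix")
        arr = self.values.to_numpy()
        if np.isnan(arr).any():
            raise MorganError("expression matrix contains missing values")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise MorganError(
                f"negative expression value at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )

    @property
    def genes(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.values.columns.tolist()


@dataclass
class GeneMethylationMatrix:
    """Gene × sample methylation level in [0, 1]; NaN marks gene–sample pairs
    with no covered sites."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        finite = arr[~np.isnan(arr)]
        if finite.size and ((finite < 0).any() or (finite > 1).any()):
            raise MorganError("methylation levels must lie in [0, 1]")

    @property
    def genes(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.values.columns.tolist()


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    gene: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # 1-based inclusive, sorted, non-overlapping
    cds: tuple[tuple[int, int], ...]    # subset of the exon union; may be empty

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)


@dataclass
class TranscriptAnnotation:
    """Transcript models keyed by id, with a per-chromosome index."""

    transcripts: dict[str, Transcript]
    _by_chrom: dict[str, list[Transcript]] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        for tx in self.transcripts.values():
            ex = sorted(tx.exons)
            for (s1, e1), (s2, e2) in zip(ex, ex[1:]):
                if s2 <= e1:
                    raise MorganError(
                        f"transcript {tx.transcript_id}: overlapping exons"
                    )
            for cs, ce in tx.cds:
                if not any(s <= cs and ce <= e for s, e in ex):
                    raise MorganError(
                        f"transcript {tx.transcript_id}: CDS interval "
                        f"[{cs},{ce}] not contained in a single exon"
                    )
        by_chrom: dict[str, list[Transcript]] = {}
        for tx in self.transcripts.values():
            by_chrom.setdefault(tx.chrom, []).append(tx)
        object.__setattr__(self, "_by_chrom", by_chrom)

    def overlapping(self, chrom: str, pos: int) -> list[Transcript]:
        out = []
        for tx in self._by_chrom.get(chrom, []):
            s, e = tx.span
            if s <= pos <= e:
                out.append(tx)
        return out

    @property
    def gene_names(self) -> set[str]:
        return {tx.gene for tx in self.transcripts.values()}

    def exonic_kb_by_gene(self) -> dict[str, float]:
        """Exonic kilobases per gene: union of exon intervals over the gene's
        transcripts, merged per chromosome/strand."""
        per_gene: dict[str, list[tuple[str, int, int]]] = {}
        for tx in self.transcripts.values():
            per_gene.setdefault(tx.gene, []).extend(
                (tx.chrom, s, e) for s, e in tx.exons
            )
        out = {}
        for gene, ivs in per_gene.items():
            total = 0
            by_chrom: dict[str, list[tuple[int, int]]] = {}
            for chrom, s, e in ivs:
                by_chrom.setdefault(chrom, []).append((s, e))
            for chrom_ivs in by_chrom.values():
                chrom_ivs.sort()
                cur_s, cur_e = chrom_ivs[0]
                for s, e in chrom_ivs[1:]:
                    if s <= cur_e + 1:
                        cur_e = max(cur_e, e)
                    else:
                        total += cur_e - cur_s + 1
                        cur_s, cur_e = s, e
                total += cur_e - cur_s + 1
            out[gene] = total / 1000.0
        return out


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeSequence:
    """Named sequences over {A,C,G,T,N} with 1-based inclusive lookup."""

    sequences: dict[str, str]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return bases [start, end] (1-based inclusive), padding out-of-bounds
        positions with N."""
        if chrom not in self.sequences:
            raise MorganError(f"chromosome {chrom!r} absent from genome")
        seq = self.sequences[chrom]
        left_pad = max(0, 1 - start)
        right_pad = max(0, end - len(seq))
        core = seq[max(start, 1) - 1 : min(end, len(seq))]
        return "N" * left_pad + core.upper() + "N" * right_pad
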