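"""Readers and writers for the tabular and sequence formats the pipeline
consumes: sample metadata, per-sample m5C site tables (bisulfite-caller
dialect), gene × sample count matrices, Ensembl-style GTF and FASTA.

All TSVs are tab-separated UTF-8 with '#'-prefixed comment lines ignored;
every path may be plain or gzip-compressed ('.gz').
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .types import (
    GROUPS,
    SITE_COLUMNS,
    ExpressionMatrix,
    GenomeSequence,
    MorganError,
    SampleSheet,
    SiteTable,
    Transcript,
    TranscriptAnnotation,
)

# Aliases absorbing meRanCall-style column headers (case-insensitive).
DEFAULT_SITE_COLUMNS = {
    "chrom": ("chrom", "#seqid", "seqid", "chr"),
    "pos": ("pos", "refpos", "position"),
    "strand": ("strand", "refstrand"),
    "coverage": ("coverage", "cov"),
    "methylated": ("methylated", "c_count", "methylated_reads"),
    "meth_rate": ("meth_rate", "methrate"),
    "gene": ("gene", "genename", "gene_name"),
}


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    with _open_text(path) as fh:
        return pd.read_csv(fh, sep="\t", comment="#", **kwargs)


def read_sample_sheet(path) -> SampleSheet:
    """Parse a metadata TSV with columns ``sample_id`` and ``group``.

    Group labels are matched case-insensitively against cancer/normal;
    anything else is a hard error naming the offending row.
    """
    df = _read_tsv(path, dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise MorganError(f"{path}: missing required column {col!r}")
    dup = df["sample_id"].duplicated()
    if dup.any():
        raise MorganError(
            f"{path}: duplicate sample_id {df.loc[dup, 'sample_id'].iloc[0]!r}"
        )
    groups: dict[str, str] = {}
    for i, row in df.iterrows():
        grp = str(row["group"]).strip().lower()
        if grp not in GROUPS:
            raise MorganError(
                f"{path} row {i + 1} (sample {row['sample_id']!r}): group "
                f"{row['group']!r} not recognised; allowed labels: {list(GROUPS)}"
            )
        groups[str(row["sample_id"])] = grp
    return SampleSheet(groups)


def read_site_table(path, sample_id: str, columns: dict | None = None) -> SiteTable:
    """Parse one sample's called-site TSV into a :class:`SiteTable`.

    ``columns`` maps canonical names (chrom, pos, strand, coverage,
    methylated, meth_rate, gene) to the file's header names; by default a
    set of common caller aliases is matched case-insensitively. meth_rate is
    recomputed as methylated/coverage whenever both counts are present;
    coverage-0 records are kept with meth_rate flagged missing (NaN).
    """
    # meRanCall-style files start their header line with '#' (e.g. #SeqID);
    # treat a tab-containing first '#' line as the header, not a comment
    with _open_text(path) as fh:
        lines = fh.readlines()
    if lines and lines[0].startswith("#") and "\t" in lines[0]:
        lines[0] = lines[0].lstrip("#")
    body = [ln for ln in lines if not ln.startswith("#")]
    df = pd.read_csv(_io.StringIO("".join(body)), sep="\t")
    lower = {c.lower(): c for c in df.columns}
    resolved: dict[str, str] = {}
    alias_map = dict(DEFAULT_SITE_COLUMNS)
    if columns:
        for canon, name in columns.items():
            alias_map[canon] = (name,)
    for canon, aliases in alias_map.items():
        for alias in aliases:
            if alias.lower() in lower:
                resolved[canon] = lower[alias.lower()]
                break
    for required in ("chrom", "pos", "strand", "coverage"):
        if required not in resolved:
            raise MorganError(f"{path}: no column found for {required!r}")
    if "methylated" not in resolved and "meth_rate" not in resolved:
        raise MorganError(f"{path}: need a methylated-count or meth_rate column")

    out = pd.DataFrame(
        {
            "chrom": df[resolved["chrom"]].astype(str),
            "pos": df[resolved["pos"]].astype(int),
            "strand": df[resolved["strand"]].astype(str),
            "coverage": df[resolved["coverage"]].astype(int),
        }
    )
    if "methylated" in resolved:
        out["methylated"] = df[resolved["methylated"]].astype(int)
        with np.errstate(divide="ignore", invalid="ignore"):
            out["meth_rate"] = np.where(
                out["coverage"] > 0, out["methylated"] / out["coverage"], np.nan
            )
    else:
        rate = df[resolved["meth_rate"]].astype(float)
        out["methylated"] = np.rint(rate.fillna(0) * out["coverage"]).astype(int)
        out["meth_rate"] = np.where(out["coverage"] > 0, rate, np.nan)
    out["gene"] = (
        df[resolved["gene"]].fillna("").astype(str) if "gene" in resolved else ""
    )
    return SiteTable(sample_id, out[SITE_COLUMNS])


def read_expression_matrix(path) -> ExpressionMatrix:
    """Parse a gene × sample raw-count TSV (first column = gene names)."""
    df = _read_tsv(path, index_col=0)
    if df.empty:
        raise MorganError(f"{path}: no data rows")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                gene = df.index[bad.to_numpy().nonzero()[0][0]]
                raise MorganError(
                    f"{path}: non-numeric value at gene {gene!r}, sample {col!r}"
                )
            df[col] = coerced
    df.index = df.index.astype(str)
    df.index.name = "gene"
    return ExpressionMatrix(df.astype(float), scale="raw_counts")


FLOAT_FORMAT = "%.7g"  # 7 significant digits: round-trips within 1e-6 relative


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write any tabular result as a TSV with a deterministic column order
    (as given) and floats at 7 significant digits."""
    path = Path(path)
    try:
        with _open_text(path, "wt") as fh:
            df.to_csv(fh, sep="\t", index=index, float_format=FLOAT_FORMAT)
    except OSError as exc:
        raise MorganError(f"cannot write {path}: {exc}") from exc


def read_table(path, **kwargs) -> pd.DataFrame:
    return _read_tsv(path, **kwargs)


def read_fasta(path) -> GenomeSequence:
    with _open_text(path) as fh:
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    if not seqs:
        raise MorganError(f"{path}: no FASTA records")
    return GenomeSequence(seqs)


def write_fasta(genome: GenomeSequence, path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gtf(path) -> TranscriptAnnotation:
    """Load transcript models (exons + CDS) from an Ensembl-dialect GTF.

    Parsing is delegated to gffutils (in-memory database). Only ``exon`` and
    ``CDS`` features are used; transcripts are keyed by ``transcript_id`` and
    genes by ``gene_name`` (``gene_id`` fallback).
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tids = feat.attributes.get("transcript_id", [])
        if not tids:
            raise MorganError(f"{path}: {feat.featuretype} without transcript_id")
        tid = tids[0]
        gene = (
            feat.attributes.get("gene_name")
            or feat.attributes.get("gene_id")
            or [""]
        )[0]
        meta.setdefault(tid, (gene, feat.seqid, feat.strand))
        target = exons if feat.featuretype == "exon" else cds
        target.setdefault(tid, []).append((feat.start, feat.end))
    transcripts = {}
    for tid, (gene, chrom, strand) in meta.items():
        if tid not in exons:
            raise MorganError(f"{path}: transcript {tid} has CDS but no exons")
        transcripts[tid] = Transcript(
            tid, gene, chrom, strand,
            tuple(sorted(exons[tid])), tuple(sorted(cds.get(tid, []))),
        )
    if not transcripts:
        raise MorganError(f"{path}: no transcripts found")
    return TranscriptAnnotation(transcripts)


def write_gtf(annotation: TranscriptAnnotation, path) -> None:
    with _open_text(path, "wt") as fh:
        for tx in annotation.transcripts.values():
            attrs = f'gene_name "{tx.gene}"; transcript_id "{tx.transcript_id}";'
            for feature, ivs in (("exon", tx.exons), ("CDS", tx.cds)):
                for s, e in ivs:
                    fh.write(
                        f"{tx.chrom}\tmorgan5c\t{feature}\t{s}\t{e}\t.\t"
                        f"{tx.strand}\t.\t{attrs}\n"
                    )


def write_site_table(table: SiteTable, path) -> None:
    write_table(table.df, path)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    df = pd.DataFrame(
        {"sample_id": sheet.samples, "group": [sheet.groups[s] for s in sheet.samples]}
    )
    write_table(df, path)
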