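"""Expression normalization, low-expression filtering, site→gene methylation
aggregation, and matching of the two matrices into the paired dataset the
driver screen consumes."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .site_stats import rank_sum_test
from .types import (
    ExpressionMatrix,
    GeneMethylationMatrix,
    MorganError,
    SampleSheet,
)

log = logging.getLogger(__name__)


@dataclass
class MatchedDataset:
    """Methylation and expression restricted to shared genes and samples,
    with identical row/column orderings, plus the matching group labels."""

    methylation: GeneMethylationMatrix
    expression: ExpressionMatrix  # cpm scale
    metadata: SampleSheet

    @property
    def genes(self) -> list[str]:
        return self.methylation.genes

    @property
    def samples(self) -> list[str]:
        return self.methylation.samples


def cpm_normalize(raw: ExpressionMatrix) -> ExpressionMatrix:
    """Counts-per-million: value[g,s] = raw[g,s] / colsum(s) * 1e6."""
    if raw.scale != "raw_counts":
        raise MorganError(f"cpm_normalize expects raw counts, got {raw.scale!r}")
    colsums = raw.values.sum(axis=0)
    zero = colsums[colsums == 0]
    if len(zero):
        raise MorganError(f"zero column sum for sample {zero.index[0]!r}")
    return ExpressionMatrix(raw.values / colsums * 1e6, scale="cpm")


def filter_low_expression(
    raw: ExpressionMatrix, max_zero_fraction: float = 0.25
) -> ExpressionMatrix:
    """Drop genes with zero counts in strictly more than ``max_zero_fraction``
    of samples (a gene at exactly the boundary fraction is retained)."""
    zero_frac = (raw.values == 0).sum(axis=1) / raw.values.shape[1]
    keep = zero_frac <= max_zero_fraction
    dropped = int((~keep).sum())
    if dropped:
        log.info("filter_low_expression: dropped %d of %d genes", dropped, len(keep))
    return ExpressionMatrix(raw.values.loc[keep], scale=raw.scale)


def aggregate_gene_methylation(
    site_tables, method: str = "pooled"
) -> GeneMethylationMatrix:
    """Collapse per-site methylation to one level per gene and sample.

    ``pooled`` (default): coverage-weighted rate, sum(methylated)/sum(coverage)
    over the gene's covered sites — robust to shallow sites. ``mean``:
    unweighted mean of the per-site rates. Sites with an empty gene field or
    zero coverage are skipped; gene–sample pairs with no usable site are NaN.
    """
    if method not in ("pooled", "mean"):
        raise MorganError(f"unknown aggregation method {method!r}")
    frames = []
    for table in site_tables:
        df = table.df
        usable = df[(df["gene"] != "") & (df["coverage"] > 0)]
        if usable.empty:
            continue
        if method == "pooled":
            grouped = usable.groupby("gene")[["methylated", "coverage"]].sum()
            level = grouped["methylated"] / grouped["coverage"]
        else:
            level = usable.groupby("gene")["meth_rate"].mean()
        level.name = table.sample_id
        frames.append(level)
    if not frames:
        raise MorganError("no usable (gene-assigned, covered) sites in any sample")
    values = pd.concat(frames, axis=1).sort_index()
    return GeneMethylationMatrix(values)


def match(
    methylation: GeneMethylationMatrix,
    expression: ExpressionMatrix,
    metadata: SampleSheet,
) -> MatchedDataset:
    """Strictly match the two matrices by gene name and sample id.

    Keeps the intersections in lexicographic order; logs dropped counts.
    """
    genes = sorted(set(methylation.genes) & set(expression.genes))
    samples = sorted(
        set(methylation.samples) & set(expression.samples) & set(metadata.samples)
    )
    if not genes:
        raise MorganError("no genes shared between methylation and expression")
    if not samples:
        raise MorganError("no samples shared between methylation, expression and metadata")
    log.info(
        "match: kept %d genes (dropped %d meth-only, %d expr-only), %d samples",
        len(genes),
        len(set(methylation.genes) - set(genes)),
        len(set(expression.genes) - set(genes)),
        len(samples),
    )
    return MatchedDataset(
        methylation=GeneMethylationMatrix(methylation.values.loc[genes, samples]),
        expression=ExpressionMatrix(
            expression.values.loc[genes, samples], scale=expression.scale
        ),
        metadata=metadata.subset(samples),
    )


def simple_de(
    cpm: ExpressionMatrix,
    metadata: SampleSheet,
    p_max: float = 0.01,
    min_fold: float = 2.0,
    pseudocount: float = 1.0,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Built-in two-group differential-expression screen.

    Per gene: fold change = (mean cancer CPM + 1) / (mean normal CPM + 1)
    and a two-sided rank-sum p; Benjamini–Hochberg adjusted p-values are
    reported alongside. Returns the genes below the ``p_max`` cut (on the
    raw p by default, the BH padj with ``use_adjusted``) with fold >=
    ``min_fold`` (direction "up") or <= 1/``min_fold`` ("down"). This is a
    lightweight stand-in for a count-model DE fit; externally produced gene
    lists can be supplied to the pipeline instead.
    """
    if cpm.scale != "cpm":
        raise MorganError("simple_de expects a CPM-scaled matrix")
    cancer = metadata.samples_in("cancer")
    normal = metadata.samples_in("normal")
    if len(cancer) < 2 or len(normal) < 2:
        raise MorganError("simple_de needs >= 2 samples per group")
    rows = []
    for gene in cpm.genes:
        x = cpm.values.loc[gene, cancer].to_numpy(dtype=float)
        y = cpm.values.loc[gene, normal].to_numpy(dtype=float)
        fold = (x.mean() + pseudocount) / (y.mean() + pseudocount)
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            p = 1.0
        else:
            _, p = rank_sum_test(x, y)
        rows.append((gene, fold, p))
    df = pd.DataFrame(rows, columns=["gene", "fold_change", "p"])
    df["padj"] = multipletests(df["p"], method="fdr_bh")[1]
    crit = df["padj"] if use_adjusted else df["p"]
    up = (crit < p_max) & (df["fold_change"] >= min_fold)
    down = (crit < p_max) & (df["fold_change"] <= 1.0 / min_fold)
    df["direction"] = np.where(up, "up", np.where(down, "down", ""))
    return df[df["direction"] != ""].reset_index(drop=True)
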