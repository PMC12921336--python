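"""Per-gene Pearson correlation between gene-level methylation and CPM
expression across samples, and the |r| > 0.6 candidate screen."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import MatchedDataset
from .types import MorganError


def gene_correlations(dataset: MatchedDataset, group: str | None = None) -> pd.DataFrame:
    """Pearson r (and classical two-sided t-based p) per gene.

    Samples of both groups are pooled by default; ``group`` restricts to one
    group for sensitivity analysis. Missing methylation entries are
    pairwise-deleted per gene; ``n`` reports the pairs used. Genes with fewer
    than 3 usable pairs or with a constant vector are flagged undefined
    (r = NaN) rather than assigned a value, and are excluded from screening.

    Returns a DataFrame with columns gene, r, p, n, defined.
    """
    if group is not None:
        samples = dataset.metadata.samples_in(group)
        if not samples:
            raise MorganError(f"no samples in group {group!r}")
    else:
        samples = dataset.samples
    meth = dataset.methylation.values[samples]
    expr = dataset.expression.values[samples]
    rows = []
    for gene in dataset.genes:
        m = meth.loc[gene].to_numpy(dtype=float)
        e = expr.loc[gene].to_numpy(dtype=float)
        ok = ~np.isnan(m) & ~np.isnan(e)
        n = int(ok.sum())
        if n < 3 or np.ptp(m[ok]) == 0 or np.ptp(e[ok]) == 0:
            rows.append((gene, np.nan, np.nan, n, False))
            continue
        res = stats.pearsonr(m[ok], e[ok])
        rows.append((gene, float(res.statistic), float(res.pvalue), n, True))
    return pd.DataFrame(rows, columns=["gene", "r", "p", "n", "defined"])


def select_candidates(
    results: pd.DataFrame,
    threshold: float = 0.6,
    sign: str = "positive",
    n_min: int = 5,
) -> pd.DataFrame:
    """Screen the correlation table for candidate driver genes.

    Keeps defined correlations with |r| strictly above ``threshold`` (and
    r > 0 when ``sign`` is "positive"), computed from at least ``n_min``
    sample pairs; output is sorted by descending |r|.
    """
    if not (0 <= threshold < 1):
        raise MorganError(f"correlation threshold must be in [0, 1), got {threshold}")
    if sign not in ("positive", "both"):
        raise MorganError(f"sign must be 'positive' or 'both', got {sign!r}")
    if results.empty:
        raise MorganError("empty correlation results")
    sel = results[results["defined"] & (results["n"] >= n_min)].copy()
    sel = sel[sel["r"].abs() > threshold]
    if sign == "positive":
        sel = sel[sel["r"] > 0]
    sel = sel.reindex(sel["r"].abs().sort_values(ascending=False, kind="mergesort").index)
    return sel.reset_index(drop=True)
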