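"""Per-sample descriptive m5C methylome statistics and cancer-vs-normal
comparisons: site counts, modified-gene counts and percentages, site density,
per-site methylation-rate distributions, Welch t tests on the per-sample
summaries and a Wilcoxon rank-sum test on the pooled per-site rates.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .types import MorganError, SampleSheet, SiteTable, TranscriptAnnotation

SUMMARY_METRICS = [
    "n_sites",
    "n_modified_genes",
    "pct_modified_genes",
    "density",
    "mean_meth_rate",
    "median_meth_rate",
]


def _enumeration_rank_sum(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided rank-sum p by exhaustive enumeration of all
    C(n1+n2, n1) group assignments of the pooled values (ties handled by the
    0.5-credit U statistic). Feasible for small groups only."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    # cmp[i, j] = 1 if pooled[i] > pooled[j], 0.5 on ties
    cmp = (pooled[:, None] > pooled[None, :]).astype(float)
    cmp += 0.5 * (pooled[:, None] == pooled[None, :])
    np.fill_diagonal(cmp, 0.0)
    rowsum = cmp.sum(axis=1)

    def u_of(subset: np.ndarray) -> float:
        # U(S) = sum_{i in S, j not in S} cmp[i, j]
        return rowsum[subset].sum() - cmp[np.ix_(subset, subset)].sum()

    u_obs = u_of(np.arange(n1))
    mu = n1 * n2 / 2.0
    dev_obs = abs(u_obs - mu)
    total = 0
    as_extreme = 0
    for comb in combinations(range(n1 + n2), n1):
        total += 1
        if abs(u_of(np.array(comb)) - mu) >= dev_obs - 1e-12:
            as_extreme += 1
    return u_obs, as_extreme / total


def rank_sum_test(
    x, y, exact_max_n: int = 8
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Returns (U statistic of ``x``, two-sided p). When both groups have at
    most ``exact_max_n`` observations the p-value is exact: scipy's exact
    null distribution for tie-free data, exhaustive enumeration of all group
    assignments otherwise. Larger samples use the normal approximation with
    tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise MorganError("rank_sum_test requires non-empty groups")
    small = len(x) <= exact_max_n and len(y) <= exact_max_n
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if small and has_ties:
        return _enumeration_rank_sum(x, y)
    method = "exact" if small else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def summarize_sample(
    table: SiteTable,
    gene_universe,
    annotation: TranscriptAnnotation | None = None,
) -> dict:
    """One row of descriptive statistics for a sample's site table.

    ``gene_universe`` fixes the denominator of pct_modified_genes (the
    annotated gene set, or the expressed-gene set, per configuration).
    Density is sites-per-exonic-kilobase of the modified genes when an
    annotation is available, and sites-per-modified-gene otherwise; with an
    annotation, both flavours are reported.
    """
    universe = set(gene_universe)
    if not universe:
        raise MorganError("gene universe must be non-empty")
    df = table.df
    n_sites = len(df)
    modified = sorted(set(df.loc[df["gene"] != "", "gene"]))
    n_modified = len(modified)
    rates = df["meth_rate"].dropna()
    out = {
        "sample_id": table.sample_id,
        "n_sites": n_sites,
        "n_modified_genes": n_modified,
        "pct_modified_genes": 100.0 * n_modified / len(universe),
        "mean_meth_rate": float(rates.mean()) if len(rates) else np.nan,
        "median_meth_rate": float(rates.median()) if len(rates) else np.nan,
    }
    density_per_gene = n_sites / n_modified if n_modified else np.nan
    if annotation is not None:
        kb = annotation.exonic_kb_by_gene()
        annotated_genes = set(kb)
        n_in_annotated = int((df["gene"].isin(annotated_genes)).sum())
        total_kb = sum(kb[g] for g in modified if g in kb)
        out["density"] = n_in_annotated / total_kb if total_kb > 0 else np.nan
        out["density_per_gene"] = density_per_gene
    else:
        out["density"] = density_per_gene
    return out


def summarize_samples(
    tables, gene_universe, annotation: TranscriptAnnotation | None = None
) -> pd.DataFrame:
    return pd.DataFrame(
        [summarize_sample(t, gene_universe, annotation) for t in tables]
    )


def pooled_site_rates(
    tables, metadata: SampleSheet, deduplicate: bool = False
) -> dict[str, np.ndarray]:
    """Per-group pooled per-site methylation rates (NaN rates dropped).

    By default a site recurring in several samples contributes once per
    sample; ``deduplicate`` keeps one rate per (chrom, pos, strand) per group
    (the mean over the group's samples carrying the site).
    """
    out = {}
    for group in ("cancer", "normal"):
        members = set(metadata.samples_in(group))
        frames = [t.df for t in tables if t.sample_id in members]
        if not frames:
            raise MorganError(f"no site tables for group {group!r}")
        pooled = pd.concat(frames, ignore_index=True).dropna(subset=["meth_rate"])
        if deduplicate:
            pooled = (
                pooled.groupby(["chrom", "pos", "strand"])["meth_rate"]
                .mean()
                .reset_index()
            )
        out[group] = pooled["meth_rate"].to_numpy(dtype=float)
    return out


def compare_groups(
    summaries: pd.DataFrame,
    tables,
    metadata: SampleSheet,
    deduplicate_sites: bool = False,
    exact_max_n: int = 8,
) -> pd.DataFrame:
    """Cancer-vs-normal comparison table.

    Each per-sample summary metric gets a two-sided Welch (unequal-variance)
    t test; the pooled per-site methylation rates get a two-sided Wilcoxon
    rank-sum test.
    """
    metadata.require_both_groups()
    cancer = metadata.samples_in("cancer")
    normal = metadata.samples_in("normal")
    if len(cancer) < 2 or len(normal) < 2:
        raise MorganError("Welch t tests need >= 2 samples per group")
    indexed = summaries.set_index("sample_id")
    rows = []
    for metric in SUMMARY_METRICS:
        if metric not in indexed.columns:
            continue
        x = indexed.loc[[s for s in cancer if s in indexed.index], metric].dropna()
        y = indexed.loc[[s for s in normal if s in indexed.index], metric].dropna()
        with warnings.catch_warnings():
            # constant metrics (e.g. identical site counts) are legitimate
            # inputs; the nan they produce is corrected just below
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(x, y, equal_var=False)
        if np.isnan(t) and x.nunique() <= 1 and y.nunique() <= 1 and len(x) and len(y) and x.iloc[0] == y.iloc[0]:
            t, p = 0.0, 1.0  # identical constant groups: no difference
        rows.append((metric, "welch_t", float(t), float(p),
                     float(x.mean()), float(y.mean())))
    pooled = pooled_site_rates(tables, metadata, deduplicate=deduplicate_sites)
    u, p = rank_sum_test(pooled["cancer"], pooled["normal"], exact_max_n=exact_max_n)
    rows.append(
        ("per_site_meth_rate", "rank_sum", float(u), float(p),
         float(np.mean(pooled["cancer"])), float(np.mean(pooled["normal"])))
    )
    return pd.DataFrame(
        rows,
        columns=["metric", "test_name", "statistic", "p", "mean_cancer", "mean_normal"],
    )
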