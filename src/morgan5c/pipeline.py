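"""End-to-end driver screen: normalize → match → correlate → per-gene
mixture states → DM score → ranking. This is the library face of the
workflow; the CLI wraps it."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import correlate, dm_score, preprocess, state_model
from .preprocess import MatchedDataset
from .types import (
    ExpressionMatrix,
    GeneMethylationMatrix,
    MorganError,
    SampleSheet,
)

log = logging.getLogger(__name__)


@dataclass
class RunResult:
    matched: MatchedDataset
    correlations: pd.DataFrame
    candidates: pd.DataFrame
    fits: dict[str, state_model.MixtureFit]
    dm_results: list[dm_score.DMResult]
    ranking: pd.DataFrame          # all scored genes, ranked
    top: pd.DataFrame              # head(top_n)
    skipped: list[str] = field(default_factory=list)

    @property
    def full_table(self) -> pd.DataFrame:
        return dm_score.result_table(self.dm_results)


def run_morgan(
    methylation: GeneMethylationMatrix,
    raw_counts: ExpressionMatrix,
    metadata: SampleSheet,
    *,
    max_zero_fraction: float = 0.25,
    restrict_genes=None,
    corr_threshold: float = 0.6,
    corr_sign: str = "positive",
    corr_n_min: int = 5,
    corr_group: str | None = None,
    G_range=(1, 2, 3),
    gmm_tol: float = 1e-8,
    gmm_max_iter: int = 500,
    gmm_var_floor: float = 1e-6,
    o_mode: str = "occupancy_entropy",
    dm_eps: float = 1e-6,
    missing_group_policy: str = "group_global_mean",
    top_n: int = 10,
) -> RunResult:
    """Run the full m5C driver screen on a matched cohort.

    ``restrict_genes`` optionally limits the screen to an externally supplied
    gene list (e.g. a differential-expression result) before correlation.
    Genes whose mixture fit is inadmissible, or whose state summary cannot be
    formed, are recorded in ``skipped`` rather than aborting the run.
    """
    metadata.require_both_groups()
    filtered = preprocess.filter_low_expression(raw_counts, max_zero_fraction)
    if filtered.values.empty:
        raise MorganError("no genes survive the low-expression filter")
    cpm = preprocess.cpm_normalize(filtered)
    matched = preprocess.match(methylation, cpm, metadata)
    if restrict_genes is not None:
        keep = sorted(set(matched.genes) & set(restrict_genes))
        if not keep:
            raise MorganError("gene restriction removes every matched gene")
        matched = MatchedDataset(
            methylation=GeneMethylationMatrix(matched.methylation.values.loc[keep]),
            expression=ExpressionMatrix(
                matched.expression.values.loc[keep], scale="cpm"
            ),
            metadata=matched.metadata,
        )
    correlations = correlate.gene_correlations(matched, group=corr_group)
    candidates = correlate.select_candidates(
        correlations, threshold=corr_threshold, sign=corr_sign, n_min=corr_n_min
    )
    log.info(
        "screen: %d candidates of %d matched genes (|r| > %g, sign=%s)",
        len(candidates), len(correlations), corr_threshold, corr_sign,
    )

    samples = matched.samples
    group_labels = matched.metadata.labels(samples)
    fits: dict[str, state_model.MixtureFit] = {}
    results: list[dm_score.DMResult] = []
    skipped: list[str] = []
    for row in candidates.itertuples(index=False):
        gene = row.gene
        values = matched.methylation.values.loc[gene, samples].to_numpy(dtype=float)
        ok = ~np.isnan(values)
        try:
            fit = state_model.select_model(
                values[ok], G_range=G_range, tol=gmm_tol,
                max_iter=gmm_max_iter, var_floor=gmm_var_floor, gene=gene,
            )
            labels = state_model.assign_states(fit)
            res = dm_score.score_gene(
                gene, values[ok], labels, group_labels[ok], fit=fit,
                r=float(row.r), missing_group_policy=missing_group_policy,
                o_mode=o_mode, eps=dm_eps,
            )
        except MorganError as exc:
            log.warning("skipping gene %s: %s", gene, exc)
            skipped.append(gene)
            continue
        fits[gene] = fit
        results.append(res)
    ranking = dm_score.rank_genes(results, top_n=None)
    return RunResult(
        matched=matched,
        correlations=correlations,
        candidates=candidates,
        fits=fits,
        dm_results=results,
        ranking=ranking,
        top=ranking.head(top_n),
        skipped=skipped,
    )


def fit_summary_table(fits: dict[str, state_model.MixtureFit]) -> pd.DataFrame:
    """Per-gene mixture summary (means/variances/weights as comma-joined
    fields) for the audit TSV."""
    rows = []
    for gene, fit in fits.items():
        rows.append(
            {
                "gene": gene,
                "G": fit.G,
                "means": ",".join(f"{m:.6g}" for m in fit.means),
                "variances": ",".join(f"{v:.6g}" for v in fit.variances),
                "weights": ",".join(f"{w:.6g}" for w in fit.weights),
                "loglik": fit.loglik,
                "bic": fit.bic,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "G", "means", "variances", "weights", "loglik", "bic",
                 "converged"],
    )
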