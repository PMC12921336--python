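"""The Differential Methylation (DM) value: an entropy/occupancy-weighted
mean, over a gene's methylation states, of the log-shifted cancer-minus-normal
mean-methylation difference.

For each state i of a gene's mixture fit, with C_i samples MAP-assigned,
occupancy p_i = C_i / N, group means mu_cancer_i and mu_normal_i and
difference delta_i, the score is

    DM = sum_i O_i * C_i * ln(delta_i + 1) / sum_i O_i * C_i

with complexity weight O_i = -p_i * ln(p_i) by default (an alternative mode
uses the mean posterior-assignment entropy of the state's members). The
log-shift ln(delta + 1) amplifies hypermethylated states; delta + 1 is
clamped below at ``eps`` so a fully reversed state (delta = -1) yields a
large negative contribution rather than -inf. When every weight vanishes
(the single-state case: p = 1 so -p ln p = 0) the sample counts C_i take
over as weights; a higher DM value indicates a stronger cancer-associated
methylation gain. Ranking is invariant to the base of the logarithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .state_model import MixtureFit
from .types import MorganError


@dataclass
class StateSummary:
    """Per-state occupancy, weights, and group methylation means."""

    state: int                # 1..G, ascending-mean order
    C: int                    # samples MAP-assigned to the state
    p: float                  # occupancy C / N
    O: float                  # complexity (entropy) weight
    mu_cancer: float
    mu_normal: float
    delta: float              # mu_cancer - mu_normal
    contribution: float       # ln(max(delta + 1, eps))
    fallback_cancer: bool     # group mean substituted by gene-wide mean
    fallback_normal: bool


@dataclass
class DMResult:
    gene: str
    dm_value: float
    states: list[StateSummary]
    r: float | None = None
    G: int | None = None
    rank: int | None = None


def state_summaries(
    values,
    map_state,
    group_labels,
    fit: MixtureFit | None = None,
    missing_group_policy: str = "group_global_mean",
    o_mode: str = "occupancy_entropy",
    eps: float = 1e-6,
) -> list[StateSummary]:
    """Per-state group methylation means and weights.

    ``values`` are the gene's per-sample methylation levels, ``map_state``
    the MAP labels (1..G) and ``group_labels`` the matching cancer/normal
    array. A state missing one group either borrows that group's gene-wide
    mean (policy ``group_global_mean``, flagged) or is dropped from the
    weighted sum (policy ``drop_state``).
    """
    if missing_group_policy not in ("group_global_mean", "drop_state"):
        raise MorganError(f"unknown missing-group policy {missing_group_policy!r}")
    if o_mode not in ("occupancy_entropy", "posterior_entropy"):
        raise MorganError(f"unknown O_i mode {o_mode!r}")
    if o_mode == "posterior_entropy" and fit is None:
        raise MorganError("posterior_entropy mode needs the mixture fit")
    x = np.asarray(values, dtype=float)
    labels = np.asarray(map_state, dtype=int)
    groups = np.asarray(group_labels)
    if not (len(x) == len(labels) == len(groups)):
        raise MorganError("values, states and group labels must align")
    n = len(x)
    is_cancer = groups == "cancer"
    is_normal = groups == "normal"
    if not is_cancer.any() or not is_normal.any():
        raise MorganError("both cancer and normal samples are required")
    global_mu = {
        "cancer": float(x[is_cancer].mean()),
        "normal": float(x[is_normal].mean()),
    }
    summaries: list[StateSummary] = []
    for state in sorted(set(labels.tolist())):
        members = labels == state
        c = int(members.sum())
        p = c / n
        if o_mode == "occupancy_entropy":
            o = float(-p * np.log(p)) if p < 1.0 else 0.0
        else:
            resp = fit.responsibilities[members]
            with np.errstate(divide="ignore", invalid="ignore"):
                ent = -np.nansum(np.where(resp > 0, resp * np.log(resp), 0.0), axis=1)
            o = float(ent.mean())
        fb_c = not (members & is_cancer).any()
        fb_n = not (members & is_normal).any()
        if (fb_c or fb_n) and missing_group_policy == "drop_state":
            continue
        mu_c = global_mu["cancer"] if fb_c else float(x[members & is_cancer].mean())
        mu_n = global_mu["normal"] if fb_n else float(x[members & is_normal].mean())
        delta = mu_c - mu_n
        summaries.append(
            StateSummary(
                state=state,
                C=c,
                p=p,
                O=o,
                mu_cancer=mu_c,
                mu_normal=mu_n,
                delta=delta,
                contribution=float(np.log(max(delta + 1.0, eps))),
                fallback_cancer=fb_c,
                fallback_normal=fb_n,
            )
        )
    return summaries


def dm_value(summaries: list[StateSummary]) -> float:
    """Weighted mean of the per-state log-shifted differences.

    Weights are w_i = O_i * C_i; when they all vanish (G = 1), w_i = C_i.
    """
    if not summaries:
        raise MorganError("no states to score")
    w = np.array([s.O * s.C for s in summaries], dtype=float)
    contrib = np.array([s.contribution for s in summaries], dtype=float)
    if w.sum() == 0.0:
        w = np.array([s.C for s in summaries], dtype=float)
    return float(np.dot(w, contrib) / w.sum())


def score_gene(
    gene,
    values,
    map_state,
    group_labels,
    fit: MixtureFit | None = None,
    r: float | None = None,
    missing_group_policy: str = "group_global_mean",
    o_mode: str = "occupancy_entropy",
    eps: float = 1e-6,
) -> DMResult:
    summaries = state_summaries(
        values, map_state, group_labels, fit=fit,
        missing_group_policy=missing_group_policy, o_mode=o_mode, eps=eps,
    )
    return DMResult(
        gene=gene,
        dm_value=dm_value(summaries),
        states=summaries,
        r=r,
        G=fit.G if fit is not None else None,
    )


def rank_genes(results: list[DMResult], top_n: int | None = 10) -> pd.DataFrame:
    """Order candidates by descending DM value (ties: descending r, then
    gene name) and fill ranks 1..K; ``top_n`` truncates the table
    (None keeps all)."""
    def key(res: DMResult):
        r = res.r if res.r is not None and np.isfinite(res.r) else -np.inf
        return (-res.dm_value, -r, res.gene)

    ordered = sorted(results, key=key)
    rows = []
    for rank, res in enumerate(ordered, start=1):
        res.rank = rank
        rows.append(
            {
                "gene": res.gene,
                "r": res.r,
                "G": res.G,
                "dm_value": res.dm_value,
                "rank": rank,
            }
        )
    df = pd.DataFrame(rows, columns=["gene", "r", "G", "dm_value", "rank"])
    if top_n is not None:
        df = df.head(top_n)
    return df


def result_table(results: list[DMResult], max_states: int = 3) -> pd.DataFrame:
    """Wide per-gene table with per-state columns (C_i, O_i, group means,
    contribution, fallback flags) for auditability."""
    rows = []
    for res in results:
        row = {
            "gene": res.gene,
            "r": res.r,
            "G": res.G,
            "dm_value": res.dm_value,
            "rank": res.rank,
        }
        for s in res.states:
            i = s.state
            row.update(
                {
                    f"C_{i}": s.C,
                    f"O_{i}": s.O,
                    f"mu_cancer_{i}": s.mu_cancer,
                    f"mu_normal_{i}": s.mu_normal,
                    f"contribution_{i}": s.contribution,
                    f"fallback_{i}": int(s.fallback_cancer or s.fallback_normal),
                }
            )
        rows.append(row)
    cols = ["gene", "r", "G", "dm_value", "rank"]
    for i in range(1, max_states + 1):
        cols += [f"C_{i}", f"O_{i}", f"mu_cancer_{i}", f"mu_normal_{i}",
                 f"contribution_{i}", f"fallback_{i}"]
    return pd.DataFrame(rows).reindex(columns=cols)
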