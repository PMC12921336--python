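"""One-dimensional Gaussian mixture over a gene's per-sample methylation
levels.

Each candidate gene's methylation values are modeled as a mixture of G
Gaussians, G = 1..3, capturing low/medium/high methylation states across the
cohort. EM runs from a deterministic quantile initialization (no random
restarts, so fits are seed-free and bit-stable), per-component variances are
free but floored, the component count is chosen by minimizing
BIC = -2*loglik + (3G-1)*ln(n), and each sample is MAP-assigned to the state
of maximal posterior responsibility after states are re-ordered by ascending
mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import MorganError

_LOG2PI = np.log(2.0 * np.pi)


class FitRefused(MorganError):
    """The requested mixture cannot be fit on this input (too few points or
    zero spread); a refusal, not a crash — model selection skips it."""


@dataclass
class MixtureFit:
    """A converged (or iteration-capped) G-component fit, states sorted by
    ascending mean."""

    G: int
    means: np.ndarray          # shape (G,)
    variances: np.ndarray      # shape (G,), >= var_floor
    weights: np.ndarray        # shape (G,), sums to 1
    loglik: float
    bic: float
    responsibilities: np.ndarray  # shape (n, G), rows sum to 1
    converged: bool
    loglik_trace: list[float] = field(default_factory=list)
    gene: str | None = None

    @property
    def n(self) -> int:
        return self.responsibilities.shape[0]

    @property
    def state_names(self) -> list[str]:
        return {
            1: ["single"],
            2: ["low", "high"],
            3: ["low", "medium", "high"],
        }[self.G]


def _log_density(x: np.ndarray, means, variances, weights) -> np.ndarray:
    """Per-point, per-component weighted log density, shape (n, G)."""
    return (
        -0.5 * ((x[:, None] - means[None, :]) ** 2 / variances[None, :])
        - 0.5 * (np.log(variances[None, :]) + _LOG2PI)
        + np.log(weights[None, :])
    )


def fit_gmm_1d(
    values,
    G: int,
    tol: float = 1e-8,
    max_iter: int = 500,
    var_floor: float = 1e-6,
    var_floor_rel: float = 0.01,
    gene: str | None = None,
) -> MixtureFit:
    """EM fit of a G-component univariate Gaussian mixture.

    Initialization is deterministic: means at the i/(G+1) quantiles,
    variances at the pooled sample variance, equal weights. Iterates until
    the log-likelihood improves by less than ``tol`` or ``max_iter`` is hit.
    Refuses (raises :class:`FitRefused`) when n < 3G or when G > 1 on
    all-identical values.

    The unconstrained likelihood of a free-variance mixture is unbounded (a
    component can collapse onto a few near-identical points), so the fit is
    the constrained MLE with every component variance floored at
    ``max(var_floor, var_floor_rel * var(x))`` — no state may be narrower
    than a tenth (by default) of the sample's overall spread. The floored
    M-step is the exact constrained maximizer, so EM monotonicity is
    preserved.
    """
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise MorganError("mixture input contains non-finite values")
    n = len(x)
    if n < 3 * G:
        raise FitRefused(f"n={n} < 3*G={3 * G}")
    if G > 1 and np.ptp(x) == 0:
        raise FitRefused("all values identical; G > 1 not identifiable")
    var_floor = max(var_floor, var_floor_rel * float(np.var(x)))

    means = np.quantile(x, [(i + 1) / (G + 1) for i in range(G)])
    if G > 1 and np.any(np.diff(means) <= 0):
        # heavy ties can collapse quantiles; spread deterministically
        means = means + np.arange(G) * 1e-6
    variances = np.full(G, max(float(np.var(x)), var_floor))
    weights = np.full(G, 1.0 / G)

    trace: list[float] = []
    prev = -np.inf
    converged = False
    resp = None
    for _ in range(max_iter):
        logd = _log_density(x, means, variances, weights)
        norm = np.logaddexp.reduce(logd, axis=1)
        loglik = float(norm.sum())
        resp = np.exp(logd - norm[:, None])
        trace.append(loglik)
        if abs(loglik - prev) < tol:
            converged = True
            break
        prev = loglik
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        weights = nk / n
        means = resp.T @ x / nk
        variances = np.maximum(
            (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk, var_floor
        )
    else:
        # final E-step so reported responsibilities match reported params
        logd = _log_density(x, means, variances, weights)
        norm = np.logaddexp.reduce(logd, axis=1)
        loglik = float(norm.sum())
        resp = np.exp(logd - norm[:, None])
        trace.append(loglik)

    order = np.argsort(means, kind="stable")
    means, variances, weights = means[order], variances[order], weights[order]
    resp = resp[:, order]
    k = 3 * G - 1
    bic = -2.0 * loglik + k * np.log(n)
    return MixtureFit(
        G=G,
        means=means,
        variances=variances,
        weights=weights,
        loglik=loglik,
        bic=float(bic),
        responsibilities=resp,
        converged=converged,
        loglik_trace=trace,
        gene=gene,
    )


def select_model(
    values,
    G_range=(1, 2, 3),
    tol: float = 1e-8,
    max_iter: int = 500,
    var_floor: float = 1e-6,
    var_floor_rel: float = 0.01,
    gene: str | None = None,
    return_all: bool = False,
):
    """Fit every admissible component count and keep the minimal-BIC fit.

    A count G is skipped when n < 3G or the fit is refused; BIC ties within
    1e-9 resolve to the smaller G (fits are evaluated in ascending order).
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise MorganError(f"model selection needs n >= 3, got {len(x)}")
    fits: dict[int, MixtureFit] = {}
    for G in sorted(G_range):
        try:
            fits[G] = fit_gmm_1d(
                x, G, tol=tol, max_iter=max_iter, var_floor=var_floor,
                var_floor_rel=var_floor_rel, gene=gene,
            )
        except FitRefused:
            continue
    if not fits:
        raise MorganError("no admissible component count for this input")
    best = None
    for G in sorted(fits):
        if best is None or fits[G].bic < best.bic - 1e-9:
            best = fits[G]
    return (best, fits) if return_all else best


def assign_states(fit: MixtureFit) -> np.ndarray:
    """MAP state labels (1..G, ascending-mean order) per sample.

    Exact responsibility ties resolve to the lower-mean state.
    """
    return np.argmax(fit.responsibilities, axis=1) + 1
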