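"""Independent brute-force oracles used by the tests.

These deliberately re-derive results with the plainest possible Python
(loops, itertools, closed forms) and share no code with the package, so a
test comparing the two is a genuine dual-route check.
"""

from __future__ import annotations

import math
from itertools import combinations


def brute_force_dm(values, states, groups):
    """Differential Methylation value computed straight from its definition.

    values: per-sample methylation levels; states: per-sample state labels;
    groups: per-sample 'cancer'/'normal'. Weighted mean over states of
    ln(mu_cancer - mu_normal + 1), weights O_i * C_i with O_i = -p ln p,
    falling back to C_i when every weight is zero; a state missing one group
    borrows that group's mean over all samples.
    """
    n = len(values)
    cancer_all = [v for v, g in zip(values, groups) if g == "cancer"]
    normal_all = [v for v, g in zip(values, groups) if g == "normal"]
    per_state = []
    for s in sorted(set(states)):
        members = [i for i in range(n) if states[i] == s]
        c = len(members)
        p = c / n
        o = -p * math.log(p) if p < 1.0 else 0.0
        canc = [values[i] for i in members if groups[i] == "cancer"]
        norm = [values[i] for i in members if groups[i] == "normal"]
        mu_c = sum(canc) / len(canc) if canc else sum(cancer_all) / len(cancer_all)
        mu_n = sum(norm) / len(norm) if norm else sum(normal_all) / len(normal_all)
        delta = mu_c - mu_n
        per_state.append((o, c, math.log(max(delta + 1.0, 1e-6))))
    wsum = sum(o * c for o, c, _ in per_state)
    if wsum == 0.0:
        num = sum(c * contrib for _, c, contrib in per_state)
        den = sum(c for _, c, _ in per_state)
    else:
        num = sum(o * c * contrib for o, c, contrib in per_state)
        den = wsum
    return num / den


def exact_rank_sum_p(x, y):
    """Exact two-sided rank-sum p by enumerating every group assignment.

    Uses the rank-sum W of the first group (mid-ranks for ties) and counts
    assignments whose |W - E[W]| is at least the observed deviation.
    """
    pooled = list(x) + list(y)
    n1 = len(x)
    n = len(pooled)
    order = sorted(range(n), key=lambda i: pooled[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        midrank = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = midrank
        i = j + 1
    w_obs = sum(ranks[:n1])
    ew = n1 * (n + 1) / 2.0
    dev = abs(w_obs - ew)
    total = extreme = 0
    for subset in combinations(range(n), n1):
        total += 1
        w = sum(ranks[i] for i in subset)
        if abs(w - ew) >= dev - 1e-12:
            extreme += 1
    return extreme / total


def pearson_r(x, y):
    """Textbook covariance / (sigma_x * sigma_y)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def gaussian_mixture_loglik(x, means, variances, weights):
    """Direct density evaluation of a 1-D Gaussian mixture."""
    total = 0.0
    for v in x:
        dens = 0.0
        for m, var, w in zip(means, variances, weights):
            dens += w * math.exp(-0.5 * (v - m) ** 2 / var) / math.sqrt(2 * math.pi * var)
        total += math.log(dens)
    return total
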