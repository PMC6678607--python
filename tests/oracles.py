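"""Independent brute-force oracles, coded straight from the definitions and
kept free of any code path they are used to check."""

import math

import numpy as np
from scipy.optimize import minimize


def ssgsea_bruteforce(values, in_set, alpha, names=None):
    """Running-sum single-sample enrichment, explicit O(n^2) loops.

    ``values``: 1-D expression vector for one sample; ``in_set``: boolean
    membership; average ranks for ties (rank n = highest), walk descending
    (tied values ordered by gene name), in-set increments rank^alpha
    normalized by the in-set total, out-of-set increments uniform; score is
    the sum of the running-sum differences at every position.
    """
    values = list(values)
    n = len(values)
    if names is None:
        names = [f"G{i}" for i in range(n)]
    # average ascending ranks computed by counting, not via scipy
    ranks = []
    for i, v in enumerate(values):
        less = sum(1 for u in values if u < v)
        equal = sum(1 for u in values if u == v)
        ranks.append(less + (equal + 1) / 2.0)
    order = sorted(range(n), key=lambda i: (-values[i], names[i]))
    denom_in = sum(ranks[i] ** alpha for i in order if in_set[i])
    n_out = sum(1 for i in range(n) if not in_set[i])
    if denom_in == 0 or n_out == 0:
        return 0.0
    score = 0.0
    p_in = 0.0
    p_out = 0.0
    for i in order:
        if in_set[i]:
            p_in += ranks[i] ** alpha / denom_in
        else:
            p_out += 1.0 / n_out
        score += p_in - p_out
    return score


def logistic_ml_or_2x2(a, b, c, d):
    """Odds ratio from a direct numerical ML fit of the saturated logistic
    model to a 2x2 table (exposure -> outcome), independent of any closed
    form or IRLS machinery."""

    def negloglik(params):
        b0, b1 = params
        ll = 0.0
        for x, y, count in ((1, 1, a), (1, 0, b), (0, 1, c), (0, 0, d)):
            eta = b0 + b1 * x
            p = 1.0 / (1.0 + math.exp(-eta))
            p = min(max(p, 1e-12), 1 - 1e-12)
            ll += count * (y * math.log(p) + (1 - y) * math.log(1 - p))
        return -ll

    res = minimize(negloglik, x0=np.zeros(2), method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 10000})
    return math.exp(res.x[1])


def kruskal_h_bruteforce(groups):
    """H = 12/(n(n+1)) * sum n_i (rbar_i - rbar)^2 on pooled average ranks
    (no tie correction; use on tie-free data)."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    order = sorted(range(n), key=lambda i: pooled[i])
    ranks = [0.0] * n
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    rbar = (n + 1) / 2.0
    h = 0.0
    start = 0
    for g in groups:
        size = len(g)
        gr = ranks[start:start + size]
        start += size
        h += size * (sum(gr) / size - rbar) ** 2
    return 12.0 / (n * (n + 1)) * h
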