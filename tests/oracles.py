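"""Independent reference implementations used only to check the package.

Each oracle solves the same problem as the production code by a different
route: proximal gradient instead of coordinate descent, exhaustive
enumeration instead of closed-form distributions, pair counting instead of
rank formulas.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def proximal_gradient_lasso(y, X, delta, lambda1, tol=1e-12, max_iter=200000):
    """ISTA solver for (1/2n)||y - Xb||^2 + lambda1 * sum delta_k |b_k|."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    delta = np.asarray(delta, float)
    n, M = X.shape
    L = np.linalg.eigvalsh(X.T @ X / n).max()  # Lipschitz constant of the gradient
    step = 1.0 / L
    b = np.zeros(M)
    thresh = step * lambda1 * delta
    for _ in range(max_iter):
        grad = X.T @ (X @ b - y) / n
        z = b - step * grad
        b_new = np.sign(z) * np.maximum(np.abs(z) - thresh, 0.0)
        if np.max(np.abs(b_new - b)) < tol:
            return b_new
        b = b_new
    return b


def mannwhitney_exact_p(a, b) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all rank assignments."""
    a = list(a)
    b = list(b)
    pooled = a + b
    assert len(set(pooled)) == len(pooled), "enumeration oracle assumes no ties"
    n1 = len(a)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    u_obs = sum(ranks[v] for v in a) - n1 * (n1 + 1) / 2

    def two_sided_dev(u):
        return abs(u - n1 * len(b) / 2.0)

    total = 0
    extreme = 0
    for subset in combinations(range(1, len(pooled) + 1), n1):
        u = sum(subset) - n1 * (n1 + 1) / 2
        total += 1
        if two_sided_dev(u) >= two_sided_dev(u_obs) - 1e-12:
            extreme += 1
    return extreme / total


def hypergeom_upper_p(overlap, background, set_size, list_size) -> float:
    """P[X >= overlap] by direct combinatorial summation."""
    num = sum(
        comb(set_size, k) * comb(background - set_size, list_size - k)
        for k in range(overlap, min(set_size, list_size) + 1)
    )
    return num / comb(background, list_size)


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher p by enumerating all tables with the same margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    return sum(prob(x) for x in range(max(0, c1 - r2), min(r1, c1) + 1)
               if prob(x) <= p_obs * (1 + 1e-12))


def auc_pair_counting(scores, truth) -> float:
    """AUC by explicit positive-negative pair comparison."""
    scores = np.asarray(scores, float)
    truth = np.asarray(truth).astype(bool)
    pos = scores[truth]
    neg = scores[~truth]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return float(wins / (len(pos) * len(neg)))


def logrank_two_group(time, event, group):
    """Hand-tabulated unweighted two-group log-rank chi-square."""
    time = np.asarray(time, float)
    event = np.asarray(event).astype(int)
    group = np.asarray(group)
    g1 = np.unique(group)[1]
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == g1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == g1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def quantile_normalize_reference(values):
    """Literal sort/average/unsort quantile normalization with tie averaging."""
    values = np.asarray(values, float)
    n, g = values.shape
    ref = np.sort(values, axis=1).mean(axis=0)
    out = np.empty_like(values)
    for i in range(n):
        row = values[i]
        order = sorted(range(g), key=lambda j: row[j])
        positions = {}
        for pos, j in enumerate(order):
            positions.setdefault(row[j], []).append(pos)
        for j in range(g):
            out[i, j] = np.mean([ref[p] for p in positions[row[j]]])
    return out
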