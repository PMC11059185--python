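"""Independent brute-force oracles used by the test suite.

Each function recomputes a quantity by a route deliberately different
from the package implementation (dynamic programming, exhaustive
enumeration, closed forms, hand-coded formulas) so agreement is
evidence, not tautology.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def kmeans_1d_optimal_wss(values, k: int) -> float:
    """Global optimum of 1-D k-means by DP over sorted contiguous blocks.

    In one dimension the optimal k-means partition consists of
    contiguous blocks of the sorted values; dynamic programming over
    block boundaries finds the global minimum within-cluster sum of
    squares exactly.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    pre = np.concatenate([[0.0], np.cumsum(x)])
    pre2 = np.concatenate([[0.0], np.cumsum(x**2)])

    def block_cost(i: int, j: int) -> float:  # cost of x[i:j]
        m = j - i
        s = pre[j] - pre[i]
        return (pre2[j] - pre2[i]) - s * s / m

    INF = float("inf")
    dp = np.full((k + 1, n + 1), INF)
    dp[0, 0] = 0.0
    for kk in range(1, k + 1):
        for j in range(kk, n + 1):
            dp[kk, j] = min(
                dp[kk - 1, i] + block_cost(i, j) for i in range(kk - 1, j)
            )
    return float(dp[k, n])


def ward_first_merge(points: np.ndarray) -> tuple[int, int, float]:
    """First agglomerative Ward merge on leaves by exhaustive search.

    Returns the pair of leaf indices with minimal Ward distance
    sqrt(2 * (n_i*n_j)/(n_i+n_j)) * ||c_i - c_j|| (singleton clusters:
    plain Euclidean distance) and that distance.
    """
    n = len(points)
    best = (None, None, float("inf"))
    for i, j in itertools.combinations(range(n), 2):
        d = float(np.linalg.norm(points[i] - points[j]))
        if d < best[2]:
            best = (i, j, d)
    return best


def pooled_percent(records) -> dict:
    """Pool neuron counts record by record: 100 * sum(pos) / sum(total)."""
    acc: dict = {}
    for _, r in records.iterrows():
        key = (r["subject_id"], r["region"], r["rater_id"])
        pos, tot = acc.get(key, (0, 0))
        acc[key] = (pos + r["n_positive"], tot + r["n_total"])
    return {k: 100.0 * p / t for k, (p, t) in acc.items() if t > 0}


def mwu_statistic(x, y) -> float:
    """Mann-Whitney U for x by counting all pairs (+0.5 per tie)."""
    u = 0.0
    for xi in x:
        for yi in y:
            if xi > yi:
                u += 1.0
            elif xi == yi:
                u += 0.5
    return u


def welch_f(groups: dict) -> tuple[float, float, float]:
    """Welch's F and degrees of freedom from the textbook formulas."""
    w, m, n = {}, {}, {}
    for g, v in groups.items():
        v = np.asarray(v, dtype=float)
        n[g] = len(v)
        m[g] = v.mean()
        w[g] = n[g] / v.var(ddof=1)
    k = len(groups)
    sw = sum(w.values())
    grand = sum(w[g] * m[g] for g in groups) / sw
    num = sum(w[g] * (m[g] - grand) ** 2 for g in groups) / (k - 1)
    lam = sum((1 - w[g] / sw) ** 2 / (n[g] - 1) for g in groups)
    den = 1 + 2 * (k - 2) / (k**2 - 1) * lam
    f = num / den
    df2 = (k**2 - 1) / (3 * lam)
    return float(f), float(k - 1), float(df2)


def icc_2_1(mat: np.ndarray) -> float:
    """ICC(2,1) from two-way ANOVA mean squares, computed by hand."""
    mat = np.asarray(mat, dtype=float)
    n, k = mat.shape
    grand = mat.mean()
    row_means = mat.mean(axis=1)
    col_means = mat.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((mat - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))


def bh_stepup(p) -> np.ndarray:
    """BH adjusted p-values via min over the tail of p * m / rank."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def hypergeom_upper_tail(k: int, M: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(M, n, N), by direct summation."""
    total = 0.0
    for x in range(k, min(n, N) + 1):
        total += (
            math.comb(n, x) * math.comb(M - n, N - x) / math.comb(M, N)
        )
    return total


def first_pc_eigh(z: np.ndarray) -> np.ndarray:
    """First-PC scores via explicit covariance eigendecomposition."""
    zc = z - z.mean(axis=0, keepdims=True)
    cov = zc.T @ zc / (len(z) - 1)
    vals, vecs = np.linalg.eigh(cov)
    v = vecs[:, np.argmax(vals)]
    return zc @ v
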