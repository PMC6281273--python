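"""Independent brute-force oracles used to verify the package's statistics.

Everything here is deliberately naive: textbook formulas, exact integer
arithmetic and exhaustive enumeration, sharing no code with the package.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
from scipy.stats import chi2 as _chi2_dist
from scipy.stats import norm as _norm


def chi2_2x2(ma: float, ua: float, mb: float, ub: float):
    """Pearson chi-squared via expected cells, df=1, no correction."""
    table = np.array([[ma, ua], [mb, ub]], dtype=float)
    n = table.sum()
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if n == 0 or np.any(rows == 0) or np.any(cols == 0):
        return 0.0, 1.0
    expected = np.outer(rows, cols) / n
    stat = float(((table - expected) ** 2 / expected).sum())
    return stat, float(_chi2_dist.sf(stat, df=1))


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), exact enumeration."""
    denom = math.comb(N, n)
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        if n - i <= N - K:
            total += Fraction(math.comb(K, i) * math.comb(N - K, n - i), denom)
    return float(total)


def fisher_one_sided(table) -> float:
    """One-sided (greater) Fisher p from the hypergeometric upper tail."""
    (a, b), (c, d) = table
    return hypergeom_tail(a, a + b + c + d, a + b, a + c)


def bh_adjust(p: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up, written out longhand."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adjusted[i] = running
    return adjusted


def binom_two_sided(k: int, n: int) -> float:
    """Exact two-sided binomial test at p0 = 1/2 (minlike definition).

    Sums P(X = i) over every i whose point probability does not exceed
    P(X = k); exact through integer binomial coefficients.
    """
    ck = math.comb(n, k)
    total = sum(math.comb(n, i) for i in range(n + 1) if math.comb(n, i) <= ck)
    return float(Fraction(total, 2**n))


def signed_rank_two_sided(diffs) -> float:
    """Exact paired signed-rank p by dynamic programming over rank sums.

    Zero differences are dropped; assumes no ties among |differences| (use
    continuous inputs). The null distribution of W+ is built by convolving
    {0, rank} over ranks 1..n; two-sided p = 2 * min(P(W+ <= w), P(W+ >= w)),
    capped at 1.
    """
    d = np.asarray([x for x in diffs if x != 0], dtype=float)
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_plus = int(ranks[d > 0].sum())
    max_sum = n * (n + 1) // 2
    counts = np.zeros(max_sum + 1, dtype=object)
    counts[0] = 1
    for r in range(1, n + 1):
        new = counts.copy()
        new[r:] = new[r:] + counts[: max_sum + 1 - r]
        counts = new
    total = 2**n
    p_le = Fraction(int(sum(counts[: w_plus + 1])), total)
    p_ge = Fraction(int(sum(counts[w_plus:])), total)
    return float(min(1, 2 * min(p_le, p_ge)))


def logistic_lrt(groups, n_meth, n_unmeth, tol=1e-12, max_iter=200):
    """Binomial-GLM likelihood-ratio test by hand-rolled IRLS.

    Model: logit(p) = b0 + b1 * group, observations weighted by coverage.
    Returns (lrt, p) against the intercept-only model.
    """
    g = np.asarray(groups, dtype=float)
    m = np.asarray(n_meth, dtype=float)
    u = np.asarray(n_unmeth, dtype=float)
    cov = m + u

    def fit(X):
        beta = np.zeros(X.shape[1])
        for _ in range(max_iter):
            eta = X @ beta
            p = 1.0 / (1.0 + np.exp(-eta))
            p = np.clip(p, 1e-12, 1 - 1e-12)
            W = cov * p * (1 - p)
            z = eta + (m - cov * p) / W
            new = np.linalg.solve(X.T @ (W[:, None] * X), X.T @ (W * z))
            if np.max(np.abs(new - beta)) < tol:
                beta = new
                break
            beta = new
        eta = X @ beta
        p = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
        return float(np.sum(m * np.log(p) + u * np.log(1 - p)))

    ll1 = fit(np.column_stack([np.ones_like(g), g]))
    ll0 = fit(np.ones((len(g), 1)))
    lrt = max(0.0, 2.0 * (ll1 - ll0))
    return lrt, float(_chi2_dist.sf(lrt, df=1))


def quartile_threshold(counts, stringency):
    """Box-whisker outlier threshold with linear-interpolation quartiles."""
    x = sorted(counts)
    n = len(x)

    def quantile(q):
        h = q * (n - 1)
        lo = int(math.floor(h))
        hi = min(lo + 1, n - 1)
        return x[lo] + (h - lo) * (x[hi] - x[lo])

    q1, q3 = quantile(0.25), quantile(0.75)
    return q3 + stringency * (q3 - q1)
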