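"""Rank-based statistics used throughout the report.

Thin, uniform wrappers over scipy with the conventions fixed once: ties by
average rank, two-sided p-values, signed-rank zeros dropped, exact
small-sample signed-rank null, and an optional exact permutation p-value
for Spearman at very small n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats


@dataclass
class CorrelationResult:
    pair: str
    r_s: float
    n: int
    p: float
    method: str


@dataclass
class TestResult:
    test: str
    statistic: float
    p: float
    n: int
    note: str = ""


def spearman(
    x, y, pair: str = "", exact: bool = False
) -> CorrelationResult:
    """Spearman rank correlation with average-rank ties.

    The p-value uses the t approximation with n-2 degrees of freedom;
    with ``exact=True`` and n <= 10, the full permutation null of the rank
    correlation is enumerated instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(pair, float("nan"), n, float("nan"), "constant input")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    if exact:
        if n > 10:
            raise ValueError("exact permutation p only supported for n <= 10")
        count = 0
        total = 0
        ry_c = ry - ry.mean()
        rx_c = rx - rx.mean()
        denom = math.sqrt(float(np.sum(rx_c**2) * np.sum(ry_c**2)))
        obs = abs(float(np.sum(rx_c * ry_c)) / denom)
        for perm in permutations(range(n)):
            rp = rx_c[list(perm)]
            val = abs(float(np.sum(rp * ry_c)) / denom)
            count += val >= obs - 1e-12
            total += 1
        return CorrelationResult(pair, r, n, count / total, "exact permutation")
    if abs(r) >= 1.0:
        return CorrelationResult(pair, r, n, 0.0, "t approximation")
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return CorrelationResult(pair, r, n, p, "t approximation")


def signed_rank(x, y=None, exact_max_n: int = 25) -> TestResult:
    """Two-sided Wilcoxon signed-rank test; zero differences are dropped.

    Exact null for n <= ``exact_max_n`` nonzero differences without ties,
    tie-corrected normal approximation otherwise.
    """
    d = np.asarray(x, dtype=float) - (0.0 if y is None else np.asarray(y, dtype=float))
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return TestResult("signed_rank", float("nan"), float("nan"), 0,
                          "all differences zero")
    has_ties = len(np.unique(np.abs(d))) < n
    method = "exact" if (n <= exact_max_n and not has_ties) else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method,
                         correction=False)
    return TestResult("signed_rank", float(res.statistic), float(res.pvalue), n,
                      method)


def rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum test, tie-corrected normal approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return TestResult("rank_sum", float(res.statistic), float(res.pvalue),
                      len(x) + len(y), "normal approximation")


def paired_t(x, y) -> TestResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t, p = stats.ttest_rel(x, y)
    return TestResult("paired_t", float(t), float(p), len(x))


def welch_t(x, y) -> TestResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return TestResult("welch_t", float(t), float(p), len(x) + len(y))
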