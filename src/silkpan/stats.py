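"""Shared statistical kernels.

Everything downstream (gene/SV frequency scans, expression association,
fineness summaries) funnels through these few functions so that zero-handling
conventions and the multiple-testing procedure are defined in exactly one
place.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = [
    "TestResult",
    "fisher_exact_two_sided",
    "bh_fdr",
    "two_sample_t",
    "pearson_linear",
    "fold_change",
    "silk_fineness",
]


@dataclass
class TestResult:
    """Outcome of a single hypothesis test.

    ``q_value`` and ``fold_change`` are filled in by the scan routines that
    batch tests together; a bare kernel call leaves them ``None``.
    """

    statistic: float
    p_value: float
    q_value: float | None = None
    fold_change: float | None = None


def _validate_table(table) -> tuple[int, int, int, int]:
    arr = np.asarray(table)
    if arr.shape == (2, 2):
        a, b, c, d = int(arr[0, 0]), int(arr[0, 1]), int(arr[1, 0]), int(arr[1, 1])
    elif arr.shape == (4,):
        a, b, c, d = (int(v) for v in arr)
    else:
        raise ValueError("contingency table must be 2x2 or a flat 4-tuple")
    cells = (a, b, c, d)
    if not np.all(np.asarray(arr, dtype=float) == np.asarray(cells, dtype=float).reshape(arr.shape)):
        raise ValueError("contingency table entries must be integers")
    if any(v < 0 for v in cells):
        raise ValueError("contingency table entries must be non-negative")
    if sum(cells) == 0:
        raise ValueError("all-zero contingency table has no defined test")
    return a, b, c, d


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Uses the probability-mass rule: p is the total hypergeometric probability
    of all tables with the observed margins whose probability does not exceed
    that of the observed table.  The enumeration is carried out in exact
    integer arithmetic (the tables compared are rationals with a common
    denominator), so ties are decided exactly rather than to float precision.
    """
    a, b, c, d = _validate_table(table)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    # Numerators of the hypergeometric pmf over the common denominator C(n, c1).
    obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    total = 0
    for k in range(lo, hi + 1):
        w = math.comb(r1, k) * math.comb(r2, c1 - k)
        if w <= obs:
            total += w
    denom = math.comb(n, c1)
    return min(1.0, total / denom)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved.

    q_(i) = min_{j >= i} m * p_(j) / j over the ascending order statistics,
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def two_sample_t(group_a, group_b, welch: bool = False) -> TestResult:
    """Two-tailed two-sample t-test (pooled-variance Student by default).

    Degenerate convention: both groups constant with equal means -> t = 0,
    p = 1; both constant with different means -> p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("groups must contain finite values")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0.0 and vb == 0.0:
        if np.mean(a) == np.mean(b):
            return TestResult(statistic=0.0, p_value=1.0)
        sign = 1.0 if np.mean(a) > np.mean(b) else -1.0
        return TestResult(statistic=sign * math.inf, p_value=0.0)
    res = _sps.ttest_ind(a, b, equal_var=not welch)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue))


def pearson_linear(x, y) -> tuple[float, float, float]:
    """Pearson r, r^2, and the simple-regression F-test p-value.

    For one predictor the regression F test is equivalent to the two-sided
    t test on the slope, which is what :func:`scipy.stats.linregress` reports.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size or xv.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = _sps.linregress(xv, yv)
    r = float(res.rvalue)
    return r, r * r, float(res.pvalue)


def fold_change(freq_a: float, freq_b: float) -> float:
    """Ratio of the larger to the smaller frequency.

    Exactly one zero frequency gives +inf (a fixed difference passes any
    finite threshold); two zeros give 1 (no change, never significant).
    """
    if not (0.0 <= freq_a <= 1.0 and 0.0 <= freq_b <= 1.0):
        raise ValueError("frequencies must lie in [0, 1]")
    if freq_a == 0.0 and freq_b == 0.0:
        return 1.0
    if freq_a == 0.0 or freq_b == 0.0:
        return math.inf
    return max(freq_a, freq_b) / min(freq_a, freq_b)


def silk_fineness(weight_g: float, length_m: float) -> float:
    """Fiber fineness in dtex: 10,000 x weight (g) / length (m)."""
    if length_m <= 0:
        raise ValueError("silk length must be positive")
    if weight_g < 0:
        raise ValueError("silk weight must be non-negative")
    return 10_000.0 * weight_g / length_m
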