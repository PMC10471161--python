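"""Statistical primitives shared across the pipeline.

The multiple-comparison corrections (Bonferroni, Holm–Sidak) are implemented
here directly because per-bin significance families are the core inference of
the population analyses.  The classical tests (Fisher exact, Brown–Forsythe,
Mann–Whitney) are thin wrappers around :mod:`scipy.stats` with pinned
conventions so the backing implementation can be swapped without changing
results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "bonferroni_adjust",
    "holm_sidak_adjust",
    "fisher_exact_2x2",
    "robust_spread_test",
    "rank_sum_test",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test.

    Parameters
    ----------
    statistic
        Test statistic (odds ratio for the exact test, F for the spread test,
        U for the rank-sum test).
    p
        Two-sided p-value in [0, 1].
    method
        Short label of the procedure used.
    n
        Sample sizes the test consumed.
    adjusted_p
        Multiplicity-adjusted p-value, when a correction was applied.
    """

    statistic: float
    p: float
    method: str
    n: tuple[int, ...]
    adjusted_p: float | None = None

    def __post_init__(self) -> None:
        if np.isfinite(self.p) and not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p-value out of range: {self.p}")
        if self.adjusted_p is not None and np.isfinite(self.adjusted_p):
            if self.adjusted_p < self.p - 1e-12:
                raise ValueError("adjusted p-value below raw p-value")


def _as_pvals(pvals) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    with np.errstate(invalid="ignore"):
        bad = (p < 0) | (p > 1)
    if np.any(bad & np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def bonferroni_adjust(pvals, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjust p-values: ``min(1, p * m)``.

    ``m`` defaults to the number of (finite) p-values supplied; it may be
    larger when some tests in the family were unavailable, but never smaller
    than the number supplied.  NaN entries (unavailable tests) pass through.
    """
    p = _as_pvals(pvals)
    n_avail = int(np.isfinite(p).sum())
    if m is None:
        m = len(p)
    if m < 1:
        raise ValueError("family size m must be >= 1")
    if m < n_avail:
        raise ValueError(f"family size m={m} smaller than {n_avail} supplied p-values")
    return np.minimum(1.0, p * m)


def holm_sidak_adjust(pvals, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm–Sidak step-down adjustment.

    Sort raw p ascending; the i-th ordered p (0-based, family size m) receives
    ``1 - (1 - p_(i))**(m - i)``, made monotone by a running maximum and capped
    at 1.  Rejection walks down the sorted list while the adjusted value is
    below ``alpha`` and stops at the first failure.

    Returns ``(adjusted, reject)`` in the original order.  NaN entries are
    excluded from the family and come back NaN / not rejected.
    """
    p = _as_pvals(pvals)
    adjusted = np.full_like(p, np.nan)
    reject = np.zeros(p.shape, dtype=bool)
    finite = np.isfinite(p)
    m = int(finite.sum())
    if m == 0:
        return adjusted, reject
    idx = np.argsort(np.where(finite, p, np.inf), kind="stable")[:m]
    ordered = p[idx]
    k = m - np.arange(m)  # remaining hypotheses at each step
    with np.errstate(invalid="ignore"):
        step = 1.0 - (1.0 - ordered) ** k
    adj_sorted = np.minimum(1.0, np.maximum.accumulate(step))
    adjusted[idx] = adj_sorted
    # step-down: stop rejecting at the first adjusted value >= alpha
    passing = adj_sorted < alpha
    cutoff = np.argmin(passing) if not passing.all() else m
    reject[idx[:cutoff]] = True
    return adjusted, reject


def fisher_exact_2x2(table) -> TestResult:
    """Two-sided Fisher exact test on a 2x2 contingency table.

    Uses the probability-mass convention: the p-value sums hypergeometric
    probabilities of all tables (with the observed margins) no more probable
    than the observed one.  The conditional odds ratio is returned as the
    statistic.  A zero margin makes every table equally (un)informative and
    yields p = 1 with a warning.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t_float = np.asarray(table, dtype=float)
        if np.any(t_float < 0) or np.any(t_float != np.round(t_float)):
            raise ValueError("table entries must be nonnegative integers")
        t = t_float.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        warnings.warn("zero margin in 2x2 table; exact test is degenerate", stacklevel=2)
        return TestResult(statistic=np.nan, p=1.0, method="fisher_exact", n=tuple(t.sum(axis=1)))
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return TestResult(statistic=float(odds), p=float(p), method="fisher_exact", n=tuple(t.sum(axis=1)))


def robust_spread_test(*groups) -> TestResult:
    """Brown–Forsythe test for unequal spread.

    One-way ANOVA on absolute deviations from each group's median — robust to
    non-normality, the standard choice for comparing latency-distribution
    variability.  Accepts either separate array arguments or a single list of
    arrays.
    """
    if len(groups) == 1 and not np.isscalar(groups[0][0]):
        groups = tuple(groups[0])
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    for g in arrs:
        if g.size < 2:
            raise ValueError("each group needs n >= 2")
    if all(np.ptp(g) == 0 for g in arrs):
        # all groups constant: deviations identically zero, no spread difference
        return TestResult(statistic=0.0, p=1.0, method="brown_forsythe",
                          n=tuple(g.size for g in arrs))
    stat, p = sps.levene(*arrs, center="median")
    return TestResult(statistic=float(stat), p=float(p), method="brown_forsythe",
                      n=tuple(g.size for g in arrs))


def rank_sum_test(a, b) -> TestResult:
    """Two-sided Mann–Whitney U test with tie handling.

    Exact null distribution for small tie-free samples, normal approximation
    with tie correction otherwise (scipy's ``method='auto'``).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return TestResult(statistic=float(res.statistic), p=float(res.pvalue),
                      method="mann_whitney", n=(a.size, b.size))
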