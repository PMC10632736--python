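"""Two-sample tests and the sample-size-driven test-selection rule.

The heterotypic-vs-homotypic comparison uses Student's t (equal variances),
Welch's t (unequal variances) or the Mann-Whitney U test depending on group
sizes: when both groups exceed 30 observations a parametric test is chosen,
routed by a two-sided F test on the variance ratio; otherwise the rank test
is used. An optional Shapiro-Wilk gate can force the rank test when either
group departs from normality.

The t and U statistics are computed from their closed forms (pooled-SD
Student t, Welch t with Satterthwaite degrees of freedom, U = min(U1, U2)
from rank sums with mid-ranks for ties); p-values come from the scipy
distribution functions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestSelection",
    "f_test_equal_var",
    "student_t",
    "welch_t",
    "mann_whitney_u",
    "shapiro_wilk",
    "choose_test",
    "run_selected_test",
    "log_ratio",
    "bh_fdr",
]


@dataclass(frozen=True)
class TestSelection:
    """Which two-sample test applies to a pair of groups, and why."""

    test: str  # student_t | welch_t | mann_whitney
    reason: str  # both_n_gt_30_equal_var | both_n_gt_30_unequal_var | small_sample | non_normal
    normality_checked: bool = False


def _as1d(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if a.size == 0:
        raise ValueError("empty sample")
    return a


def f_test_equal_var(a, b, alpha: float = 0.05) -> bool:
    """Two-sided F test of equal variances; True = no evidence of inequality."""
    a, b = _as1d(a), _as1d(b)
    if a.size < 2 or b.size < 2:
        raise ValueError("F test needs at least 2 observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        warnings.warn("both variances zero; treating as equal", stacklevel=2)
        return True
    if va == 0 or vb == 0:
        return False
    f = va / vb
    cdf = sps.f.cdf(f, a.size - 1, b.size - 1)
    p = 2 * min(cdf, 1 - cdf)
    return p > alpha


def student_t(a, b) -> tuple[float, float]:
    """Pooled-variance two-sample t test (two-sided).

    t = (mean(a) - mean(b)) / (sp * sqrt(1/n1 + 1/n2)) with the pooled
    standard deviation sp^2 = ((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2).
    """
    a, b = _as1d(a), _as1d(b)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("t test needs at least 2 observations per group")
    s1sq, s2sq = a.var(ddof=1), b.var(ddof=1)
    sp = np.sqrt(((n1 - 1) * s1sq + (n2 - 1) * s2sq) / (n1 + n2 - 2))
    diff = a.mean() - b.mean()
    if sp == 0:
        if diff == 0:
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means")
    t = diff / (sp * np.sqrt(1.0 / n1 + 1.0 / n2))
    p = 2 * sps.t.sf(abs(t), n1 + n2 - 2)
    return float(t), float(p)


def welch_t(a, b) -> tuple[float, float]:
    """Welch's unequal-variance t test (two-sided), Satterthwaite df."""
    a, b = _as1d(a), _as1d(b)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("t test needs at least 2 observations per group")
    v1, v2 = a.var(ddof=1) / n1, b.var(ddof=1) / n2
    diff = a.mean() - b.mean()
    if v1 + v2 == 0:
        if diff == 0:
            return 0.0, 1.0
        raise ValueError("zero variances with unequal means")
    t = diff / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2 * sps.t.sf(abs(t), df)
    return float(t), float(p)


# exact enumeration is affordable only for small totals; beyond this the
# tie/continuity-corrected normal approximation is used
_EXACT_MAX_TOTAL = 25
_EXACT_MIN_SMALL = 8


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Mann-Whitney U test (two-sided) with mid-ranks for ties.

    U = min(U1, U2) where U_i = n1*n2 + n_i(n_i+1)/2 - R_i and R_i is the
    rank sum of group i in the pooled sample. The p-value is exact (no ties,
    small samples) or a normal approximation with tie and continuity
    correction.
    """
    a, b = _as1d(a), _as1d(b)
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    r2 = ranks[n1:].sum()
    u1 = n1 * n2 + n1 * (n1 + 1) / 2 - r1
    u2 = n1 * n2 + n2 * (n2 + 1) / 2 - r2
    u = min(u1, u2)

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool(np.any(tie_counts > 1))
    if (
        not has_ties
        and min(n1, n2) < _EXACT_MIN_SMALL
        and n1 + n2 <= _EXACT_MAX_TOTAL
    ):
        p = _exact_u_pvalue(int(round(u)), n1, n2)
    else:
        n = n1 + n2
        mu = n1 * n2 / 2.0
        tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1)) if n > 1 else 0.0
        sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
        if sigma2 <= 0:  # all values identical
            return float(u), 1.0
        z = (u - mu + 0.5) / np.sqrt(sigma2)  # u <= mu by construction
        p = min(1.0, 2 * sps.norm.cdf(z))
    return float(u), float(p)


def _exact_u_pvalue(u: int, n1: int, n2: int) -> float:
    """Exact two-sided p by enumerating the null rank-sum distribution.

    dp[k, w] counts k-subsets of the pooled ranks 1..N with rank sum w;
    U1 <= u corresponds to R1 >= n1*n2 + n1(n1+1)/2 - u, and the U
    distribution is symmetric so min(U1, U2) may be used directly.
    """
    n = n1 + n2
    wmax = n * (n + 1) // 2
    dp = np.zeros((n1 + 1, wmax + 1), dtype=float)
    dp[0, 0] = 1.0
    for i in range(1, n + 1):
        for k in range(min(i, n1), 0, -1):
            dp[k, i:] += dp[k - 1, :-i]
    dist = dp[n1]
    thresh = n1 * n2 + n1 * (n1 + 1) // 2 - u
    cdf = dist[thresh:].sum() / dist.sum()
    return min(1.0, 2 * cdf)


def shapiro_wilk(a, alpha: float = 0.05) -> bool:
    """Shapiro-Wilk normality verdict; True = consistent with normal."""
    a = _as1d(a)
    if a.size < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3")
    if np.ptp(a) == 0:
        warnings.warn("constant sample; reporting non-normal", stacklevel=2)
        return False
    n = a.size
    if n > 5000:
        a = a[:5000]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = sps.shapiro(a)
    return bool(p > alpha)


def choose_test(a, b, use_normality: bool = False, alpha_var: float = 0.05) -> TestSelection:
    """Select the two-sample test from group sizes (and optionally normality).

    Both groups strictly larger than 30: parametric, routed to Student's or
    Welch's t by the F test. Otherwise (or if the optional normality gate
    fails): Mann-Whitney U.
    """
    a, b = _as1d(a), _as1d(b)
    if min(a.size, b.size) <= 30:
        return TestSelection("mann_whitney", "small_sample", use_normality)
    if use_normality and not (shapiro_wilk(a) and shapiro_wilk(b)):
        return TestSelection("mann_whitney", "non_normal", True)
    if f_test_equal_var(a, b, alpha=alpha_var):
        return TestSelection("student_t", "both_n_gt_30_equal_var", use_normality)
    return TestSelection("welch_t", "both_n_gt_30_unequal_var", use_normality)


def run_selected_test(a, b, selection: TestSelection) -> tuple[float, float]:
    """Apply the selected test, returning (statistic, two-sided p)."""
    fn = {"student_t": student_t, "welch_t": welch_t, "mann_whitney": mann_whitney_u}[
        selection.test
    ]
    return fn(a, b)


def log_ratio(het, homo, pseudo: float = 1e-9, base: float = 2.0) -> float:
    """log_base of the ratio of group means on the normalized scale."""
    het, homo = _as1d(het), _as1d(homo)
    return float(
        (np.log(het.mean() + pseudo) - np.log(homo.mean() + pseudo)) / np.log(base)
    )


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
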