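"""Group-comparison statistics: t-tests, chi-square, Hedges' g, permutation p.

The effect-size machinery mirrors a case-control comparison battery:
independent-samples t-test from summary statistics, 2x2 chi-square for
categorical composition, small-sample bias-corrected standardized mean
difference (Hedges' g) with a normal-approximation 95% CI, and a two-sided
label-permutation test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sst

__all__ = [
    "GroupComparison",
    "ttest_from_summary",
    "chi_square_2x2",
    "hedges_g",
    "permutation_test",
    "paired_permutation_test",
    "compare_groups",
]


@dataclass
class GroupComparison:
    """One row of a group-difference table."""

    measure: str
    mean_difference: float
    hedges_g: float
    ci95_low: float
    ci95_high: float
    p_value: float
    method: str  # "parametric" or "permutation"
    n1: int
    n2: int
    n_permutations: int = 0
    seed: int | None = None

    def __post_init__(self):
        if not (self.ci95_low <= self.hedges_g <= self.ci95_high):
            raise ValueError("effect size outside its own confidence interval")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def ttest_from_summary(m1: float, sd1: float, n1: int,
                       m2: float, sd2: float, n2: int,
                       variant: str = "welch"):
    """Two-sided independent-samples t-test from group summaries."""
    if variant not in ("welch", "pooled"):
        raise ValueError("variant must be 'welch' or 'pooled'")
    res = sst.ttest_ind_from_stats(m1, sd1, n1, m2, sd2, n2,
                                   equal_var=(variant == "pooled"))
    return float(res.statistic), float(res.pvalue)


def chi_square_2x2(table, continuity: bool = False):
    """Pearson chi-square on a 2x2 contingency table (optional Yates)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    total = t.sum()
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    expected = np.outer(row, col) / total
    diff = np.abs(t - expected)
    if continuity:
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float((diff ** 2 / expected).sum())
    p = float(sst.chi2.sf(chi2, df=1))
    return chi2, p


def _hedges_J(df: float) -> float:
    # Hedges' small-sample correction factor, J = 1 - 3/(4 df - 1)
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def hedges_g(x, y):
    """Bias-corrected standardized mean difference with 95% CI.

    g = J(df) * (mean_x - mean_y) / s_pooled, df = n1 + n2 - 2.  The CI uses
    the normal-approximation variance
    var(g) = J^2 * ((n1+n2)/(n1*n2) + d^2 / (2*df)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per group")
    df = n1 + n2 - 2
    s_pooled = math.sqrt(((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1))
                         / df)
    J = _hedges_J(df)
    if s_pooled == 0.0:
        return 0.0, (0.0, 0.0)
    d = (x.mean() - y.mean()) / s_pooled
    g = J * d
    var_g = J ** 2 * ((n1 + n2) / (n1 * n2) + d ** 2 / (2.0 * df))
    half = 1.959963984540054 * math.sqrt(var_g)
    return float(g), (float(g - half), float(g + half))


def _mean_diff(x, y):
    return float(np.mean(x) - np.mean(y))


def permutation_test(x, y, statistic=None, n_perm: int = 5000,
                     seed: int = 0, exhaustive_limit: int = 12):
    """Two-sided label-permutation p-value.

    p is the proportion of label assignments whose |statistic| is at least
    the observed one, counting the identity assignment in both numerator and
    denominator.  When the number of distinct splits is at most
    ``exhaustive_limit`` choose ``n1``, all splits are enumerated exactly;
    otherwise ``n_perm`` random permutations are drawn.
    """
    statistic = statistic or _mean_diff
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1 = len(x)
    pooled = np.concatenate([x, y])
    n = len(pooled)
    observed = abs(statistic(x, y))
    if n <= exhaustive_limit:
        count = 0
        total = 0
        idx_all = frozenset(range(n))
        for comb in combinations(range(n), n1):
            sel = np.asarray(comb, dtype=int)
            rest = np.asarray(sorted(idx_all - set(comb)), dtype=int)
            stat = abs(statistic(pooled[sel], pooled[rest]))
            if stat >= observed - 1e-12:
                count += 1
            total += 1
        return count / total
    rng = np.random.default_rng(seed)
    count = 1  # identity permutation
    for _ in range(n_perm):
        perm = rng.permutation(n)
        stat = abs(statistic(pooled[perm[:n1]], pooled[perm[n1:]]))
        if stat >= observed - 1e-12:
            count += 1
    return count / (n_perm + 1)


def paired_permutation_test(x, y, n_perm: int = 5000, seed: int = 0,
                            exhaustive_limit: int = 14):
    """Two-sided sign-flip permutation p for paired samples.

    The statistic is the mean paired difference; under the null the sign of
    each pair's difference is exchangeable.  All 2^n sign patterns are
    enumerated when n <= ``exhaustive_limit`` (exact p), otherwise ``n_perm``
    random patterns are drawn with the identity counted in both numerator and
    denominator.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    n = len(d)
    observed = abs(d.mean())
    if n <= exhaustive_limit:
        count = 0
        for bits in range(2 ** n):
            signs = np.fromiter(((1.0 if bits >> k & 1 else -1.0)
                                 for k in range(n)), dtype=float, count=n)
            if abs((signs * d).mean()) >= observed - 1e-12:
                count += 1
        return count / 2 ** n
    rng = np.random.default_rng(seed)
    count = 1
    for _ in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n)
        if abs((signs * d).mean()) >= observed - 1e-12:
            count += 1
    return count / (n_perm + 1)


def compare_groups(x, y, measure: str, method: str = "permutation",
                   n_perm: int = 5000, seed: int = 0) -> GroupComparison:
    """Full comparison row: mean difference, Hedges' g + CI, p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    g, (lo, hi) = hedges_g(x, y)
    if method == "permutation":
        p = permutation_test(x, y, n_perm=n_perm, seed=seed)
        nper = n_perm
    elif method == "parametric":
        _, p = sst.ttest_ind(x, y, equal_var=False)
        nper = 0
    else:
        raise ValueError("method must be 'permutation' or 'parametric'")
    return GroupComparison(
        measure=measure, mean_difference=_mean_diff(x, y), hedges_g=g,
        ci95_low=lo, ci95_high=hi, p_value=float(p), method=method,
        n1=len(x), n2=len(y), n_permutations=nper, seed=seed)
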