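"""Two-sample statistical kernel used by every analysis stage.

Thin, convention-fixing wrappers over scipy.stats that return a uniform
:class:`TestResult` and pin down the degenerate cases scipy leaves as NaN
(identical constant samples, zero-variance paired differences, a single
shared value). Conventions:

* Mann-Whitney U is the statistic of the *first* sample (greater-than
  count plus half the ties), exact enumeration when feasible without ties,
  normal approximation with tie and continuity correction otherwise.
* All tests are two-sided by default; direction is interpreted by callers.
* The two-sample Cramér-von Mises p-value is asymptotic when both samples
  have at least ``cvm_exact_below`` observations, and a seeded permutation
  p otherwise.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .core import TestResult

_ALTS = {"two_sided": "two-sided", "greater": "greater", "less": "less"}


def _as_array(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if a.size == 0:
        raise ValueError(f"{name} must be nonempty")
    return a


def welch_t(x, y, alternative: str = "two_sided") -> TestResult:
    """Welch's unequal-variance t-test with Welch-Satterthwaite df."""
    x = _as_array(x, "x")
    y = _as_array(y, "y")
    if len(x) < 2 or len(y) < 2:
        raise ValueError("welch_t needs at least 2 observations per sample")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return TestResult(0.0, 1.0, "welch_t", df=float(len(x) + len(y) - 2),
                              alternative=alternative)
        # constant samples with different means: infinitely strong evidence
        sign = np.sign(x.mean() - y.mean())
        p = 0.0 if alternative == "two_sided" else (
            0.0 if (alternative == "greater") == (sign > 0) else 1.0
        )
        return TestResult(float(sign * np.inf), p, "welch_t (degenerate)",
                          df=float(len(x) + len(y) - 2), alternative=alternative)
    res = sps.ttest_ind(x, y, equal_var=False, alternative=_ALTS[alternative])
    return TestResult(float(res.statistic), float(res.pvalue), "welch_t",
                      df=float(res.df), alternative=alternative)


def mann_whitney_u(x, y, alternative: str = "two_sided",
                   exact_max_product: int = 10_000) -> TestResult:
    """Mann-Whitney U of the first sample.

    Exact p by enumeration when ``len(x) * len(y) <= exact_max_product`` and
    the data are tie-free; otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = _as_array(x, "x")
    y = _as_array(y, "y")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = (
        "exact" if (len(x) * len(y) <= exact_max_product and not has_ties)
        else "asymptotic"
    )
    res = sps.mannwhitneyu(x, y, alternative=_ALTS[alternative], method=method)
    return TestResult(float(res.statistic), float(res.pvalue),
                      f"mann_whitney_u ({method})", alternative=alternative)


def ks_two_sample(x, y) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test, asymptotic p."""
    x = _as_array(x, "x")
    y = _as_array(y, "y")
    res = sps.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return TestResult(float(res.statistic), float(min(res.pvalue, 1.0)),
                      "ks_two_sample (asymptotic)")


def _cvm_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Anderson's rank form of the two-sample Cramér-von Mises statistic."""
    nx, ny = len(x), len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    rx = np.sort(ranks[:nx])
    ry = np.sort(ranks[nx:])
    u = nx * np.sum((rx - np.arange(1, nx + 1)) ** 2)
    u += ny * np.sum((ry - np.arange(1, ny + 1)) ** 2)
    n = nx + ny
    return float(u / (nx * ny * n) - (4 * nx * ny - 1) / (6 * n))


def cramer_von_mises_two(x, y, cvm_exact_below: int = 10,
                         n_permutations: int = 10_000,
                         seed: int = 0,
                         max_pooled: int = 2_000) -> TestResult:
    """Two-sample Cramér-von Mises test (Anderson's rank form).

    Asymptotic p when both samples have >= ``cvm_exact_below`` observations;
    otherwise a seeded permutation p with ``n_permutations`` draws. For the
    permutation branch, a sample larger than ``max_pooled`` minus the other
    sample's size is first reduced to a seeded random subsample: the
    permutation null is exchangeable either way and the cap keeps the
    resampling tractable against very large empirical backgrounds.
    """
    x = _as_array(x, "x")
    y = _as_array(y, "y")
    if min(len(x), len(y)) >= cvm_exact_below:
        res = sps.cramervonmises_2samp(x, y, method="asymptotic")
        return TestResult(float(res.statistic),
                          float(min(max(res.pvalue, 0.0), 1.0)),
                          "cramer_von_mises_two (asymptotic)")
    rng = np.random.default_rng(seed)
    if len(y) > max_pooled - len(x):
        y = rng.choice(y, size=max_pooled - len(x), replace=False)
    if len(x) > max_pooled - len(y):
        x = rng.choice(x, size=max_pooled - len(y), replace=False)
    t_obs = _cvm_statistic(x, y)
    pooled = np.concatenate([x, y])
    nx = len(x)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        if _cvm_statistic(perm[:nx], perm[nx:]) >= t_obs:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return TestResult(t_obs, float(p), "cramer_von_mises_two (permutation)")


def paired_t(x, y, alternative: str = "two_sided") -> TestResult:
    """Paired t-test: one-sample t on differences x - y, df = n - 1."""
    x = _as_array(x, "x")
    y = _as_array(y, "y")
    if len(x) != len(y):
        raise ValueError("paired_t requires samples of equal length")
    if len(x) < 2:
        raise ValueError("paired_t needs at least 2 pairs")
    d = x - y
    df = float(len(d) - 1)
    if d.var(ddof=1) == 0.0:
        if d[0] == 0.0:
            return TestResult(0.0, 1.0, "paired_t", df=df, alternative=alternative)
        sign = np.sign(d[0])
        p = 0.0 if alternative == "two_sided" else (
            0.0 if (alternative == "greater") == (sign > 0) else 1.0
        )
        # constant nonzero difference: t unbounded, p reported at its bound
        return TestResult(float(sign * np.inf), p, "paired_t (degenerate)",
                          df=df, alternative=alternative)
    res = sps.ttest_rel(x, y, alternative=_ALTS[alternative])
    return TestResult(float(res.statistic), float(res.pvalue), "paired_t",
                      df=df, alternative=alternative)


def empirical_quantile(values, q: float) -> float:
    """Order-statistic quantile with type-7 (linear) interpolation."""
    values = _as_array(values, "values")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"quantile level {q} outside [0, 1]")
    return float(np.quantile(values, q, method="linear"))
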