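"""Fold-change distribution statistics and hypothesis tests.

The comparisons these functions support: are lncRNA log fold-change
distributions right-skewed relative to coding genes (sample skewness,
D'Agostino K-squared omnibus test), do the two classes differ globally
(two-sample Kolmogorov-Smirnov, Student's t), and are up- vs down-regulated
proportions unequal (two-proportion chi-squared, Fisher's exact test)?

Statistics are delegated to scipy.stats; the wrappers pin down the exact
conventions used (biased moment skewness g1, pooled-variance t by default,
two-sided Fisher by hypergeometric probability ordering) and return a
uniform :class:`TestResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: int | None = None
    table: tuple | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class SkewnessResult:
    g1: float
    z_g1: float
    k2: float
    p_value: float


def sample_skewness(x, adjusted: bool = False) -> float:
    """Moment-based sample skewness g1 = m3 / m2^(3/2).

    ``adjusted=True`` returns the bias-adjusted G1 instead.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need n >= 3 for skewness")
    if np.var(x) == 0:
        raise ValueError("zero variance: skewness undefined")
    return float(stats.skew(x, bias=not adjusted))


def dagostino_k2(x) -> SkewnessResult:
    """D'Agostino's K-squared omnibus normality test.

    Combines the skewness transformation Z(g1) with the Anscombe-Glynn
    kurtosis transformation Z(g2): K2 = Z(g1)^2 + Z(g2)^2, referred to a
    chi-squared distribution with 2 df.  Requires n >= 20 for the
    transformations to be valid.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 20:
        raise ValueError(
            f"D'Agostino K-squared requires n >= 20 (validity guard), got {x.size}")
    z_g1 = float(stats.skewtest(x).statistic)
    z_g2 = float(stats.kurtosistest(x).statistic)
    k2, p = stats.normaltest(x)
    return SkewnessResult(g1=sample_skewness(x), z_g1=z_g1,
                          k2=float(k2), p_value=float(p))


def skewness_z_test(x) -> TestResult:
    """Skewness-only normal-deviate test (the Z(g1) component of K-squared)."""
    x = np.asarray(x, dtype=float)
    res = stats.skewtest(x)
    return TestResult(float(res.statistic), float(res.pvalue),
                      method="dagostino_skewness_z")


def ks_two_sample(x, y) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test (asymptotic two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(x, y, alternative="two-sided", method="asymp")
    return TestResult(float(res.statistic), float(res.pvalue),
                      method="ks_two_sample")


def chi2_two_proportions(x1: int, n1: int, x2: int, n2: int,
                         yates: bool = False) -> TestResult:
    """Chi-squared test that two proportions x1/n1 and x2/n2 are equal.

    Builds the 2x2 table [[x1, n1-x1], [x2, n2-x2]] and applies the df=1
    chi-squared test, optionally with Yates' continuity correction.  An
    expected cell below 1 is recorded as a warning on the result, not an
    error.
    """
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("need 0 <= x_i <= n_i")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    warnings = []
    if table.sum() == 0 or 0 in table.sum(axis=0) or 0 in table.sum(axis=1):
        raise ValueError("degenerate margin in 2x2 table")
    chi2, p, df, expected = stats.chi2_contingency(table, correction=yates)
    if (expected < 1).any():
        warnings.append("expected cell count < 1; chi-squared approximation poor")
    return TestResult(float(chi2), float(p), method="chi2_two_proportions",
                      df=int(df), table=tuple(map(tuple, table.astype(int))),
                      warnings=warnings)


def fisher_exact(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 count table.

    The two-sided p-value sums, with margins fixed, the probabilities of all
    tables no more likely than the observed one (the conventional
    definition).
    """
    table = np.asarray(table, dtype=int)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    if 0 in table.sum(axis=0) or 0 in table.sum(axis=1):
        raise ValueError("degenerate margin in 2x2 table")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return TestResult(float(odds), float(p), method="fisher_exact",
                      table=tuple(map(tuple, table)))


def student_t_two_sample(x, y, equal_variance: bool = True) -> TestResult:
    """Two-sample t test; pooled variance by default (Student's), Welch by flag."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need n >= 2 in each group")
    if equal_variance and np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValueError("zero pooled variance")
    res = stats.ttest_ind(x, y, equal_var=equal_variance)
    method = "student_t" if equal_variance else "welch_t"
    return TestResult(float(res.statistic), float(res.pvalue), method=method,
                      df=int(x.size + y.size - 2) if equal_variance else None)


def pearson_correlation(x, y) -> TestResult:
    """Pearson correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired vectors must have equal length")
    if x.size < 3:
        raise ValueError("need >= 3 pairs for a correlation test")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in one of the vectors")
    res = stats.pearsonr(x, y)
    return TestResult(float(res.statistic), float(res.pvalue),
                      method="pearson_r")


def density_and_ecdf(values, bandwidth_rule: str = "silverman",
                     grid=None) -> tuple[np.ndarray, np.ndarray,
                                         np.ndarray, np.ndarray]:
    """Gaussian kernel density and empirical CDF of a sample.

    Returns ``(grid, density, sorted_values, ecdf)`` where ``density`` is the
    Gaussian KDE (Silverman bandwidth by default) evaluated on ``grid`` and
    ``ecdf[i]`` is the right-continuous empirical CDF at ``sorted_values[i]``
    (so the last entry is exactly 1).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need n >= 2")
    if grid is None:
        lo, hi = values.min(), values.max()
        pad = 4 * values.std() + 1e-9
        grid = np.linspace(lo - pad, hi + pad, 512)
    else:
        grid = np.asarray(grid, dtype=float)
    if np.var(values) == 0:
        # point mass: a narrow Gaussian centred on the value
        sd = max(abs(values[0]) * 1e-3, 1e-3)
        density = stats.norm.pdf(grid, loc=values[0], scale=sd)
    else:
        density = stats.gaussian_kde(values, bw_method=bandwidth_rule)(grid)
    xs = np.sort(values)
    ecdf = np.arange(1, xs.size + 1) / xs.size
    return grid, density, xs, ecdf
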