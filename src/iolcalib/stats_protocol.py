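"""Statistical battery of the AL-correction study.

Normality screening (exact one-sample Kolmogorov-Smirnov), one-sample and
paired t-tests, Friedman's test with Bonferroni-adjusted rank post-hocs for
comparing absolute errors across AL options, Bland-Altman agreement, and the
paired-design sample-size calculation on the noncentral t distribution.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors as _lilliefors

__all__ = [
    "TestResult",
    "BlandAltman",
    "PowerSpec",
    "paired_t",
    "one_sample_t",
    "friedman_bonferroni",
    "ks_normality",
    "bland_altman",
    "paired_t_power",
    "paired_t_sample_size",
]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    df: Optional[float] = None
    method: str = ""

    def __post_init__(self) -> None:
        if not -1e-12 <= self.p_value <= 1 + 1e-12:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        self.p_value = float(min(max(self.p_value, 0.0), 1.0))


@dataclass
class BlandAltman:
    """Bias and 95% limits of agreement of paired differences (x - y)."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int


@dataclass
class PowerSpec:
    """Design of the paired t-test sample-size calculation."""

    delta: float  # detectable mean difference (D)
    sigma: float  # within-subject SD of the differences (D)
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if self.delta <= 0 or self.sigma <= 0:
            raise ValueError("delta and sigma must be positive")
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must lie in (0, 1)")


def _paired_diffs(x, y) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("paired test requires n >= 2")
    return x - y


def paired_t(x, y) -> TestResult:
    """Two-sided paired Student t-test; df = n - 1."""
    d = _paired_diffs(x, y)
    if np.allclose(d, d[0]) and not np.allclose(d, 0.0):
        raise ValueError("constant nonzero differences: paired t-test undefined (sd = 0)")
    if np.allclose(d, 0.0):
        return TestResult(0.0, 1.0, df=d.size - 1, method="paired t-test")
    stat, p = stats.ttest_rel(x, y)
    return TestResult(float(stat), float(p), df=d.size - 1, method="paired t-test")


def one_sample_t(x, mu: float = 0.0) -> TestResult:
    """Two-sided one-sample Student t-test against ``mu``; df = n - 1."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("one-sample test requires n >= 2")
    if x.std(ddof=1) == 0:
        if np.allclose(x, mu):
            return TestResult(0.0, 1.0, df=x.size - 1, method="one-sample t-test")
        raise ValueError("zero variance: one-sample t-test undefined")
    stat, p = stats.ttest_1samp(x, mu)
    return TestResult(float(stat), float(p), df=x.size - 1, method="one-sample t-test")


def friedman_bonferroni(matrix) -> Tuple[TestResult, Dict[Tuple[int, int], float]]:
    """Friedman's rank test across conditions plus Bonferroni post-hocs.

    ``matrix`` is n subjects x k conditions (absolute errors in the study
    protocol).  Within-subject ranks use average ranks for ties and the
    tie-corrected chi-square statistic.  Pairwise comparisons use the
    normal approximation of the mean-rank difference, with p-values
    multiplied by the number of pairs (capped at 1).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("matrix must be 2-D (subjects x conditions)")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("Friedman test requires n >= 2 subjects and k >= 2 conditions")
    if np.any(~np.isfinite(m)):
        raise ValueError("missing or non-finite cells are not allowed")

    ranks = np.apply_along_axis(stats.rankdata, 1, m)
    col_sums = ranks.sum(axis=0)
    # tie-robust form: (k-1) * sum (Rj - n(k+1)/2)^2 / (sum r_ij^2 - n k (k+1)^2 / 4)
    num = (k - 1) * float(((col_sums - n * (k + 1) / 2.0) ** 2).sum())
    den = float((ranks**2).sum()) - n * k * (k + 1) ** 2 / 4.0
    if den <= 0:  # every row fully tied
        overall = TestResult(0.0, 1.0, df=k - 1, method="Friedman chi-square")
        pairwise = {pair: 1.0 for pair in itertools.combinations(range(k), 2)}
        return overall, pairwise
    chi2 = num / den
    p = float(stats.chi2.sf(chi2, k - 1))
    overall = TestResult(float(chi2), p, df=k - 1, method="Friedman chi-square")

    mean_ranks = col_sums / n
    se = math.sqrt(k * (k + 1) / (6.0 * n))
    pairs = list(itertools.combinations(range(k), 2))
    pairwise: Dict[Tuple[int, int], float] = {}
    for i, j in pairs:
        z = abs(mean_ranks[i] - mean_ranks[j]) / se
        raw = 2.0 * float(stats.norm.sf(z))
        pairwise[(i, j)] = min(1.0, raw * len(pairs))
    return overall, pairwise


def ks_normality(x, lilliefors: bool = False) -> TestResult:
    """One-sample Kolmogorov-Smirnov normality test with estimated parameters.

    Default: exact small-sample KS p-value against a normal with the sample
    mean and SD (the nominal protocol).  Because the parameters are
    estimated from the same sample, this p-value is conservative (inflated);
    ``lilliefors=True`` switches to the Lilliefors-corrected variant.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise ValueError("normality screen requires n >= 5")
    if lilliefors:
        stat, p = _lilliefors(x, dist="norm")
        return TestResult(float(stat), float(p), method="Lilliefors KS")
    mean, sd = x.mean(), x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: normality test undefined")
    res = stats.kstest(x, "norm", args=(mean, sd), method="exact")
    return TestResult(float(res.statistic), float(res.pvalue), method="exact one-sample KS")


def bland_altman(x, y) -> BlandAltman:
    """Bland-Altman agreement of paired measurements.

    Differences are x - y; limits of agreement are bias +/- 1.96 * SD of the
    differences (the conventional normal quantile, not a t quantile).
    """
    d = _paired_diffs(x, y)
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        n=int(d.size),
    )


def paired_t_power(n: int, spec: PowerSpec) -> float:
    """Power of the two-sided paired t-test at sample size ``n``."""
    if n < 2:
        return 0.0
    df = n - 1
    t_crit = stats.t.ppf(1 - spec.alpha / 2.0, df)
    ncp = spec.delta / spec.sigma * math.sqrt(n)
    return float(1 - stats.nct.cdf(t_crit, df, ncp) + stats.nct.cdf(-t_crit, df, ncp))


def paired_t_sample_size(spec: PowerSpec, max_n: int = 10_000_000) -> int:
    """Smallest n reaching the requested power for a two-sided paired t-test.

    Searches upward from the normal-approximation lower bound
    ceil(((z_{1-alpha/2} + z_{power}) * sigma / delta)^2), evaluating the
    exact noncentral-t power at each integer n.
    """
    z_bound = math.ceil(
        ((stats.norm.ppf(1 - spec.alpha / 2.0) + stats.norm.ppf(spec.power)) * spec.sigma / spec.delta) ** 2
    )
    n = max(2, z_bound)
    while n <= max_n:
        if paired_t_power(n, spec) >= spec.power:
            return n
        n += 1
    raise ValueError(f"requested power not reachable with n <= {max_n}")
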