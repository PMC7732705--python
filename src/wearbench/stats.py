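"""Statistical layer: descriptives, paired Wilcoxon tests, Bonferroni,
single-measures ICC, and the a-priori correlation power analysis.

Conventions (stated because they matter for reproducibility):

* quartiles use linear interpolation between order statistics;
* the Wilcoxon statistic is W = min(W+, W-); zero differences are dropped by
  default ("wilcox" policy) with Pratt handling available; exact p-values
  (by sign-assignment enumeration) are used for n <= 25 without ties,
  otherwise a normal approximation with continuity and tie correction;
* the ICC is the two-way, absolute-agreement, single-measures form ICC(A,1).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedSample",
    "TestResult",
    "ICCResult",
    "median_iqr",
    "wilcoxon_signed_rank",
    "bonferroni_alpha",
    "icc_single",
    "sample_size_for_correlation",
    "correlation_power",
]


@dataclass(frozen=True)
class PairedSample:
    """Paired per-surface values for one outcome metric."""

    ids: tuple
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if len(self.ids) != len(x) or len(x) != len(y):
            raise ValueError("ids, x, y must have equal lengths")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("surface ids must be unique")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @classmethod
    def from_arrays(cls, x, y, ids=None) -> "PairedSample":
        x = np.asarray(x, dtype=float)
        if ids is None:
            ids = tuple(range(len(x)))
        return cls(tuple(ids), x, np.asarray(y, dtype=float))

    def differences(self) -> np.ndarray:
        return self.y - self.x


@dataclass(frozen=True)
class TestResult:
    statistic: float  # W = min(W+, W-)
    p_value: float
    n_effective: int
    method: str  # exact | normal_approx | degenerate
    significant_at: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value out of [0, 1]")
        if self.statistic < 0:
            raise ValueError("W must be >= 0")


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci_lower: float
    ci_upper: float
    model: str = "two-way, absolute agreement, single measures (ICC(A,1))"
    degenerate: bool = False

    def __post_init__(self):
        if not self.degenerate:
            if not (self.ci_lower - 1e-9 <= self.estimate <= self.ci_upper + 1e-9):
                raise ValueError("ICC estimate outside its CI")


# --------------------------------------------------------------------------
# Descriptives
# --------------------------------------------------------------------------

def median_iqr(values) -> tuple[float, float, float]:
    """(median, q1, q3) with linear-interpolation quartiles."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return float(med), float(q1), float(q3)


# --------------------------------------------------------------------------
# Wilcoxon signed-rank
# --------------------------------------------------------------------------

def _signed_rank_distribution(ranks: np.ndarray) -> np.ndarray:
    """Null pmf of W+ over all 2^n sign assignments, via the counting DP.

    ``ranks`` may contain midranks; they are doubled to stay integral, and
    the returned pmf is over W+ * 2.
    """
    r2 = np.round(ranks * 2).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts / counts.sum()


def wilcoxon_signed_rank(sample: PairedSample, zero_policy: str = "wilcox") -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired values.

    ``zero_policy``: "wilcox" drops zero differences (classical default);
    "pratt" ranks them but excludes them from W+/W-. Exact p-values come
    from the full sign-assignment null distribution of W = min(W+, W-) when
    n_effective <= 25 and there are no ties; otherwise a normal
    approximation with continuity and tie corrections is used.
    """
    if zero_policy not in {"wilcox", "pratt"}:
        raise ValueError(f"unknown zero policy {zero_policy!r}")
    d = sample.differences()
    if np.all(d == 0):
        return TestResult(statistic=0.0, p_value=1.0, n_effective=0, method="degenerate")

    if zero_policy == "wilcox":
        d = d[d != 0]
        ranks = sps.rankdata(np.abs(d))
    else:
        ranks_all = sps.rankdata(np.abs(d))
        nz = d != 0
        d, ranks = d[nz], ranks_all[nz]
    n = len(d)
    if n < 5:
        raise ValueError("need at least 5 nonzero differences")

    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    has_ties = len(np.unique(np.abs(d))) != n or zero_policy == "pratt"

    if n <= 25 and not has_ties:
        pmf = _signed_rank_distribution(ranks)
        total = len(pmf) - 1  # = 2 * sum of ranks
        w2 = int(round(w * 2))
        support = np.arange(total + 1)
        p = float(pmf[(support <= w2) | (support >= total - w2)].sum())
        return TestResult(statistic=w, p_value=min(p, 1.0), n_effective=n, method="exact")

    mu = n * (n + 1) / 4.0
    if zero_policy == "pratt":
        n_zero = int(np.sum(sample.differences() == 0))
        ntot = n + n_zero
        mu = (ntot * (ntot + 1) - n_zero * (n_zero + 1)) / 4.0
        sigma2 = (ntot * (ntot + 1) * (2 * ntot + 1) - n_zero * (n_zero + 1) * (2 * n_zero + 1)) / 24.0
    else:
        sigma2 = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction on the ranks actually used
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    sigma2 -= float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    if sigma2 <= 0:
        return TestResult(statistic=w, p_value=1.0, n_effective=n, method="degenerate")
    z = (w - mu + 0.5) / np.sqrt(sigma2)  # continuity correction toward the mean
    p = float(min(1.0, 2.0 * sps.norm.cdf(z)))
    return TestResult(statistic=w, p_value=p, n_effective=n, method="normal_approx")


# --------------------------------------------------------------------------
# Bonferroni
# --------------------------------------------------------------------------

def bonferroni_alpha(family_alpha: float, m: int) -> float:
    """Per-comparison threshold family_alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not (0 < family_alpha < 1):
        raise ValueError("family_alpha must be in (0, 1)")
    return family_alpha / m


# --------------------------------------------------------------------------
# ICC(A,1)
# --------------------------------------------------------------------------

def icc_single(sample: PairedSample, confidence: float = 0.95) -> ICCResult:
    """Two-way absolute-agreement single-measures ICC with its F-based CI.

    Uses the standard mean-squares estimator for k raters (here k = 2) and
    the McGraw & Wong confidence interval.
    """
    data = np.column_stack([sample.x, sample.y])
    n, k = data.shape
    if n < 5:
        raise ValueError("need at least 5 pairs")
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or ss_rows <= 0:
        return ICCResult(0.0, -1.0, 1.0, degenerate=True)
    icc = (msr - mse) / denom

    alpha = 1.0 - confidence
    if mse <= 0:
        return ICCResult(float(icc), -1.0, 1.0, degenerate=True)
    a = k * icc / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b = 1.0 + k * icc * (n - 1) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    if not np.isfinite(a):
        return ICCResult(1.0, -1.0, 1.0, degenerate=True)
    v_num = (a * msc + b * mse) ** 2
    v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = v_num / v_den
    f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    lower = float(np.clip(lower, -1.0, 1.0))
    upper = float(np.clip(upper, -1.0, 1.0))
    return ICCResult(float(icc), lower, upper)


# --------------------------------------------------------------------------
# Power / sample size for detecting a correlation
# --------------------------------------------------------------------------

def correlation_power(rho: float, n: int, alpha: float, two_tailed: bool = True) -> float:
    """Power of the test of rho = 0 at sample size n.

    The sample correlation under the alternative is approximated by the
    bias-corrected Fisher z: atanh(r) ~ Normal(atanh(rho) + rho / (2(n-1)),
    1 / sqrt(n-3)); the critical r comes from the t distribution of
    r * sqrt(n-2) / sqrt(1-r^2) under the null.
    """
    if n < 4:
        return 0.0
    tail = alpha / 2 if two_tailed else alpha
    t_crit = sps.t.ppf(1 - tail, n - 2)
    r_crit = t_crit / np.sqrt(t_crit**2 + n - 2)
    mu = np.arctanh(rho) + rho / (2.0 * (n - 1))
    sd = 1.0 / np.sqrt(n - 3)
    power = 1.0 - sps.norm.cdf((np.arctanh(r_crit) - mu) / sd)
    if two_tailed:
        power += sps.norm.cdf((np.arctanh(-r_crit) - mu) / sd)
    return float(power)


def sample_size_for_correlation(
    rho: float, alpha: float, power: float, two_tailed: bool = True, n_max: int = 100000
) -> int:
    """Smallest n whose power reaches the target for detecting rho vs zero."""
    if not (0 < rho < 1) or not (0 < alpha < 1) or not (0 < power < 1):
        raise ValueError("rho, alpha, power must lie in (0, 1)")
    for n in range(5, n_max + 1):
        if correlation_power(rho, n, alpha, two_tailed) >= power:
            return n
    raise ValueError(f"power {power} unattainable below n = {n_max}")
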