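"""Inter-observer agreement statistics.

Implements the full battery used in multi-reader dosimetry reproducibility
studies on an ``n treatments x k observers`` matrix of a single quantity:

* **ICC** — intraclass correlation, two-way random effects, absolute
  agreement, single rater (ICC(A,1) in McGraw & Wong's nomenclature), with
  the F-based 95% confidence interval.  Works on any observer-pair subset or
  the full matrix.
* **Pairwise CV** — root-mean-square within-pair coefficient of variation, in
  percent: per treatment s_i = |x_i - y_i|/sqrt(2), m_i = (x_i + y_i)/2, and
  CV = 100 * sqrt(mean((s_i/m_i)^2)).  Scale invariant.
* **Bland-Altman** — bias (mean difference) and limits of agreement at
  bias +/- 2*SD (multiplier 2, as commonly drawn on the plots, not 1.96).
* **RDC** — reproducibility coefficient: the maximum ratio between any two
  observers' readings of the same treatment expected in 95% of cases.
  Estimated on the log scale from one-way random-effects variance components
  (treatment as random block, residual = inter-observer error):
  RDC = exp(q * sigma_hat) where q is the 95th percentile of the range of k
  iid standard normals.  CI by nonparametric bootstrap over treatments.
* **Location tests** — Shapiro-Wilk normality gate per observer column; if
  every column passes, paired t tests plus additive two-way ANOVA (observer
  effect); otherwise Wilcoxon signed-rank plus Friedman.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import integrate, optimize, stats

__all__ = [
    "ReadingsMatrix",
    "IccResult",
    "BlandAltmanResult",
    "RdcResult",
    "PairwiseTest",
    "ComparisonResult",
    "icc",
    "pairwise_cv",
    "bland_altman",
    "rdc",
    "compare_readers",
    "normal_range_quantile",
]

_EPS = 1e-12


@dataclass(frozen=True)
class ReadingsMatrix:
    """n_treatments x n_observers readings of one quantity."""

    values: np.ndarray
    observer_labels: tuple[str, ...]
    treatment_labels: tuple[str, ...]
    quantity: str = ""
    units: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise ValueError("values must be 2-D (treatments x observers)")
        n, k = v.shape
        if n < 2 or k < 2:
            raise ValueError("need at least 2 treatments and 2 observers")
        if len(self.observer_labels) != k or len(self.treatment_labels) != n:
            raise ValueError("label lengths do not match matrix shape")
        if not np.all(np.isfinite(v)):
            raise ValueError("matrix contains missing or non-finite cells")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_table(cls, table, quantity: str, units: str = "") -> "ReadingsMatrix":
        """Pivot a long-format observer table (one row per treatment x
        observer) into a matrix for one quantity column."""
        from .cohort import COLUMN_BY_QUANTITY

        col = COLUMN_BY_QUANTITY.get(quantity, quantity)
        wide = table.pivot(index="treatment_id", columns="observer_id", values=col)
        if wide.isna().any().any():
            raise ValueError("incomplete block design: missing (treatment, observer)")
        return cls(
            values=wide.to_numpy(dtype=float),
            observer_labels=tuple(str(c) for c in wide.columns),
            treatment_labels=tuple(str(i) for i in wide.index),
            quantity=quantity,
            units=units,
        )

    def subset(self, observers) -> "ReadingsMatrix":
        idx = [self.observer_labels.index(o) for o in observers]
        return ReadingsMatrix(
            values=self.values[:, idx],
            observer_labels=tuple(observers),
            treatment_labels=self.treatment_labels,
            quantity=self.quantity,
            units=self.units,
        )

    def column(self, observer: str) -> np.ndarray:
        return self.values[:, self.observer_labels.index(observer)]


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IccResult:
    estimate: float
    ci_low: float
    ci_high: float
    model_label: str = "ICC(A,1): two-way random, absolute agreement, single rater"
    low_n: bool = False


def two_way_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """(MSR, MSC, MSE) of the additive treatments x observers layout."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc(matrix: ReadingsMatrix, alpha: float = 0.05) -> IccResult:
    """Two-way random-effects, absolute-agreement, single-rater ICC with the
    standard F-based confidence interval (McGraw & Wong ICC(A,1))."""
    x = matrix.values
    n, k = x.shape
    msr, msc, mse = two_way_mean_squares(x)
    scale = float(np.var(x))
    if scale < _EPS * max(1.0, float(np.mean(x)) ** 2):
        raise ValueError("ICC undefined: zero total variance")
    low_n = n < 5

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    est = (msr - mse) / denom

    if mse <= _EPS * msr and msc <= _EPS * msr:
        # perfect agreement: no residual or observer variance
        return IccResult(1.0, 1.0, 1.0, low_n=low_n)

    a = k * est / (n * (1.0 - est))
    b = 1.0 + k * est * (n - 1) / (n * (1.0 - est))
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    ci_low = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    ci_high = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    ci_low = min(ci_low, est)
    ci_high = min(max(ci_high, est), 1.0)
    return IccResult(float(est), float(ci_low), float(ci_high), low_n=low_n)


# ---------------------------------------------------------------------------
# Pairwise CV
# ---------------------------------------------------------------------------


def pairwise_cv(x, y) -> float:
    """Root-mean-square within-pair CV between two observers, in percent."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and paired")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("pairwise CV requires strictly positive readings")
    s = np.abs(x - y) / math.sqrt(2.0)
    m = (x + y) / 2.0
    return float(100.0 * math.sqrt(np.mean((s / m) ** 2)))


# ---------------------------------------------------------------------------
# Bland-Altman
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    means: np.ndarray = field(repr=False)
    differences: np.ndarray = field(repr=False)
    multiplier: float = 2.0

    @property
    def n(self) -> int:
        return len(self.differences)


def bland_altman(x, y, multiplier: float = 2.0) -> BlandAltmanResult:
    """Bias and limits of agreement bias +/- multiplier*SD of differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need paired 1-D series with n >= 2")
    d = x - y
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - multiplier * sd,
        loa_high=bias + multiplier * sd,
        means=(x + y) / 2.0,
        differences=d,
        multiplier=multiplier,
    )


# ---------------------------------------------------------------------------
# RDC
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def normal_range_quantile(k: int, p: float = 0.95) -> float:
    """p-quantile of the range of k iid standard normals by quadrature.

    The range CDF is F(r) = k * integral phi(u) [Phi(u+r) - Phi(u)]^(k-1) du,
    obtained by conditioning on the location of the sample minimum.
    """
    if k < 2:
        raise ValueError("k must be >= 2")

    def range_cdf(r: float) -> float:
        def integrand(u):
            return (
                k
                * stats.norm.pdf(u)
                * (stats.norm.cdf(u + r) - stats.norm.cdf(u)) ** (k - 1)
            )

        val, _ = integrate.quad(integrand, -9.0, 9.0, limit=200)
        return val

    return float(optimize.brentq(lambda r: range_cdf(r) - p, 1e-9, 12.0, xtol=1e-10))


@dataclass(frozen=True)
class RdcResult:
    estimate: float
    ci_low: float
    ci_high: float
    sigma_within_log: float
    q95_range_k: float
    n_bootstrap: int
    seed: int | None


def _within_row_var(logx: np.ndarray) -> np.ndarray:
    """Per-treatment unbiased variance across observers of the log readings
    (one-way random-effects residual contributions)."""
    return np.var(logx, axis=1, ddof=1)


def rdc(
    matrix: ReadingsMatrix,
    n_bootstrap: int = 2000,
    seed: int | None = 0,
    alpha: float = 0.05,
) -> RdcResult:
    """Reproducibility coefficient with bootstrap percentile CI.

    The within-treatment observer SD sigma_hat is the square root of the
    one-way ANOVA residual mean square of the log readings (treatments are
    random blocks; observer bias, if any, inflates the residual, which is the
    intended reading of a "maximum ratio between observers" statistic).
    """
    x = matrix.values
    if np.any(x <= 0):
        raise ValueError("RDC requires strictly positive readings (log transform)")
    k = matrix.k
    q = normal_range_quantile(k, 0.95)
    logx = np.log(x)
    s2 = _within_row_var(logx)
    sigma = math.sqrt(float(np.mean(s2)))
    if sigma < _EPS:
        return RdcResult(1.0, 1.0, 1.0, 0.0, q, 0, seed)
    estimate = math.exp(q * sigma)

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, matrix.n, size=(n_bootstrap, matrix.n))
    sigma_b = np.sqrt(np.mean(s2[idx], axis=1))
    boots = np.exp(q * sigma_b)
    ci_low, ci_high = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    ci_low = min(float(ci_low), estimate)
    ci_high = max(float(ci_high), estimate)
    return RdcResult(estimate, ci_low, ci_high, sigma, q, n_bootstrap, seed)


# ---------------------------------------------------------------------------
# Location tests with normality gate
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairwiseTest:
    pair: tuple[str, str]
    statistic: float | None
    p_value: float | None
    degenerate: bool = False


@dataclass(frozen=True)
class ComparisonResult:
    normality_p: dict[str, float]
    family: str  # "parametric" | "non-parametric"
    overall_test: str
    overall_statistic: float | None
    overall_p: float | None
    pairwise_test: str
    pairwise: tuple[PairwiseTest, ...]
    alpha: float
    degenerate: bool = False


def _observer_effect_anova(x: np.ndarray) -> tuple[float, float]:
    """Observer-effect F test from the additive two-way layout (one reading
    per cell, so no interaction term is estimable)."""
    n, k = x.shape
    _, msc, mse = two_way_mean_squares(x)
    if mse < _EPS:
        return math.inf, 0.0
    f = msc / mse
    p = float(stats.f.sf(f, k - 1, (n - 1) * (k - 1)))
    return float(f), p


def compare_readers(matrix: ReadingsMatrix, alpha: float = 0.05) -> ComparisonResult:
    """Normality-gated reader comparison.

    Shapiro-Wilk is applied to every observer column; only if all columns are
    compatible with normality at ``alpha`` is the parametric family used
    (paired t per pair, additive two-way ANOVA observer effect overall),
    otherwise Wilcoxon signed-rank per pair and Friedman overall.
    """
    x = matrix.values
    n, k = x.shape
    if n < 3:
        raise ValueError("normality testing requires n >= 3")
    labels = matrix.observer_labels

    normality_p = {}
    for j, lab in enumerate(labels):
        col = x[:, j]
        if np.ptp(col) < _EPS:
            normality_p[lab] = 0.0  # constant column: not testable, fail the gate
        else:
            normality_p[lab] = float(stats.shapiro(col).pvalue)
    parametric = all(p > alpha for p in normality_p.values())

    pairs = list(itertools.combinations(range(k), 2))
    pairwise = []
    if parametric:
        pairwise_name = "paired t"
        for i, j in pairs:
            d = x[:, i] - x[:, j]
            if np.max(np.abs(d)) < _EPS:
                pairwise.append(PairwiseTest((labels[i], labels[j]), None, None, True))
            else:
                t = stats.ttest_rel(x[:, i], x[:, j])
                pairwise.append(
                    PairwiseTest(
                        (labels[i], labels[j]), float(t.statistic), float(t.pvalue)
                    )
                )
        overall_name = "two-way ANOVA (observer effect)"
        if np.ptp(x - x.mean(axis=1, keepdims=True)) < _EPS:
            overall_stat, overall_p, degenerate = None, None, True
        else:
            overall_stat, overall_p = _observer_effect_anova(x)
            degenerate = False
    else:
        pairwise_name = "Wilcoxon signed-rank"
        for i, j in pairs:
            d = x[:, i] - x[:, j]
            if np.max(np.abs(d)) < _EPS:
                pairwise.append(PairwiseTest((labels[i], labels[j]), None, None, True))
            else:
                w = stats.wilcoxon(x[:, i], x[:, j])
                pairwise.append(
                    PairwiseTest(
                        (labels[i], labels[j]), float(w.statistic), float(w.pvalue)
                    )
                )
        overall_name = "Friedman"
        if np.ptp(x - x.mean(axis=1, keepdims=True)) < _EPS:
            overall_stat, overall_p, degenerate = None, None, True
        else:
            fr = stats.friedmanchisquare(*(x[:, j] for j in range(k)))
            overall_stat, overall_p = float(fr.statistic), float(fr.pvalue)
            degenerate = False

    return ComparisonResult(
        normality_p=normality_p,
        family="parametric" if parametric else "non-parametric",
        overall_test=overall_name,
        overall_statistic=overall_stat,
        overall_p=overall_p,
        pairwise_test=pairwise_name,
        pairwise=tuple(pairwise),
        alpha=alpha,
        degenerate=degenerate,
    )
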