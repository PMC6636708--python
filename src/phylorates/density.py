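"""Regression layer: rate-vs-time and rate-vs-diversity quadratic fits, the
across-family exponential trend, and the three-way density-dependence
classification of binned interval rates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .rates import BinnedRateSeries, RateEstimate

__all__ = [
    "RegressionFit",
    "DensityClass",
    "DensityDependence",
    "ols_fit",
    "rate_vs_time",
    "RateTimeResult",
    "rate_vs_diversity",
    "RateDiversityResult",
    "across_family_trend",
    "TrendResult",
    "classify_density",
]


@dataclass(frozen=True)
class RegressionFit:
    """A polynomial OLS fit with its overall F-test.

    ``coefficients`` are intercept-first.  ``vertex`` is the stationary point
    of a quadratic fit in predictor units, defined only when the quadratic
    coefficient is nonzero.
    """

    degree: int
    coefficients: np.ndarray
    f_statistic: float
    df_model: int
    df_resid: int
    r_squared: float
    p_value: float
    coef_pvalues: np.ndarray

    @property
    def vertex(self) -> float | None:
        if self.degree == 2 and self.coefficients[2] != 0.0:
            return float(-self.coefficients[1] / (2.0 * self.coefficients[2]))
        return None


def ols_fit(x: Sequence[float], y: Sequence[float], degree: int = 1) -> RegressionFit:
    """Least-squares polynomial fit (with intercept) plus the model F-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    if x.size != y.size:
        raise ValueError("x and y must have the same length")
    if x.size < degree + 2:
        raise ValueError(f"need at least {degree + 2} points for degree {degree}")
    if np.ptp(x) == 0.0:
        raise ValueError("x values are all equal")
    if np.ptp(y) == 0.0:
        # constant response: a flat fit with no explained variance
        coefs = np.zeros(degree + 1)
        coefs[0] = y[0]
        return RegressionFit(degree, coefs, 0.0, degree, x.size - degree - 1, 0.0, 1.0,
                             np.array([0.0] + [1.0] * degree))
    design = sm.add_constant(np.column_stack([x**d for d in range(1, degree + 1)]))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design matrix")
    res = sm.OLS(y, design).fit()
    return RegressionFit(
        degree=degree,
        coefficients=np.asarray(res.params),
        f_statistic=float(res.fvalue),
        df_model=int(res.df_model),
        df_resid=int(res.df_resid),
        r_squared=float(res.rsquared),
        p_value=float(res.f_pvalue),
        coef_pvalues=np.asarray(res.pvalues),
    )


# ---------------------------------------------------------------------------
# rate through time (summed-lineages view)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RateTimeResult:
    fit: RegressionFit
    midpoints_bp: np.ndarray  # predictor: time BP of each between-bin rate
    rates: np.ndarray  # per-year rates between consecutive bins
    vertex_bp: float | None  # turning point of the fitted quadratic, years BP
    vertex_reliable: bool  # quadratic coefficient significant at 5%


def rate_vs_time(millennial: Sequence[tuple[float, float]]) -> RateTimeResult:
    """Quadratic fit of the between-bin diversification rate against time BP.

    ``millennial`` is the (bin midpoint BP, mean N) output of the millennial
    binning, ordered oldest first.  The rate between consecutive bins,
    Delta ln(mean N) / Delta t, is assigned to the midpoint between the two
    bin centers.
    """
    if len(millennial) < 5:
        raise ValueError("need at least 5 bins")
    t = np.array([m[0] for m in millennial], dtype=float)
    n = np.array([m[1] for m in millennial], dtype=float)
    if np.any(np.diff(t) >= 0):
        raise ValueError("bin midpoints must be strictly decreasing (years BP)")
    if np.any(n <= 0):
        raise ValueError("bin means must be positive")
    # moving toward the present: t decreases, elapsed time is t_old - t_young
    rates = np.diff(np.log(n)) / -np.diff(t)
    mids = (t[:-1] + t[1:]) / 2.0
    fit = ols_fit(mids, rates, degree=2)
    reliable = bool(fit.coef_pvalues[2] < 0.05)
    return RateTimeResult(fit, mids, rates, fit.vertex, reliable)


@dataclass(frozen=True)
class RateDiversityResult:
    fit: RegressionFit
    peak_n: float | None  # diversity at maximum rate; None when curvature >= 0


def rate_vs_diversity(points: Sequence[tuple[float, float]]) -> RateDiversityResult:
    """Quadratic fit of rate against ln(diversity); peak N* from the vertex.

    Only the predictor is logged (rates can be zero).  The peak diversity
    N* = exp(-b1 / (2 b2)) is reported only for concave fits (b2 < 0).
    """
    if len(points) < 5:
        raise ValueError("need at least 5 points")
    n = np.array([p[0] for p in points], dtype=float)
    r = np.array([p[1] for p in points], dtype=float)
    if np.any(n < 1):
        raise ValueError("diversity must be >= 1")
    fit = ols_fit(np.log(n), r, degree=2)
    peak = math.exp(fit.vertex) if fit.coefficients[2] < 0 else None
    return RateDiversityResult(fit, peak)


# ---------------------------------------------------------------------------
# across families
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrendResult:
    fit: RegressionFit
    slope: float  # per year, on the chosen response scale
    percent_per_millennium: float
    rate_doubling_time: float  # years for the rate itself to double
    response: str
    n_excluded: int


def across_family_trend(
    estimates: Sequence[RateEstimate], response: str = "log_rate"
) -> TrendResult:
    """Trend of per-family overall rates against root age.

    With ``response="log_rate"`` (default) fits ln(r) on root age, matching an
    exponential change of rates through time; ``"raw_rate"`` fits r directly.
    Zero rates are excluded (with a warning) under the log response.
    """
    if response not in ("log_rate", "raw_rate"):
        raise ValueError("response must be 'log_rate' or 'raw_rate'")
    usable = [e for e in estimates if e.r_e > 0]
    n_excluded = len(estimates) - len(usable)
    if n_excluded and response == "log_rate":
        warnings.warn(f"excluded {n_excluded} zero-rate estimates from log trend", stacklevel=2)
    if len(usable) < 3:
        raise ValueError("need at least 3 families with positive rates")
    ages = np.array([e.root_age for e in usable])
    r = np.array([e.r_e for e in usable])
    y = np.log(r) if response == "log_rate" else r
    fit = ols_fit(ages, y, degree=1)
    slope = float(fit.coefficients[1])
    pct = (math.exp(abs(slope) * 1000.0) - 1.0) * 100.0
    t2 = math.log(2.0) / abs(slope) if slope != 0 else math.inf
    return TrendResult(fit, slope, pct, t2, response, n_excluded)


# ---------------------------------------------------------------------------
# within-family density dependence
# ---------------------------------------------------------------------------


class DensityDependence(Enum):
    NEGATIVE = "negative_density_dependence"
    POSITIVE = "positive_density_dependence"
    CONSTANT = "constant_rate"


@dataclass(frozen=True)
class DensityClass:
    value: DensityDependence
    slope: float
    p_value: float
    alpha: float


def classify_density(binned: BinnedRateSeries, alpha: float = 0.05) -> DensityClass:
    """Classify a family's interval rates as negative/positive density
    dependence or constant-rate growth.

    Regresses the per-bin rate on ln N at the bin's older edge.  A slope
    significantly below 0 (two-sided p < alpha) is negative density
    dependence, significantly above 0 positive; otherwise constant rate.
    """
    x = np.asarray(binned.ln_n_start, dtype=float)
    r = np.asarray(binned.rates, dtype=float)
    usable = np.isfinite(x) & np.isfinite(r)
    x, r = x[usable], r[usable]
    if x.size < 4:
        raise ValueError("fewer than 4 usable bins: insufficient resolution to classify")
    if np.ptp(x) == 0.0:
        # lineage count never changed across bin edges; nothing to regress on
        return DensityClass(DensityDependence.CONSTANT, 0.0, 1.0, alpha)
    fit = ols_fit(x, r, degree=1)
    slope = float(fit.coefficients[1])
    p = float(fit.coef_pvalues[1])
    if not math.isfinite(p):  # e.g. a perfectly constant response
        p = 1.0
    if p < alpha and slope < 0:
        cls = DensityDependence.NEGATIVE
    elif p < alpha and slope > 0:
        cls = DensityDependence.POSITIVE
    else:
        cls = DensityDependence.CONSTANT
    return DensityClass(cls, slope, p, alpha)
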