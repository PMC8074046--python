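"""Regression-based risk of meropenem target non-attainment.

The original calculator models the minimum (8 h trough) meropenem
concentration after standard dosing as a linear regression of ln(C8h)
on ln(CLCR). The risk of missing the 100% T>MIC target is then the
predictive probability that C8h falls below the MIC, obtained from
classic linear-model theory: the predictive distribution of a new
ln-concentration at a given ln(CLCR) is a scaled-and-shifted Student t
with n-2 degrees of freedom (a Gaussian variant is available because
some implementations use standardized residuals with normal quantiles).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ApplicabilityError, ValidationError

log = logging.getLogger(__name__)


@dataclass
class RegressionRiskModel:
    """Fitted double-log regression of trough concentration on CLCR.

    Parameters are on the natural-log scale: ``intercept`` in ln(mg/L),
    ``slope`` per ln(mL/min). ``residual_sd``, ``n_train``, ``mean_ln_x``
    and ``sxx`` carry the training-sample information needed for exact
    prediction intervals and predictive probabilities. ``clcr_range`` is
    the applicability window (default 25-255 mL/min) outside which the
    model refuses to predict.
    """

    intercept: float
    slope: float
    residual_sd: float
    n_train: int
    mean_ln_x: float
    sxx: float
    clcr_range: tuple = (25.0, 255.0)
    gaussian_approx: bool = False

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValidationError(f"residual_sd must be >= 0, got {self.residual_sd}")
        if self.n_train < 3:
            raise ValidationError(f"n_train must be >= 3, got {self.n_train}")
        if self.sxx <= 0:
            raise ValidationError(f"sxx must be > 0, got {self.sxx}")
        if self.slope >= 0:
            log.warning(
                "fitted slope %.3g is non-negative; expected a negative "
                "CLCR-concentration relation for meropenem", self.slope,
            )

    def _check_range(self, clcr: float, permissive: bool = False) -> None:
        lo, hi = self.clcr_range
        if not lo <= clcr <= hi:
            msg = (
                f"clcr {clcr:g} mL/min outside the applicability range "
                f"{lo:g}-{hi:g} mL/min; the calculator's disclaimer excludes "
                "such patients"
            )
            if permissive:
                log.warning(msg)
            else:
                raise ApplicabilityError(msg)

    def _pred_sd(self, ln_clcr: float) -> float:
        """SD of a new ln-observation at ln_clcr (residual + estimation leverage)."""
        lev = 1.0 + 1.0 / self.n_train + (ln_clcr - self.mean_ln_x) ** 2 / self.sxx
        return self.residual_sd * math.sqrt(lev)


def fit_loglog_regression(
    clcr_values: Sequence[float],
    c8h_values: Sequence[float],
    clcr_range: tuple = (25.0, 255.0),
) -> RegressionRiskModel:
    """Ordinary least squares of ln(C8h) on ln(CLCR).

    Requires at least 3 strictly positive pairs. The residual SD uses the
    unbiased n-2 denominator; the training mean and sum of squares of
    ln(CLCR) are stored for exact predictive inference.
    """
    x = np.asarray(clcr_values, dtype=float)
    y = np.asarray(c8h_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("clcr_values and c8h_values must be equal-length 1-D")
    if x.size < 3:
        raise ValidationError(f"need >= 3 points to fit, got {x.size}")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValidationError("all clcr and c8h values must be > 0 (log scale)")
    lx, ly = np.log(x), np.log(y)
    mean_ln_x = float(lx.mean())
    sxx = float(np.sum((lx - mean_ln_x) ** 2))
    if sxx <= 0:
        raise ValidationError("clcr values are all identical; slope not identifiable")
    slope = float(np.sum((lx - mean_ln_x) * (ly - ly.mean())) / sxx)
    intercept = float(ly.mean() - slope * mean_ln_x)
    resid = ly - (intercept + slope * lx)
    residual_sd = float(np.sqrt(np.sum(resid**2) / (x.size - 2)))
    return RegressionRiskModel(
        intercept=intercept,
        slope=slope,
        residual_sd=residual_sd,
        n_train=int(x.size),
        mean_ln_x=mean_ln_x,
        sxx=sxx,
        clcr_range=clcr_range,
    )


def predict_c8h(model: RegressionRiskModel, clcr: float, permissive: bool = False) -> float:
    """Median predicted 8-h trough concentration (mg/L) at a given CLCR.

    The back-transformed point prediction exp(a + b ln CLCR) is the median
    of the lognormal predictive distribution (not its mean).
    """
    if clcr <= 0:
        raise ValidationError(f"clcr must be > 0, got {clcr}")
    model._check_range(clcr, permissive)
    return math.exp(model.intercept + model.slope * math.log(clcr))


def prediction_interval(
    model: RegressionRiskModel,
    clcr: float,
    level: float = 0.95,
    permissive: bool = False,
) -> tuple[float, float]:
    """Prediction interval for a new trough observation, in mg/L.

    Computed on the ln scale as yhat +/- q * s * sqrt(1 + 1/n + leverage)
    with q a Student-t (df = n-2) or normal quantile, then exponentiated.
    """
    if not 0 < level < 1:
        raise ValidationError(f"level must be in (0, 1), got {level}")
    if clcr <= 0:
        raise ValidationError(f"clcr must be > 0, got {clcr}")
    model._check_range(clcr, permissive)
    lx = math.log(clcr)
    mu = model.intercept + model.slope * lx
    sd = model._pred_sd(lx)
    pr = (1.0 + level) / 2.0
    if model.gaussian_approx:
        q = stats.norm.ppf(pr)
    else:
        q = stats.t.ppf(pr, df=model.n_train - 2)
    return (math.exp(mu - q * sd), math.exp(mu + q * sd))


def risk_regression(
    model: RegressionRiskModel,
    clcr: float,
    mic: float,
    permissive: bool = False,
) -> float:
    """Predictive probability that the 8-h trough falls below the MIC.

    P(C8h < MIC) = F((ln MIC - yhat) / pred_sd) with F the CDF of the
    t distribution with n-2 df (or the standard normal under the
    ``gaussian_approx`` switch). This is the tool's "risk of target
    non-attainment" for the 100% T>MIC target assessed at the trough.
    """
    if mic <= 0:
        raise ValidationError(f"mic must be > 0, got {mic}")
    if clcr <= 0:
        raise ValidationError(f"clcr must be > 0, got {clcr}")
    model._check_range(clcr, permissive)
    lx = math.log(clcr)
    mu = model.intercept + model.slope * lx
    sd = model._pred_sd(lx)
    if sd == 0:  # degenerate noise-free model: point mass at mu
        if math.log(mic) > mu:
            return 1.0
        if math.log(mic) < mu:
            return 0.0
        return 0.5
    z = (math.log(mic) - mu) / sd
    if model.gaussian_approx:
        return float(stats.norm.cdf(z))
    return float(stats.t.cdf(z, df=model.n_train - 2))
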