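"""Two-step model-based evaluation of the regression risk calculator.

Step 1 — benchmark the population-PK model against measured TDM
concentrations: per-sample prediction errors, summarised as a median bias
and a 50% prediction-error interval (quartiles), absolute and relative.

Step 2 — with the PK model as benchmark, quantify agreement between
regression-based and PK-based risks of target non-attainment across a MIC
grid and renal-function strata, using Lin's concordance correlation
coefficient (CCC). Unlike Pearson's r, the CCC penalises location and
scale shifts, so it measures interchangeability of the two risk engines
rather than mere correlation. Agreement strength is graded on McBride's
bands and the evaluation passes if the one-sided 95% lower confidence
limit of the CCC pooled over the whole MIC grid exceeds 0.95.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .patients import Patient
from .poppk import DosingRegimen, PopPKModel, simulate_concentrations, simulate_trough
from .regression_risk import RegressionRiskModel, risk_regression
from .risk_cfr import DEFAULT_MIC_GRID

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Step 1: prediction errors
# ---------------------------------------------------------------------------

@dataclass
class TDMObservation:
    """One measured meropenem concentration with its dose history.

    ``dose_history`` is a sequence of (dose mg, infusion_duration h,
    start_time h) events; ``sample_time`` is hours since the first dose
    start.
    """

    patient_id: str
    dose_history: Sequence[tuple]
    sample_time: float
    concentration: float

    def __post_init__(self) -> None:
        if not self.dose_history:
            raise ValidationError(f"{self.patient_id}: empty dose history")
        first = min(start for _, _, start in self.dose_history)
        if self.sample_time <= first:
            raise ValidationError(
                f"{self.patient_id}: sample at {self.sample_time} h predates the "
                f"first dose at {first} h"
            )
        if self.concentration < 0:
            raise ValidationError(f"{self.patient_id}: concentration must be >= 0")

    @property
    def time_after_last_dose(self) -> float:
        starts = [s for _, _, s in self.dose_history if s < self.sample_time]
        return self.sample_time - max(starts)


@dataclass
class PredictionErrorReport:
    """Bias and precision of PK-model predictions against observations.

    ``bias_abs`` is the median prediction error in mg/L, ``bias_rel`` the
    median relative error; ``pe_interval_50`` the (25th, 75th) percentiles
    (linear-interpolation definition). Per-sample errors are retained in
    ``per_sample``.
    """

    bias_abs: float
    bias_rel: float
    pe_interval_50: tuple
    pe_interval_50_rel: tuple
    sign_convention: str
    per_sample: pd.DataFrame = field(repr=False, default=None)


def prediction_errors(
    observations: Sequence[TDMObservation],
    patients: Mapping[str, Patient],
    model: PopPKModel,
    regimen_resolver: Optional[Callable[[TDMObservation], Sequence[tuple]]] = None,
    n_replicates: int = 2000,
    rng: Optional[np.random.Generator] = None,
    sign_convention: str = "predicted_minus_observed",
    relative_denominator: str = "observed",
    with_residual: bool = True,
    include_iiv: bool = True,
) -> PredictionErrorReport:
    """Per-sample prediction errors of the PK model and their summary.

    The predicted concentration for each sample is the median over
    ``n_replicates`` Monte-Carlo replicates (IIV and, by default, residual
    variability) at the sample time under the observation's own dose
    history. The default sign convention makes underprediction negative
    (PE = predicted - observed); the literal observed-minus-predicted
    difference is available via ``sign_convention="observed_minus_predicted"``.
    """
    if not observations:
        raise ValidationError("no observations")
    if sign_convention not in ("predicted_minus_observed", "observed_minus_predicted"):
        raise ValidationError(f"unknown sign_convention {sign_convention!r}")
    if relative_denominator not in ("observed", "predicted"):
        raise ValidationError(f"unknown relative_denominator {relative_denominator!r}")
    if rng is None:
        rng = np.random.default_rng()
    resolver = regimen_resolver or (lambda obs: obs.dose_history)

    eff_model = model
    if not include_iiv:
        eff_model = PopPKModel(**{**model.__dict__, "omega": {k: 0.0 for k in model.omega}})

    rows = []
    for obs in observations:
        if obs.patient_id not in patients:
            raise ValidationError(f"observation references unknown patient {obs.patient_id!r}")
        sims = simulate_concentrations(
            eff_model, patients[obs.patient_id], resolver(obs), [obs.sample_time],
            n_replicates, rng, with_residual=with_residual,
        )[:, 0]
        predicted = float(np.median(sims))
        pe = predicted - obs.concentration
        if sign_convention == "observed_minus_predicted":
            pe = -pe
        denom = obs.concentration if relative_denominator == "observed" else predicted
        rows.append({
            "patient_id": obs.patient_id,
            "sample_time_h": obs.sample_time,
            "time_after_last_dose_h": obs.time_after_last_dose,
            "observed_mg_l": obs.concentration,
            "predicted_mg_l": predicted,
            "pe_mg_l": pe,
            "pe_rel": pe / denom if denom > 0 else np.nan,
        })
    per_sample = pd.DataFrame(rows)
    pe = per_sample["pe_mg_l"].to_numpy()
    pe_rel = per_sample["pe_rel"].to_numpy()
    return PredictionErrorReport(
        bias_abs=float(np.median(pe)),
        bias_rel=float(np.nanmedian(pe_rel)),
        pe_interval_50=(float(np.percentile(pe, 25)), float(np.percentile(pe, 75))),
        pe_interval_50_rel=(
            float(np.nanpercentile(pe_rel, 25)), float(np.nanpercentile(pe_rel, 75))
        ),
        sign_convention=sign_convention,
        per_sample=per_sample,
    )


# ---------------------------------------------------------------------------
# Lin's concordance correlation coefficient
# ---------------------------------------------------------------------------

def lins_ccc(x: Sequence[float], y: Sequence[float]) -> float:
    """Lin's concordance correlation coefficient with population (1/n) moments.

    CCC = 2 cov(x, y) / (var(x) + var(y) + (mean x - mean y)^2).
    Degenerate pairs with zero variance on both sides are defined as 1
    (equal means) or 0 (different means).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D sequences")
    if x.size < 2:
        raise ValidationError("need at least 2 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("values must be finite")
    vx, vy = x.var(), y.var()
    dmean = x.mean() - y.mean()
    denom = vx + vy + dmean**2
    if denom == 0:
        return 1.0
    if vx == 0 and vy == 0:
        return 0.0
    sxy = float(np.mean((x - x.mean()) * (y - y.mean())))
    return float(2.0 * sxy / denom)


def ccc_confidence(
    ccc: float,
    n: int,
    level: float = 0.95,
    sided: str = "two",
    pearson_r: Optional[float] = None,
    location_shift: float = 0.0,
) -> tuple:
    """Confidence limit(s) for a CCC via Fisher's z-transform.

    Uses Lin's asymptotic variance of z = atanh(CCC), which involves the
    Pearson correlation ``pearson_r`` and the standardised location shift
    ``location_shift`` u = (mean x - mean y)/sqrt(sd_x sd_y); if
    ``pearson_r`` is omitted it defaults to the CCC (no-shift case).
    ``sided="two"`` returns (lower, upper); ``sided="lower"`` the one-sided
    lower limit as a 1-tuple.
    """
    if n < 4:
        raise ValidationError(f"need n >= 4 for a confidence limit, got {n}")
    if not 0 < level < 1:
        raise ValidationError(f"level must be in (0, 1), got {level}")
    if sided not in ("two", "lower", "upper"):
        raise ValidationError(f"sided must be 'two', 'lower' or 'upper', got {sided!r}")
    if abs(ccc) >= 1:
        log.warning("|CCC| = 1 is degenerate; returning the point value as its limit")
        return (ccc, ccc) if sided == "two" else (ccc,)
    r = ccc if pearson_r is None else pearson_r
    u = location_shift
    if abs(r) < 1e-12:
        raise ValidationError("Pearson r of 0 gives an undefined CCC variance")
    p2 = ccc * ccc
    var_z = (
        (1 - r * r) * p2 / ((1 - p2) * r * r)
        + 2 * ccc**3 * (1 - ccc) * u * u / (r * (1 - p2) ** 2)
        - ccc**4 * u**4 / (2 * r * r * (1 - p2) ** 2)
    ) / (n - 2)
    var_z = max(var_z, 0.0)
    z = math.atanh(ccc)
    se = math.sqrt(var_z)
    if sided == "two":
        q = stats.norm.ppf((1 + level) / 2)
        return (math.tanh(z - q * se), math.tanh(z + q * se))
    q = stats.norm.ppf(level)
    if sided == "lower":
        return (math.tanh(z - q * se),)
    return (math.tanh(z + q * se),)


@dataclass
class CCCResult:
    ccc: float
    lower: float          # two-sided lower limit
    upper: float          # two-sided upper limit
    lower_one_sided: float
    n: int
    grade: str


def ccc_with_ci(x: Sequence[float], y: Sequence[float], level: float = 0.95) -> CCCResult:
    """CCC with two-sided CI, one-sided lower limit and McBride grade.

    With fewer than 4 pairs no asymptotic limit is meaningful: the limits
    degrade to the point estimate (graded on it) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ccc = lins_ccc(x, y)
    sx, sy = x.std(), y.std()
    if sx > 0 and sy > 0:
        r = float(np.corrcoef(x, y)[0, 1])
        u = float((x.mean() - y.mean()) / math.sqrt(sx * sy))
    else:
        r, u = ccc, 0.0
    if x.size < 4:
        log.warning("only %d pairs: CCC confidence limits degrade to the point "
                    "estimate", x.size)
        lo = hi = lo1 = ccc
    elif abs(ccc) >= 1 or abs(r) < 1e-12:
        lo = hi = lo1 = ccc
    else:
        lo, hi = ccc_confidence(ccc, x.size, level, "two", r, u)
        (lo1,) = ccc_confidence(ccc, x.size, level, "lower", r, u)
    return CCCResult(ccc=ccc, lower=lo, upper=hi, lower_one_sided=lo1,
                     n=int(x.size), grade=mcbride_grade(max(min(lo, 1.0), -1.0)))


def mcbride_grade(value: float) -> str:
    """McBride strength-of-agreement band for a CCC (lower confidence limit).

    poor < 0.90, moderate 0.90-0.95, substantial 0.95-0.99,
    almost perfect > 0.99. Boundaries: 0.90 -> moderate, 0.95 and 0.99 ->
    substantial.
    """
    if not -1.0 <= value <= 1.0:
        raise ValidationError(f"CCC must be in [-1, 1], got {value}")
    if value < 0.90:
        return "poor"
    if value < 0.95:
        return "moderate"
    if value <= 0.99:
        return "substantial"
    return "almost_perfect"


# ---------------------------------------------------------------------------
# Step 2: agreement between the two risk engines
# ---------------------------------------------------------------------------

@dataclass
class AgreementReport:
    """Paired risk table and per-MIC / pooled CCC summaries.

    ``paired`` is tidy (patient_id, clcr, mic, risk_regression, risk_pk);
    ``table`` has one row per (stratum, mic) plus a pooled row per stratum
    (mic = "0.125-16" style label) with CCC, confidence limits and grade.
    ``pooled`` maps stratum name to its pooled CCCResult.
    """

    paired: pd.DataFrame
    table: pd.DataFrame
    pooled: dict
    mic_grid: tuple


def compare_risk_methods(
    patients: Sequence[Patient],
    regression_model: RegressionRiskModel,
    pk_model: PopPKModel,
    mic_grid: Sequence[float] = DEFAULT_MIC_GRID,
    strata: Optional[Mapping[str, Callable[[float], bool]]] = None,
    n_replicates: int = 2000,
    rng: Optional[np.random.Generator] = None,
    regimen: DosingRegimen = DosingRegimen(),
    unbound_fraction: float = 1.0,
    pk_risk_factory: Optional[Callable[[Patient], Callable[[float], float]]] = None,
) -> AgreementReport:
    """Pair regression-based and PK-based risks per patient and MIC.

    One trough cohort of ``n_replicates`` virtual patients is simulated per
    real patient (IIV only) and reused across all MIC levels, so the paired
    comparison is not inflated by independent Monte-Carlo noise per MIC.
    CCC (with confidence limits and McBride grade on the two-sided lower
    limit) is reported per MIC and pooled over the whole grid, for the full
    cohort and for each stratum (default: CLCR > 50 mL/min).
    """
    if not patients:
        raise ValidationError("need at least one patient")
    mic_grid = tuple(float(m) for m in mic_grid)
    if rng is None:
        rng = np.random.default_rng()
    if strata is None:
        strata = {"clcr_gt_50": lambda clcr: clcr > 50.0}

    rows = []
    for p in patients:
        clcr = p.resolve_clcr()
        if pk_risk_factory is None:
            c8h = simulate_trough(pk_model, p, regimen, n_replicates, rng) * unbound_fraction
            pk_risk = lambda mic: float(np.mean(c8h < mic))  # noqa: E731
        else:
            pk_risk = pk_risk_factory(p)
        for mic in mic_grid:
            rows.append({
                "patient_id": p.id,
                "clcr": clcr,
                "mic": mic,
                "risk_regression": risk_regression(regression_model, clcr, mic),
                "risk_pk": float(pk_risk(mic)),
            })
    paired = pd.DataFrame(rows)

    groups = {"all": np.ones(len(paired), dtype=bool)}
    for name, pred in strata.items():
        groups[name] = paired["clcr"].map(pred).to_numpy()

    table_rows = []
    pooled = {}
    grid_label = f"{mic_grid[0]:g}-{mic_grid[-1]:g}"
    for stratum, mask in groups.items():
        sub = paired[mask]
        if sub.empty:
            log.warning("stratum %r is empty; CCC omitted", stratum)
            continue
        for mic in mic_grid:
            cell = sub[sub["mic"] == mic]
            if len(cell) < 2:
                log.warning("stratum %r has <2 pairs at MIC %g; cell omitted",
                            stratum, mic)
                continue
            res = ccc_with_ci(cell["risk_regression"], cell["risk_pk"])
            table_rows.append(_table_row(stratum, f"{mic:g}", res))
        res = ccc_with_ci(sub["risk_regression"], sub["risk_pk"])
        pooled[stratum] = res
        table_rows.append(_table_row(stratum, grid_label, res))
    return AgreementReport(
        paired=paired, table=pd.DataFrame(table_rows), pooled=pooled, mic_grid=mic_grid
    )


def _table_row(stratum: str, mic_label: str, res: CCCResult) -> dict:
    return {
        "stratum": stratum,
        "mic": mic_label,
        "ccc": res.ccc,
        "ci_lower": res.lower,
        "ci_upper": res.upper,
        "lower_one_sided": res.lower_one_sided,
        "n_pairs": res.n,
        "grade": res.grade,
    }


def success_criterion(report: AgreementReport, threshold: float = 0.95) -> bool:
    """Evaluation success: one-sided 95% lower limit of the pooled CCC
    (all patients, whole MIC grid) strictly above the threshold."""
    if "all" not in report.pooled:
        raise ValidationError("report has no pooled CCC for the full cohort")
    return bool(report.pooled["all"].lower_one_sided > threshold)
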