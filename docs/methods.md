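# Methods

## The risk question

A critically ill patient starts empiric meropenem at standard dosing
(1000 mg infused over 0.5 h, every 8 h). For the strict pharmacodynamic
target 100% T>MIC the decisive quantity is the trough concentration C8h,
8 h after the assessed dose: the target fails exactly when C8h < MIC. Both
risk engines in this package estimate P(C8h < MIC) for a patient
characterised by the Cockcroft–Gault creatinine clearance
CLCR = (140 − age)·weight / (72·SCr), ×0.85 for women (SCr in mg/dL; a
µmol/L switch divides by 88.4). The assessed dose defaults to the first
dose (the conservative empiric-therapy reading); steady state is available
by setting `n_doses` so the trough follows the last of several q8h doses.

## Regression engine

The trough is modelled as ln C8h = a + b·ln CLCR + ε with ε ~ N(0, σ²),
fitted by ordinary least squares (σ̂² uses the n−2 denominator). Exact
linear-model theory gives the predictive distribution of a new
ln-observation at ln x₀ as â + b̂·ln x₀ + s·T_{n−2}, where
s = σ̂·√(1 + 1/n + (ln x₀ − x̄)²/Sxx). Everything the engine reports
follows from this: the back-transformed point prediction (the *median* of
the lognormal predictive distribution), prediction intervals, and
risk(MIC) = predictive CDF at ln MIC. Whether the historical tool used t or
normal quantiles, and whether it carried the leverage terms, is not
documented; the t with leverage is the default because it is the exact
small-sample theory, and a `gaussian_approx` switch provides the
standardized-residual variant. At n in the hundreds the two differ by well
under a percentage point of risk except in the extreme tails.

The engine refuses CLCR outside 25–255 mL/min (the range the tool was
calibrated for) and flags assessments combining CLCR < 50 mL/min with any
contributing MIC ≥ 8 mg/L: a log-linear model cannot represent non-renal
elimination, so it over-predicts troughs — and under-predicts risk — in
renally impaired patients, which only matters at high MICs where the risk
is not already saturated near 1.

The packaged default coefficients (intercept 9.516, slope −2.091, residual
SD 0.889 on the ln scale, n = 500) were calibrated once by
`scripts/calibrate_defaults.py`: one simulated trough per patient (IIV, no
residual error) for a 500-patient synthetic cohort under the default PK
model, seed 12345. They are a self-consistent stand-in, clearly marked in
`default_config.json`, and replacing them with authentic published
coefficients is a one-file config overlay.

## Population-PK engine

Two-compartment disposition with constant-rate infusion input,
parameterised by CL, V1, Q, V2. The covariate structure is the clinical
one for meropenem:

* CL piecewise linear in CLCR, anchored at CL(0) = f·CL_pop with non-renal
  fraction f = 0.2 and CL(CLCR_ref) = CL_pop. The knot (`clcr_breakpoint`,
  default 100 mL/min) exists so a genuine two-slope model can be
  configured; the default `slope_ratio` = 1 makes the function a single
  line with a positive intercept.
* V1 = V1_pop·(WT/73)^k with k = 1 by default (volumes scale close to
  linearly with body size; the exponent is configurable).
* V2 = V2_pop·(1 + α·(ALB − 2.5)) with α = −0.2 per g/dL
  (hypoalbuminaemia → capillary leak → larger peripheral volume), floored
  at 0.1 L so the linear form cannot go non-positive.

Typical values (CL_pop 11 L/h at CLCR 86.4 mL/min, V1_pop 10.5 L at 73 kg,
Q 15 L/h, V2_pop 12 L at 2.5 g/dL) are in the range reported for
critically ill adults; like the regression coefficients they are a
documented, replaceable default, and every test of this module is
parameter-agnostic (oracles, recovery, invariants). IIV is lognormal and
independent per parameter (ω: CL 0.25, V1/Q/V2 0.30 on the ln scale; a
correlation structure can be configured but none is assumed). Residual
error is C·(1+ε_p)+ε_a with SDs 0.20 and 0.5 mg/L; negative simulated
observations are truncated at zero with the truncation rate logged.

Concentrations come from the closed-form bi-exponential solution with
macro-constants α, β derived from (CL, V1, Q, V2), superposed over the
dose history. The Q = 0 limit degenerates exactly to the one-compartment
infusion solution (the β-term coefficient vanishes), which doubles as an
analytic oracle; the general case is verified against stiff ODE
integration to relative error < 1e−6.

`risk_pk` counts the fraction of n = 2000 virtual patients (fresh IIV per
replicate, residual error off) whose unbound-fraction-scaled trough falls
below the MIC. Residual error is excluded from risk by default because it
represents measurement noise, not true exposure; it is included when
predicting *observations* (prediction-error analysis). The unbound
fraction defaults to 1.0 — meropenem protein binding is low and total
concentrations are the conventional comparator against MIC — but is
configurable. One simulated trough cohort per patient is reused across all
MIC levels in paired comparisons so that Monte-Carlo noise does not
independently perturb each MIC cell.

## Pathogen-level risk

For a MIC frequency distribution with normalized frequencies fᵢ over
doubling-dilution bins, risk = Σᵢ fᵢ·risk(MICᵢ) = 1 − CFR. Bins outside
the 8-level evaluation grid are evaluated exactly at the bin MIC (the risk
engines are analytic or simulable at arbitrary MIC), avoiding
interpolation bias at the tails. Censored top bins ("≥ X mg/L") are placed
at X with a logged warning; this under-states risk above X and is the
conservative, documented choice. Distributions are versioned CSV files
with a mandatory `source_label` echoed in every result; there is no live
download. The packaged distribution file is synthetic (generated by
`generate_mic_distribution`, labelled as such in its header).

Two banding rules coexist deliberately: the per-patient traffic light is
boundary-inclusive (green ≤ 10% < orange ≤ 50% < red), while the
cohort-summary bands are strict (< 10%, 10–50%, > 50%) as conventionally
printed for pathogen summaries; `classify_risk` and `cohort_band` name
them separately.

## Evaluation framework

**Prediction errors.** The predicted concentration for a TDM sample is the
median of 1000–2000 Monte-Carlo replicates (IIV + residual error) at the
sample time under the patient's own dose history. Bias is the *median*
prediction error and precision the (25th, 75th) percentile interval
(linear-interpolation percentiles), pairing a robust location with a 50%
interval; a mean-based variant is a flag. Sign convention: the default is
PE = predicted − observed so that underprediction is negative, matching
the convention in which a negative bias is read as the model
under-predicting; the literal observed-minus-predicted difference is
available behind a flag. Relative errors divide by the observed
concentration by default (flag for predicted).

**Agreement.** Lin's CCC = 2·cov(x,y)/(var x + var y + (x̄ − ȳ)²) with
population (1/n) moments; degenerate zero-variance pairs are defined as 1
(equal means) or 0 (otherwise). Confidence limits use Fisher's
z-transform with Lin's asymptotic variance (involving the Pearson r and
the standardised location shift u); both two-sided and one-sided limits
are reported because tables conventionally print two-sided intervals while
the success rule is one-sided. McBride grades (poor < 0.90, moderate
0.90–0.95, substantial 0.95–0.99, almost perfect > 0.99) are assigned on
the two-sided lower limit, which reproduces the conventional star grading
of published CCC tables. The pooled "0.125–16" CCC concatenates all
(patient × MIC) pairs into one vector pair. Success means the one-sided
95% lower limit of the pooled all-patient CCC strictly exceeds 0.95.
Cells or strata with fewer than 2 pairs are omitted with a warning; with
2–3 pairs the limits degrade to the point estimate.

## Synthetic data: what it emulates, what it does not

`generate_patients` draws CLCR, age, weight and albumin from lognormals
calibrated so the median and 95th percentile hit their targets exactly
(µ = ln median, σ = ln(p95/median)/z₀.₉₅), validating the implied 5th
percentile and warning when it misses the target by more than 15% — a
two-parameter family cannot in general match three quantiles, and for the
default CLCR targets (86.4, 35.4–161) the implied lower tail is lighter
than stated. Serum creatinine is *derived* by inverting Cockcroft–Gault
from the drawn CLCR, never drawn independently, so records are internally
consistent. Characteristics are drawn independently (no correlation
structure is published for these targets); male fraction 0.652. The
inclusion screen (CLCR 25–255 mL/min, no renal replacement) can be
enforced by resampling, with the resample count logged.

`generate_tdm` observes 1 + Poisson(4.7) q8h intervals per patient (mean
5.7 samples), one sample per interval at an offset drawn as
interval·Beta(a,b) with (a,b) solved so the median (6.2 h) and 5th
percentile (3.72 h) match; the stated 95th percentile (8.13 h) exceeds the
8-h interval — routine re-dosing is sometimes late — and is capped at the
interval, a known, accepted distortion of the extreme upper tail.
Ground-truth individual parameters are returned for recovery tests.

None of this reproduces real routine data: no dose adjustments or missed
doses, no within-patient covariate drift, no correlation between
characteristics, no assay censoring (LLOQ). Passing tests therefore show
the *machinery* is correct under the stated study conditions, not that the
packaged default models predict any particular hospital's patients.

## Numerical choices and problem sizes

Monte-Carlo sizes follow the conventions used throughout: 2000 replicates
for risk and trough simulation, 1000 for per-sample predicted medians in
the evaluation pipeline, 10,000 draws for generator calibration checks,
and 10⁶ draws where a sampling oracle must resolve risks to ±0.002.
Random state is always an explicit `numpy.random.Generator`; identical
seeds give bit-identical outputs, and output files exclude timestamps so
reruns are byte-identical. The synthetic evaluation study uses 155
patients, mirroring the cohort scale the generators are calibrated to.

Known limitations: single fixed target (100% T>MIC at the 8-h trough; 40%
fT>MIC and friends are extension points), no nonlinear mixed-effects
estimation (parameters enter via config, not fitting), no extracorporeal
clearance modelling (patients on renal replacement are excluded, ECMO is
ignored), and the default parameter sets are internally calibrated
stand-ins rather than published estimates.
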