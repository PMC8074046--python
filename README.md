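# meronat

Risk of meropenem target non-attainment in critically ill patients under
standard dosing (1 g as a 0.5 h infusion every 8 h), for clinical
pharmacologists and pharmacometricians who need a fast, pre-therapy risk
estimate and a framework to evaluate such estimates against a population-PK
benchmark.

Beta-lactam efficacy tracks the time the drug concentration stays above the
pathogen's minimum inhibitory concentration (MIC). For the strict target
100% T>MIC under intermittent q8h infusion, the binding constraint is the
trough: the patient misses the target exactly when the concentration 8 h
after the dose, C8h, falls below the MIC. Renal function drives meropenem
elimination, so the risk P(C8h < MIC) can be predicted from the
Cockcroft–Gault creatinine clearance (CLCR) alone.

## What is implemented

**Regression risk engine.** A linear regression on the double natural-log
scale, ln C8h = a + b·ln CLCR + ε, ε ~ N(0, σ²). For a new patient the
predictive distribution of ln C8h is a scaled-and-shifted Student t with
n−2 degrees of freedom, so

risk(CLCR, MIC) = T_{n−2}( (ln MIC − â − b̂·ln CLCR) / (σ̂·√(1 + 1/n + (ln CLCR − x̄)²/Sxx)) ),

with 95% prediction intervals from the same theory. Applicability is
restricted to CLCR 25–255 mL/min, and the engine is flagged as unreliable
for MIC ≥ 8 mg/L when CLCR < 50 mL/min.

**Population-PK risk engine.** A two-compartment model with covariates:
clearance piecewise linear in CLCR with a non-renal floor (CLCR = 0 retains
20% of the typical clearance), central volume a power of body weight,
peripheral volume linear in serum albumin. Interindividual variability is
lognormal per parameter; residual error is combined proportional +
additive. Concentration–time profiles use the closed-form bi-exponential
infusion solution superposed over the dose history; the risk at a MIC is
the fraction of 2000 simulated virtual patients whose trough falls below it.

**Pathogen-level risk (CFR).** When only the species is known, per-MIC
risks are weighted by the pathogen's MIC frequency distribution:
risk = Σᵢ fᵢ·risk(MICᵢ) = 1 − CFR, where CFR = Σᵢ fᵢ·PTA(MICᵢ). Results are
classified green (≤ 10%), orange (> 10% to ≤ 50%) or red (> 50%).

**Evaluation framework.** Step 1 benchmarks the PK model against measured
TDM concentrations (median prediction error = bias, quartiles = 50%
prediction-error interval). Step 2 pairs the two engines' risks per patient
and MIC over the grid 0.125–16 mg/L and measures agreement with Lin's
concordance correlation coefficient (CCC), with Fisher-z confidence limits
(Lin's variance), McBride grades, and a success rule: one-sided 95% lower
limit of the pooled CCC > 0.95.

**Synthetic data.** Generators for cohorts matching stated median and
5th/95th-percentile targets (median CLCR 86.4 mL/min, weight 73 kg,
albumin 2.5 g/dL, 65.2% male), routine TDM sampling times (median 6.2 h
after dose), and EUCAST-like MIC frequency distributions.

## Worked example

```python
from functools import partial
from meronat import Patient, assess, load_config, risk_regression

cfg = load_config()
patient = Patient(id="icu-17", sex="male", age=57.0, weight=73.0,
                  serum_creatinine=0.9, serum_albumin=2.5)
clcr = patient.resolve_clcr()                    # 93.5 mL/min
risk_fn = partial(risk_regression, cfg.regression, clcr)
res = assess(patient, risk_fn, mic=2.0)
print(f"{100 * res.risk:.1f}% -> {res.category}")
```

prints `77.2% -> red`: at CLCR 93.5 mL/min the predictive probability that
the 8-h trough falls below an MIC of 2 mg/L is 77%, i.e. standard dosing is
unlikely to hold 100% T>MIC against such a pathogen. The same patient
assessed against the packaged *Pseudomonas aeruginosa* distribution
(no MIC available) gives `31.8% -> orange` — the CFR-weighted average is
dominated by the susceptible bulk of isolates.

Running `python examples/04_evaluation_pipeline.py` executes the whole
two-step evaluation on a synthetic 155-patient study and ends with

```
pooled: 0.984 (lower one-sided 0.982)   0.985
evaluation successful: True
```

— the regression engine agrees with the PK benchmark at the
"substantial" level overall, and agreement is higher still in the
CLCR > 50 mL/min stratum (the per-MIC rows show where it degrades:
MIC 8 and 16 mg/L in patients with impaired renal function).

The `examples/` directory holds one short script per capability; the
`meronat` CLI (`assess`, `cfr`, `evaluate`, `simulate`, `generate`) wraps
the same functions for shell use.

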