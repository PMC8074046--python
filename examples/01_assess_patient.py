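"""Assess one patient's risk of meropenem target non-attainment.

Shows the three microbiological input modes: a known MIC, a known pathogen
without MIC (CFR over its MIC distribution), and neither (user-chosen
breakpoint). Risks are the predictive probability that the 8-h trough after
a standard 1 g / 0.5 h / q8h dose falls below the MIC; the traffic-light
category follows green <= 10% < orange <= 50% < red.
"""

from functools import partial
from importlib import resources

from meronat import (Patient, assess, load_config, read_mic_distributions_csv,
                     risk_regression)

cfg = load_config()
patient = Patient(id="icu-17", sex="male", age=57.0, weight=73.0,
                  serum_creatinine=0.9, serum_albumin=2.5)
clcr = patient.resolve_clcr()
risk_fn = partial(risk_regression, cfg.regression, clcr)
print(f"patient {patient.id}: Cockcroft-Gault CLCR = {clcr:.1f} mL/min")

dists = read_mic_distributions_csv(
    resources.files("meronat.data").joinpath("synthetic_mic_distributions.csv"))

for kwargs in (
    {"mic": 2.0},
    {"pathogen": "Pseudomonas aeruginosa", "distributions": dists},
    {"breakpoint_mic": 8.0},
):
    res = assess(patient, risk_fn, **kwargs)
    print(f"  mode={res.mode:13s} risk={100 * res.risk:5.1f}%  -> {res.category}")

# A high MIC in a patient with poor renal function triggers the disclaimer:
weak = Patient(id="icu-40", clcr=40.0)
res = assess(weak, partial(risk_regression, cfg.regression, 40.0), mic=8.0)
print(f"clcr 40 + MIC 8: risk={100 * res.risk:.1f}%, flags={res.disclaimer_flags}")
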