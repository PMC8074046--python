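"""The two-step model-based evaluation on a fully synthetic study.

Step 1 benchmarks the population-PK model against synthetic routine TDM
samples (median prediction error = bias; quartiles = 50% prediction-error
interval). Step 2 calibrates the regression engine on simulated troughs and
measures its agreement with the PK engine across the MIC grid using Lin's
concordance correlation coefficient, pooled and within the preserved-renal-
function stratum (CLCR > 50 mL/min). The evaluation counts as successful
when the one-sided 95% lower confidence limit of the pooled CCC exceeds 0.95.
"""

import numpy as np

from meronat import (CohortSpec, DosingRegimen, PopPKModel,
                     compare_risk_methods, fit_loglog_regression,
                     generate_patients, generate_tdm, prediction_errors,
                     simulate_trough, success_criterion)

rng = np.random.default_rng(7)
spec = CohortSpec()  # 155 patients at the study conditions
patients = generate_patients(spec, rng, enforce_inclusion=True)
pk = PopPKModel()
regimen = DosingRegimen()

# Step 1: prediction errors against synthetic TDM
observations, _ = generate_tdm(patients, regimen, pk, spec, rng)
report1 = prediction_errors(observations, {p.id: p for p in patients}, pk,
                            n_replicates=1000, rng=rng)
lo, hi = report1.pe_interval_50
print(f"step 1: {len(observations)} samples from {len(patients)} patients")
print(f"  bias {report1.bias_abs:+.2f} mg/L ({100 * report1.bias_rel:+.0f}%), "
      f"50% PE interval {lo:+.2f} to {hi:+.2f} mg/L")

# Step 2: agreement of regression vs PK risk predictions
clcr = np.array([p.resolve_clcr() for p in patients])
c8h = np.array([simulate_trough(pk, p, regimen, 1, rng)[0] for p in patients])
regression = fit_loglog_regression(clcr, c8h)
report2 = compare_risk_methods(patients, regression, pk,
                               n_replicates=2000, rng=rng)
print("\nstep 2: Lin's CCC per MIC (all patients / CLCR > 50 mL/min):")
for mic in report2.mic_grid:
    label = f"{mic:g}"
    row_all = report2.table.query("stratum == 'all' and mic == @label")
    row_50 = report2.table.query("stratum == 'clcr_gt_50' and mic == @label")
    print(f"  MIC {mic:6.3f}: {row_all.ccc.iloc[0]:6.3f} ({row_all.grade.iloc[0]})"
          f"   {row_50.ccc.iloc[0]:6.3f} ({row_50.grade.iloc[0]})")
pooled = report2.pooled
print(f"  pooled: {pooled['all'].ccc:.3f} (lower one-sided "
      f"{pooled['all'].lower_one_sided:.3f})   {pooled['clcr_gt_50'].ccc:.3f}")
print(f"evaluation successful: {success_criterion(report2)}")
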