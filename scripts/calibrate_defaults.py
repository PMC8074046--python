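"""One-off calibration of the default regression coefficients.

The packaged default regression model is fitted to simulated 8-h trough
concentrations (one IIV replicate per patient, no residual error) of a
500-patient synthetic cohort drawn from the default population-PK model.
Rerunning this script regenerates the `regression` block of
src/meronat/data/default_config.json; it is not part of the test or
acceptance workflow.
"""

import json
from pathlib import Path

import numpy as np

from meronat import (CohortSpec, DosingRegimen, PopPKModel,
                     fit_loglog_regression, generate_patients, simulate_trough)

SEED = 12345


def main() -> None:
    rng = np.random.default_rng(SEED)
    patients = generate_patients(CohortSpec(n_patients=500), rng, enforce_inclusion=True)
    pk = PopPKModel()
    regimen = DosingRegimen()
    clcr = np.array([p.resolve_clcr() for p in patients])
    c8h = np.array([simulate_trough(pk, p, regimen, 1, rng)[0] for p in patients])
    model = fit_loglog_regression(clcr, c8h)

    cfg_path = Path(__file__).resolve().parents[1] / "src/meronat/data/default_config.json"
    cfg = json.loads(cfg_path.read_text())
    cfg["regression"] = {
        "intercept": round(model.intercept, 6),
        "slope": round(model.slope, 6),
        "residual_sd": round(model.residual_sd, 6),
        "n_train": model.n_train,
        "mean_ln_x": round(model.mean_ln_x, 6),
        "sxx": round(model.sxx, 6),
        "clcr_min": 25.0,
        "clcr_max": 255.0,
    }
    cfg_path.write_text(json.dumps(cfg, indent=2) + "\n")
    print(f"wrote {cfg_path}")


if __name__ == "__main__":
    main()
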