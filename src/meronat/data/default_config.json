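{
  "_regression_note": "Default coefficients calibrated once against the packaged synthetic cohort (scripts/calibrate_defaults.py, seed 12345); replace with authentic published coefficients via a user config overlay.",
  "regression": {
    "intercept": 9.516063,
    "slope": -2.090611,
    "residual_sd": 0.889374,
    "n_train": 500,
    "mean_ln_x": 4.454038,
    "sxx": 71.691898,
    "clcr_min": 25.0,
    "clcr_max": 255.0
  },
  "pk": {
    "cl_pop": 11.0,
    "v1_pop": 10.5,
    "q": 15.0,
    "v2_pop": 12.0,
    "clcr_ref": 86.4,
    "wt_ref": 73.0,
    "alb_ref": 2.5,
    "nonrenal_fraction": 0.2,
    "clcr_breakpoint": 100.0,
    "slope_ratio": 1.0,
    "wt_exponent": 1.0,
    "alb_slope": -0.2,
    "omega": {"cl": 0.25, "v1": 0.30, "q": 0.30, "v2": 0.30},
    "residual_prop_sd": 0.20,
    "residual_add_sd": 0.50
  },
  "regimen": {"dose": 1000.0, "infusion_duration": 0.5, "interval": 8.0, "n_doses": 1},
  "mic_grid": [0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0],
  "green_max": 0.10,
  "orange_max": 0.50,
  "unbound_fraction": 1.0,
  "pe_sign_convention": "predicted_minus_observed",
  "gaussian_approx": false,
  "seed": 0
}
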