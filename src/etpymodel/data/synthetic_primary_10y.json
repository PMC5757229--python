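{
  "model_id": "primary_10y",
  "horizon_years": 10.0,
  "link": "logistic",
  "intercept": -8.6806,
  "baseline_survival": null,
  "calibration_scalar": null,
  "coefficients": {
    "age": {"value": 0.065, "transform": "identity"},
    "female": {"value": -0.40, "transform": "identity"},
    "smoking": {"value": 0.55, "transform": "identity"},
    "t2dm": {"value": 0.60, "transform": "identity"},
    "htn_therapy": {"value": 0.35, "transform": "identity"},
    "sbp": {"value": 0.018, "transform": "identity"},
    "tc": {"value": 0.008, "transform": "identity"},
    "hdl": {"value": -0.025, "transform": "identity"}
  }
}
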