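{
  "model_id": "secondary_20mo",
  "horizon_years": 1.6666666666666667,
  "link": "logistic",
  "intercept": -5.12,
  "baseline_survival": null,
  "calibration_scalar": 1.0,
  "coefficients": {
    "age": {"value": 0.03, "transform": "identity"},
    "female": {"value": -0.20, "transform": "identity"},
    "smoking": {"value": 0.35, "transform": "identity"},
    "t2dm": {"value": 0.40, "transform": "identity"},
    "vascular_beds": {"value": 0.25, "transform": "identity"},
    "afib": {"value": 0.30, "transform": "identity"},
    "ecvd": {"value": 0.05, "transform": "identity"},
    "prior_mi": {"value": 0.35, "transform": "identity"},
    "prior_is": {"value": 0.40, "transform": "identity"},
    "prior_hf": {"value": 0.55, "transform": "identity"},
    "eastern_europe_or_middle_east": {"value": 0.25, "transform": "identity"}
  }
}
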