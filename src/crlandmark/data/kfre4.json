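{
  "name": "kfre4",
  "description": "4-variable Kidney Failure Risk Equation (age, sex, eGFR, urine ACR). Coefficients and baseline survivals as published for the North American development cohorts; the non-North-American recalibrated baselines are included as an option (default off).",
  "inputs": [
    {"name": "age", "units": "years", "scale": 10.0, "log": false, "center": 7.036, "coefficient": -0.2201},
    {"name": "male", "units": "indicator", "scale": 1.0, "log": false, "center": 0.5642, "coefficient": 0.2467},
    {"name": "egfr", "units": "mL/min/1.73m2", "scale": 5.0, "log": false, "center": 7.222, "coefficient": -0.5567},
    {"name": "uacr", "units": "mg/g", "scale": 1.0, "log": true, "center": 5.137, "coefficient": 0.4510, "default": 7.5}
  ],
  "baseline_survival": {"2": 0.9832, "5": 0.9365},
  "baseline_survival_non_north_american": {"2": 0.9878, "5": 0.9570}
}
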