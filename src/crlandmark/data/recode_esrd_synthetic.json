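{
  "name": "recode_esrd_synthetic",
  "description": "SYNTHETIC stand-in for the RECODe end-stage-renal-disease equation. The structure (inputs, transforms, horizon-anchored baseline survival) mirrors the published equation, but the coefficient values here are synthetic placeholders with clinically plausible signs and magnitudes, shipped only so the benchmark workflow is runnable end-to-end. Replace this file with audited published coefficients before any substantive use.",
  "synthetic": true,
  "inputs": [
    {"name": "age", "units": "years", "scale": 10.0, "log": false, "center": 6.3, "coefficient": 0.15},
    {"name": "male", "units": "indicator", "scale": 1.0, "log": false, "center": 0.6, "coefficient": 0.10},
    {"name": "black_race", "units": "indicator", "scale": 1.0, "log": false, "center": 0.2, "coefficient": 0.30},
    {"name": "sbp", "units": "mmHg", "scale": 10.0, "log": false, "center": 13.5, "coefficient": 0.12},
    {"name": "hba1c", "units": "%", "scale": 1.0, "log": false, "center": 7.5, "coefficient": 0.18},
    {"name": "egfr", "units": "mL/min/1.73m2", "scale": 5.0, "log": false, "center": 16.0, "coefficient": -0.45},
    {"name": "uacr", "units": "mg/g", "scale": 1.0, "log": true, "center": 3.0, "coefficient": 0.35, "default": 7.5}
  ],
  "baseline_survival": {"1": 0.9995, "5": 0.996, "10": 0.985}
}
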