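# Full synthetic-study configuration for `crlandmark run-all`.
simulation:
  n_subjects: 4000
  beta1: [0.6, -0.5, 0.4, 0.0, 0.0]   # true subdistribution log-hazard ratios
  beta2: [0.3, 0.1, -0.1, 0.0, 0.0]   # competing-death log-hazard ratios
  p_mass: 0.10          # asymptotic cause-1 incidence at covariates = 0
  censor_rate: 0.04     # per-year random censoring
  admin_horizon: 22.0   # administrative censoring (years)
  time_scale: 8.0       # stretches the cause-1 latent time axis (years)
  death_rate: 0.05      # baseline competing-death rate per year
  missing_rates:
    uacr: 0.85          # heavily-missing marker, binned with missing category

landmarks: [1.0, 5.0, 10.0]
horizons: [1.0, 5.0, 10.0]
split_fraction: 0.7

screening:
  threshold: 0.1        # |logOR| retention cutoff
  alpha: 0.05
  horizon: 10.0
  adjusters: [age, male, black_race]

mcp:
  gamma: 3.0
  folds: 5
  cv_horizon: 10.0
  n_lambda: 20

calibration_groups: 10
shap_samples: 64
shap_subjects: 100
seed: 7
out_dir: run
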