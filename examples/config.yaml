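# Example pipeline configuration for `opioid-its run-all --config examples/config.yaml`.
# Omitted keys fall back to the package defaults (the study conditions).
seed: 1
n_months: 60
interruption_months: [29, 50]   # May 2018 and February 2020 on the Jan-2016 grid
patients_per_month: 800
noise_sd: 0.25                  # series-tier residual SD, percentage points
ar1_rho: 0.0
alpha: 0.05                     # Durbin-Watson significance level for the AR(1) refit
estimator: auto                 # auto | ols | ar1
high_dose_mme_threshold: 100.0
multi_provider_min: 2
overlap_mode: mean_ratio        # or any_overlap
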