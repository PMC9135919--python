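# Full-chain example on a synthetic two-group cohort.
# Run:  covnet run --config examples/pipeline.yaml --outdir results/example --seed 7
#
# Replace `simulation` with `inputs` to analyse your own CSV tables:
#   inputs:
#     concentrations: {A: conc_women.csv, B: conc_men.csv}
#     covariates:     {A: cov_women.csv,  B: cov_men.csv}

seed: 7
group_names: [A, B]

simulation:
  n_per_group: [120, 90]
  n_features: 20
  n_covariates: 10
  n_blocks: 4
  block_size: 4
  within_block_rho: 0.7
  rewired_nodes: [0, 1, 2, 3]
  missing_rate: 0.10

preprocess:
  max_missing_fraction: 0.25
  log_offset: 0.0
  n_trees: 50
  max_imputer_iterations: 5

extract:
  penalty: lasso
  cv_folds: 10

network:
  n_iterations: 500
  subsample_fraction: 0.75
  keep_fraction: 0.30
  probability_threshold: 0.90
  display_threshold: 0.6

diffconn:
  k: 100
  alpha: 0.05
  retain_frac: 0.70
  perm_iterations: 100
  tie_mode: strict

covsca:
  L: 3
  n_restarts: 10

embed:
  perplexity: 15.0

plots: true
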