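# Full default pipeline configuration (demo mode: fixtures generated in-run).
# Stage seeds are derived from the global seed by fixed offsets.

outdir: runs/demo
seed: 42
n_synthetic_per_class: 50
threshold: 0.5
cv_folds: 5
run_tsne: true

fixture:
  n_active: 138
  n_inactive: 150
  n_descriptors: 50
  class_shift: 1.5
  n_shifted: 10
  latent_rank: 5
  noise_sd: 1.0
  integer_columns: [3, 4]
  seed: 42

library:
  n_compounds: 2648
  true_active_fraction: 0.3
  missing_fraction: 0.1639
  seed: 42

gan:
  noise_dim: 64
  label_embedding_dim: 8
  generator_hidden: [128, 256]
  discriminator_hidden: [256, 128]
  leaky_slope: 0.2
  real_label_smoothing: 0.9
  epochs: 1000
  batch_size: 32
  learning_rate: 1.0e-4
  beta1: 0.5
  beta2: 0.999
  seed: 42

split:
  train: 0.70
  validation: 0.15
  test: 0.15
  stratified: true
  seed: 42

gbt:
  n_estimators: 2000
  learning_rate: 0.03
  max_depth: 6
  subsample: 0.9
  colsample_bytree: 0.8
  reg_lambda: 1.0
  reg_alpha: 0.0
  tree_method: hist
  seed: 42
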