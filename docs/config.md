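# Configuration reference

All stages read one YAML file mirroring `cpcausal.config.RunConfig`. Every
stochastic stage derives its seed from the global `seed` and the stage name,
so one integer reproduces a whole run. Unspecified fields take the desk-scale
defaults shown.

```yaml
seed: 0                # global seed; stage seeds derive from it
outdir: runs/desk      # all stage outputs and manifests land here
log_level: INFO

simulator:
  n_sources: 2                     # source labs
  n_batches_per_source: 2
  n_plates_per_batch: 1
  plate_rows: 4                    # wells per plate = rows x cols
  plate_cols: 6
  fovs_per_well: 1
  n_compounds: 12
  n_moa_classes: 3
  n_target_labels: 6
  allocation_bias: 2.0             # C->T strength; 0 = randomized plate maps
  phenotype_dim: 7
  embedding_dim: 64                # hashed n-gram SMILES embedding size
  phenotype_noise_sd: 0.3
  compound_scale: 2.0              # T->P effect scale
  confounder_phenotype_scale: 0.6  # C->P effect scale
  confounder_observation_scale: 0.5  # C->O (gradient/offset/blur) scale
  image_size: 64                   # pixels per side

profiling:
  illumination_radius: 7           # median-filter radius, pixels
  expected_radius: 4.0             # nucleus radius prior for declumping
  max_saturation: 0.5
  variance_floor: 1.0e-6
  correlation_ceiling: 0.95

diffusion:
  num_train_steps: 250             # full-scale reference: 1000
  beta_start: 0.0015
  beta_end: 0.0205
  epochs: 10
  batch_size: 32
  learning_rate: 1.0e-3
  hidden_dim: 384
  num_inference_steps: 50
  autoencoder_mode: pca            # or "identity" (exact, test mode)

adjustment:
  n_combinations: 10               # N in the Monte-Carlo backdoor average
  images_per_combination: 1

subprofile:
  threshold: 0.85                  # strict sign-consistency fraction
  n_ref_per_class: 3               # reference analysis: 5
  n_folds: 4                       # reference analysis: 10
  min_class_size: 4                # reference analysis: 10

metrics:
  n_permutations: 50               # label-shuffle null size
```

CLI flags `--seed` and `--outdir` override the file; `--n-combinations`
overrides `adjustment.n_combinations` for `debias`; `--task {moa,target}`
selects the classification task.
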