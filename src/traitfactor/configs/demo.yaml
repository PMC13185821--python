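# Desk-scale demonstration run: every resampling count is reduced so the full
# pipeline finishes in well under a minute on one CPU while exercising every
# stage. See full.yaml for the full-scale evaluation settings.
seed: 0
outdir: traitfactor_demo
synth:
  n_items_per_dimension: 4
  structure: big2_hier
  cross_loading: 0.1
  noise_sd: 0.5
  missing_rate: 0.02
  acquiescence_sd: 0.0
  groups:
    - {name: g1, n: 200}
    - {name: g2, n: 200}
    - {name: g3, n: 200}
    - {name: g4, n: 200, noise_multiplier: 2.0}
rank_scan:
  ranks: [2, 3, 4, 5, 6]
  n_reps: 5
  n_folds: 5
  scheme: kfold
fit_ranks: [2, 5]
subgroup:
  label_field: group
  rank: 2
  n_null: 20
direction_scan:
  theta_true: 147
  n_features: 40
  signal_fraction: 0.5
  noise_sd: 0.5
  family_size: 2
  n_reps: 2
  n_folds: 5
  n_perm: 100
  alpha_fdr: 0.05
  K_grid: [2, 4]
  eta_grid: [0.25, 1.0]
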