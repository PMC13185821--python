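# Full-scale evaluation settings: 1,000 cross-validation repetitions, 5 folds,
# ranks 2-8, 100 null label shuffles, 5,000 permutations and bootstraps, and 30
# prediction repetitions. Expect hours of compute on a single CPU.
seed: 0
outdir: traitfactor_full
synth:
  n_items_per_dimension: 12
  structure: big2_hier
  cross_loading: 0.1
  noise_sd: 0.5
  missing_rate: 0.02
  acquiescence_sd: 0.3
  groups:
    - {name: g01, n: 2000}
    - {name: g02, n: 2000}
    - {name: g03, n: 2000}
    - {name: g04, n: 2000}
    - {name: g05, n: 2000, noise_multiplier: 1.5}
    - {name: g06, n: 2000, noise_multiplier: 2.0}
    - {name: g07, n: 2000, loading_perturbation: 0.1}
    - {name: g08, n: 2000, loading_perturbation: 0.2}
rank_scan:
  ranks: [2, 3, 4, 5, 6, 7, 8]
  n_reps: 1000
  n_folds: 5
  scheme: kfold
fit_ranks: [2, 5]
subgroup:
  label_field: group
  rank: 2
  n_null: 100
direction_scan:
  theta_true: 147
  n_features: 200
  signal_fraction: 0.3
  noise_sd: 0.5
  family_size: 2
  n_reps: 30
  n_folds: 5
  n_perm: 5000
  alpha_fdr: 0.05
  K_grid: [1, 2, 3, 5, 8]
  eta_grid: [0.1, 0.25, 0.5, 1.0]
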