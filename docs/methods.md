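# Methods

## The model

`traitfactor` decomposes a subjects × items table of 1–5 Likert responses
into a small number of additive, parts-based factors with **orthogonal
projective non-negative matrix factorization (OPNMF)**. With X the items ×
subjects matrix (non-negative, after reverse scoring and imputation), OPNMF
seeks a non-negative, approximately orthonormal basis W (items × r)
minimizing

    ‖X − W Wᵀ X‖_F .

The projective form has two consequences that the rest of the package builds
on: factor scores for any sample are H = WᵀX (no refit needed, so a basis
learned in one sample transfers to held-out data), and the near-orthogonal,
non-negative columns give each item one dominant factor, so a hard partition
by maximal loading is meaningful. Subject scores are unconstrained and free
to correlate; correlated blocks of factors are exactly what the hierarchical
"Big Two" structure (Social Adaptation over the E/A/C item blocks,
Spontaneous Mentation over N/O) looks like in this representation.

### Fitting

Multiplicative updates on the item Gram matrix C = XXᵀ:

    W ← W ∘ (C W) ⊘ (W (Wᵀ C W)),   then  W ← W / ‖W‖₂ ,

with a 1e-16 denominator guard. Because every quantity depends on X only
through C, per-iteration cost is independent of the number of subjects; the
inner loop is JIT-compiled (numba) with an identical pure-numpy fallback.
Defaults: `max_iter=50_000`, `tol=1e-5` on the relative Frobenius change of
W, deterministic NNDSVD initialization (zeros filled with mean(X)/100 so the
multiplicative updates can move every entry); `init="random"` with a seed is
available for robustness checks. Final columns are scaled to unit norm so the
argmax assignment is scale-fair across factors.

**Known numerical behavior.** The objective is non-increasing during the
transient phase, but near stationarity the update map has neutral directions
(rotations inside the factor subspace), so in float64 the trace can tick up
by ~1e-8–1e-6 relative on runs beyond a few thousand iterations. Tests
therefore assert monotonicity with a 1e-5 relative slack. The fitted bases,
partitions, and reconstruction errors are unaffected.

## Evaluation framework

`run_crossvalidation` repeats a main/hold split (reshuffled k-fold, default 5
folds; group-stratified folds that never split a labeled group; or a
cross-sample bootstrap between two instruments sharing items), fits models
independently on both sides at every candidate rank, and records:

* **aRI** – chance-adjusted agreement of the two hard partitions;
* **VI** – variation of information, H(p₁) + H(p₂) − 2I(p₁;p₂) in nats;
* **CI** – Lin's concordance correlation between the vectorized upper
  triangles of the two item × item cosine-similarity matrices (Pearson
  available as an option). For signed PCA/EFA loadings CI and assignments use
  absolute loadings, since signed cosines conflate polarity with structure;
* **iRE** – RE(W_main, X_hold) − RE(W_hold, X_hold) with normalized REs; a
  difference rather than a ratio because the within-sample RE can be ≈ 0;
* **IV** – per item, one minus the mean pairwise Jaccard overlap of the item
  sets it is assigned to across the resampled partitions.

Per rank the records are summarized by medians; aRI/CI are oriented up,
VI/iRE down; each index is min–max normalized across ranks (a constant index
contributes 0.5 everywhere) and averaged into a composite with a bootstrap
95% CI. Optimal ranks are the composite maxima. One master seed drives
per-repetition substreams, so any repetition is re-runnable in isolation.

Baselines: PCA (singular vectors of row-centered data) and EFA
(SMC-initialized iterated principal-axis factoring with varimax rotation,
hand-rolled because no EFA package is available in the target environment;
rotation via statsmodels). For baseline iRE inside the CV the reconstruction
uses the orthonormalized (QR) span of the loadings on row-centered data.

## Subgroup generalizability

The overall basis W is applied to each demographic/cultural subgroup;
generalizability is mean(actual − null) of the normalized RE over label
shuffles that preserve every group's size (default 100). Intra-group
heterogeneity refits OPNMF within the (actual or null) group; model
similarity is the CI between group and overall bases. Univariate regressions
of generalizability on heterogeneity, similarity, and sample size report r²
and two-tailed p.

Two significance measures are reported. The one-sample t-test on the
(actual − null) differences follows the stated protocol but treats only the
null REs as random; as a test of "this group behaves like a random group" it
is anti-conservative by roughly √n_null and rejects the majority of truly
random groups. The empirical two-sided permutation p (`p_perm`), which ranks
the actual RE within the null distribution, is calibrated (≈3–5% false
positives at α = 0.05 in the package's own null simulations) and is the one
used for false-positive control.

## The Big Two plane and directional prediction

Subject (SA, SM) scores are z-scored per axis; a direction θ ∈ (0°, 180°]
(0° = +SA, 90° = +SM, counterclockwise) defines the target
p = cos θ·SA + sin θ·SM. For exactly standardized axes with correlation ρ the
projection SD follows √(1 + ρ·sin 2θ), so positively coupled traits peak at
45°.

**T-PLS.** Univariate PLS is computed in its Krylov form: the K-component
PLS1 coefficient vector is the least-squares solution restricted to
span{b, Ab, …, A^{K−1}b}, A = XsᵀXs, b = Xsᵀy on internally standardized
features (verified in tests to match NIPALS PLS to 1e-13). Thresholding
keeps the ⌈η·p⌉ largest-magnitude coefficients. (K, η) are selected by
grouped inner CV (families never split); ties go to the smaller K, then
smaller η; the model is refitted on all data. Default grids for a single fit
are K ∈ {1,…,25} and η ∈ {0.05,…,1.0}; the 180-angle scan defaults to the
coarser K ∈ {1,2,3,5,8}, η ∈ {0.1,0.25,0.5,1.0} to keep 180 × reps × folds
nested fits tractable.

**Direction scan.** Accuracy per angle is the mean out-of-fold Pearson r
over `n_reps` repetitions of `n_folds`-fold CV with honest nested selection
inside every training fold; the Krylov solver is batched over all 180
angles. The permutation null permutes the target across subjects and re-runs
a single CV pass at the per-angle modal (K, η);
p = (1 + #{null ≥ observed})/(1 + n_perm) with Benjamini–Hochberg FDR across
the 180 angles. Using one CV pass and fixed hyperparameters makes the null
slightly wider than the observed statistic's sampling distribution, so
p-values are conservative; the package's null simulations measure ≤5%
FDR-significant angles on pure-noise targets. Bootstrap feature reliability
resamples subjects with replacement at fixed (K, η);
z = mean(β)/SD(β) (z = 0 where SD = 0), two-tailed normal p, BH-FDR across
features. Signature responses are zᵀ·(standardized features) per subject
(full z-vector by default; a significant-only variant is a caller-side mask).

## Synthetic data

The generator plants the structure the analysis assumes, with defaults that
are the package's study conditions:

* five blocks of items (one per Big Five dimension), dominant loadings
  U(0.8, 1.2), optional cross-loadings `cross_loading`·U(0.3, 1.0) (planted
  default 0.1), half of each block reverse-keyed;
* latent subject scores from a multivariate normal with unit variances and,
  for `big2_hier`, correlation 0.6 inside {E,A,C} and inside {N,O}. Scores
  are drawn with mean 3 and truncated at zero: the truncation keeps the
  non-negative data model while binding with probability ~1.3e-3, so the
  empirical score covariance still converges to the specified one (verified
  within 10% Frobenius error at n = 10,000);
* responses: per-item affine rescaling of W·H to [1, 5] by the item's
  1st/99th percentiles, then additive per-subject acquiescence and N(0,
  noise_sd) noise **in Likert units** (default noise 0.5), clipping,
  rounding, reverse-keyed storage flip, and uniform missingness;
* subgroups: per-group loading perturbation (clipped at 0) and noise
  multiplier; family ids are consecutive blocks, a synthetic stand-in for
  kinship;
* phenotypes: a chosen fraction of features encode w_j·proj(θ*) plus
  N(0, noise_sd) (SNR 2:1 at the default |w| ≈ 1, noise 0.5); the rest are
  pure noise.

What the generator does **not** emulate: real item wording, ordinal response
styles beyond a single additive acquiescence shift, country-level frequency
structure, or connectivity topology. Passing tests therefore demonstrate
correctness of the machinery and recoverability of planted structure, not
claims about any real inventory.

## Problem sizes in the shipped checks

Rank selection runs at n = 2,000 subjects × 60 items with 50 repetitions of
fivefold CV (the full-scale configuration, 1,000 repetitions, ships as
`configs/full.yaml`); direction scans use n = 400, p = 60, 500 permutations
(3 reps) for planted-angle recovery and 200 permutations for null
calibration; bootstrap calibration uses 1,000 resamples. The demo pipeline
(`configs/demo.yaml`) exercises every stage in under a minute and is
bit-reproducible under a fixed master seed.

## Limitations

* The multiplicative update inherits the float64 near-stationary jitter
  described above; it is not a certified-descent method.
* Item-mean imputation is applied once on the full table before CV (a
  per-fold option exists); with missingness ≫ 10% this leaks weak
  information across folds.
* The permutation null for the direction scan is conservative by
  construction (see above); exact nulls would need the full nested procedure
  per permutation.
* EFA is principal-axis + varimax only; oblique rotations are out of scope.
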