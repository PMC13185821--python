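# traitfactor

Item-level decomposition of Big Five personality questionnaires with
orthogonal projective non-negative matrix factorization (OPNMF), a
cross-validated framework for choosing the number of factors, subgroup
generalizability analysis, and a 2D "Big Two" trait space with directional
predictive modeling.

**Who it is for.** Psychometricians and personality/neuroscience researchers
who want to ask, from raw 1–5 Likert item responses rather than scale
scores: how many stable, generalizable factors does this inventory support;
does a factor model fitted on everyone transfer to demographic or cultural
subgroups; and which orientations of a low-dimensional trait plane are
predictable from emotional, cognitive, or neural phenotype features?

## The model

OPNMF approximates the items × subjects matrix X ≥ 0 as

    X ≈ W Wᵀ X,   W ≥ 0,  Wᵀ W ≈ I,

by multiplicative updates `W ← W ∘ (XXᵀW) ⊘ (W WᵀXXᵀW)` with spectral
renormalization. The non-negative, near-orthogonal basis W assigns each item
one dominant factor (a hard partition by maximal loading), and the
projective form gives out-of-sample factor scores H = WᵀX directly, which is
what makes repeated cross-validated stability evaluation cheap.

Candidate ranks are scored across repeated fivefold cross-validation by:
adjusted Rand index (aRI) and variation of information (VI) between the main
and hold-sample partitions, Lin's concordance (CI) between the item–item
cosine-similarity matrices of the bases, increased reconstruction error
(iRE) of the transferred basis, and per-item assignment variability (IV).
An oriented, normalized composite of aRI/VI/CI/iRE selects the optimal
rank(s). On data with a planted hierarchical structure — five item blocks
whose latent scores couple {E, A, C} (Social Adaptation) and {N, O}
(Spontaneous Mentation) — both the two- and five-factor solutions are stable
while three- and four-factor solutions are not.

In the Big Two plane (0° = +SA, 90° = +SM), the projection
p = cos θ·SA + sin θ·SM defines a scalar target for every direction θ ∈
1°…180°; thresholded partial least squares (T-PLS, top ⌈η·p⌉ coefficients of
a K-component PLS, tuned by nested grouped CV) maps which orientations are
predictable from a phenotype feature table, with permutation p-values,
Benjamini–Hochberg FDR across angles, and bootstrap z-scores for feature
reliability.

## Worked example

```python
import traitfactor as tf

# Plant the hierarchical structure: 60 items, five blocks, Big Two coupling
truth = tf.build_true_loadings(12, "big2_hier", cross_loading=0.1,
                               seed=1, noise_sd=0.5)
R, H_true = tf.simulate_responses(truth, 2000)
R = tf.apply_reverse_scoring(R)

records = tf.run_crossvalidation(R, ranks=range(2, 9), n_reps=50,
                                 n_folds=5, seed=1)
summary = tf.summarize_rank_selection(records)
print(summary.table[["median_ari", "median_vi", "composite"]].round(3))
print("optimal ranks:", summary.optimal_ranks)
```

Output from this exact run:

```
      median_ari  median_vi  composite
rank
2          1.000      0.000      0.750
3          0.491      0.659      0.027
4          0.585      0.555      0.164
5          1.000      0.000      0.813
6          0.890      0.244      0.702
7          0.844      0.422      0.638
8          0.801      0.553      0.598
optimal ranks: [5]
```

Ranks 2 and 5 reproduce their item partitions perfectly across resampled
fits (aRI = 1, VI = 0) while ranks 3 and 4 are unstable — the planted
two-level structure read straight off the stability profile. The composite
puts rank 5 first and rank 2 second; everything between degrades.

Downstream, `fit_opnmf` at the chosen rank plus `assign_items` give the item
partition; `analyze_subgroups` quantifies how the overall basis transfers to
labeled subgroups; `standardize_scores` → `direction_scan` maps phenotype
predictability over the Big Two plane (on synthetic phenotypes planted at
147°, the scan's peak lands on 147° with FDR-significant accuracy).

Short runnable walkthroughs for each stage live in `examples/`, and
`traitfactor --help` exposes the same stages as a CLI
(`simulate`, `rank-scan`, `fit`, `subgroup`, `direction-scan`,
`compare-targets`, `run`, `report`). A full pipeline run from the bundled
demo configuration:

```bash
traitfactor run --seed 7 --outdir demo_out
```

writes every stage's CSV/JSON artifacts plus a manifest with content hashes;
two runs with the same seed are bit-identical.

## Layout

- `src/traitfactor/synth.py` — planted-structure Likert and phenotype generators
- `src/traitfactor/ingest.py` — CSV loading, reverse scoring, imputation, centering
- `src/traitfactor/opnmf.py` — OPNMF core, projection, RE, item assignment
- `src/traitfactor/modeval.py` — aRI/VI/CI/iRE/IV, CV schemes, rank selection, PCA/EFA baselines
- `src/traitfactor/subgroup.py` — subgroup generalizability, heterogeneity, regressions
- `src/traitfactor/traitspace.py` — Big Two plane, T-PLS, direction scan, bootstrap z
- `src/traitfactor/pipeline.py`, `cli.py` — end-to-end runs, config, manifest, CLI
- `docs/methods.md` — model, numerical choices, and limitations
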