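"""Scan the Big Two plane for predictable trait orientations.

Phenotype features are planted to encode the projection at 147 degrees (the
negative-SA / positive-SM diagonal). The T-PLS scan over 180 directions
recovers the planted angle with FDR-significant accuracy at the peak.
"""

import numpy as np

import traitfactor as tf

rng = np.random.default_rng(5)
S = rng.multivariate_normal([0, 0], [[1, 0.3], [0.3, 1]], size=400)
pheno, _ = tf.simulate_phenotypes(S, theta_true=147, n_features=60,
                                  signal_fraction=0.3, noise_sd=0.5,
                                  family_size=2, seed=5)
scores = tf.standardize_scores(S, family_id=pheno.family_id)

profile, var_peak = tf.direction_variance_profile(scores)
print(f"personality variance peaks at {var_peak} deg "
      "(45 deg is the positive diagonal when the two traits correlate)")

res = tf.direction_scan(pheno, scores, n_reps=3, n_folds=5, n_perm=500,
                        seed=5, K_grid=[1, 2, 3], eta_grid=[0.25, 1.0])
tab = res.table.set_index("angle")
print(f"peak accuracy {res.peak_accuracy:.3f} at {res.peak_angle} deg "
      f"(planted 147), FDR-significant: {bool(tab.loc[res.peak_angle, 'fdr_significant'])}")
print(f"{int(res.table['fdr_significant'].sum())} of 180 directions "
      "FDR-significant at q < 0.05")

y = tf.directional_projection(scores, res.peak_angle)
bz = tf.bootstrap_feature_z(pheno, y, (2, 0.25), n_boot=500, seed=6)
top = bz.reindex(bz["z"].abs().sort_values(ascending=False).index).head(3)
print("most reliable features by bootstrap z:\n",
      top[["feature", "z", "fdr_significant"]].round(2).to_string(index=False))
sig = tf.signature_response(bz, pheno)
print("signature-vs-target correlation:",
      round(float(np.corrcoef(sig, y)[0, 1]), 3))
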