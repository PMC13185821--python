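"""Generate a synthetic Big Five questionnaire with a planted Big Two level.

Builds 60 items in five blocks (N/E/O/A/C) whose latent subject scores are
coupled inside {E, A, C} and inside {N, O}, simulates Likert responses with
noise and reverse-keyed items, and prints what the stored table looks like.
"""

import numpy as np

import traitfactor as tf

truth = tf.build_true_loadings(12, "big2_hier", cross_loading=0.1, seed=1,
                               noise_sd=0.5, missing_rate=0.02)
R, H_true = tf.simulate_responses(truth, 1000)

print("responses:", R.values.shape, "(subjects x items)")
print("item key head:\n", R.item_key.head(3).to_string(index=False))
print("missing cells:", int(R.values.isna().sum().sum()),
      "of", R.values.size, "- inserted uniformly at random")
corr = np.corrcoef(H_true)
iE, iA = 1, 3  # E and A blocks are coupled in the planted Big Two structure
print(f"latent E-A score correlation: {corr[iE, iA]:.2f} "
      "(planted positive coupling inside Social Adaptation)")
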