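import numpy as np
import pytest

import traitfactor as tf

DIM_ORDER = ["N", "E", "O", "A", "C"]


def planted_labels(truth):
    return np.array([DIM_ORDER.index(d) for d in truth.dimension_of_item])


@pytest.fixture(scope="session")
def big5_clean():
    """Noiseless Big Five block data: 20 items, 400 subjects."""
    truth = tf.build_true_loadings(4, "big5", 0.0, seed=1, noise_sd=0.0)
    R, H = tf.simulate_responses(truth, 400)
    Rs = tf.apply_reverse_scoring(R)
    X = tf.impute_missing(Rs)
    return {"truth": truth, "R": Rs, "X": X, "H": H, "labels": planted_labels(truth)}


@pytest.fixture(scope="session")
def big2_noisy():
    """Hierarchical Big Two data with realistic noise: 20 items, 600 subjects."""
    truth = tf.build_true_loadings(4, "big2_hier", 0.1, seed=3, noise_sd=0.5)
    R, H = tf.simulate_responses(truth, 600)
    Rs = tf.apply_reverse_scoring(R)
    return {"truth": truth, "R": Rs, "X": tf.impute_missing(Rs), "H": H,
            "labels": planted_labels(truth)}


@pytest.fixture(scope="session")
def planted_phenotypes():
    """Correlated 2D scores + features planted at 91 degrees, 300 subjects."""
    rng = np.random.default_rng(8)
    S = rng.multivariate_normal([0, 0], [[1, 0.3], [0.3, 1]], size=300)
    pheno, w = tf.simulate_phenotypes(
        S, 91, 60, signal_fraction=5 / 60, noise_sd=0.0, family_size=2, seed=8
    )
    scores = tf.standardize_scores(S, family_id=pheno.family_id)
    return {"S": S, "pheno": pheno, "w_true": w, "scores": scores}
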