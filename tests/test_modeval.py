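"""Evaluation indices against independent oracles; CV framework; baselines."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import traitfactor as tf
from traitfactor.modeval import (
    concordance_index,
    fit_linear_baseline,
    increased_reconstruction_error,
    item_variability,
    records_to_frame,
    split_poles,
    summarize_rank_selection,
)

# ---------------------------------------------------------------------------
# independent oracles (pair counting / explicit entropies / straight-line CCC)
# ---------------------------------------------------------------------------

def ari_pair_counting(l1, l2):
    """Hubert-Arabie aRI by brute-force enumeration of item pairs."""
    n = len(l1)
    a = b = c = d = 0
    for i, j in itertools.combinations(range(n), 2):
        s1, s2 = l1[i] == l1[j], l2[i] == l2[j]
        if s1 and s2:
            a += 1
        elif s1 and not s2:
            b += 1
        elif not s1 and s2:
            c += 1
        else:
            d += 1
    total = a + b + c + d
    expected = (a + b) * (a + c) / total
    max_index = 0.5 * ((a + b) + (a + c))
    if max_index == expected:
        return 1.0
    return (a - expected) / (max_index - expected)


def vi_entropy_oracle(l1, l2):
    """VI from explicitly enumerated joint probabilities (nats)."""
    n = len(l1)
    h1 = -sum(
        (np.sum(np.array(l1) == u) / n) * np.log(np.sum(np.array(l1) == u) / n)
        for u in set(l1)
    )
    h2 = -sum(
        (np.sum(np.array(l2) == u) / n) * np.log(np.sum(np.array(l2) == u) / n)
        for u in set(l2)
    )
    mi = 0.0
    for u in set(l1):
        for v in set(l2):
            pij = np.mean((np.array(l1) == u) & (np.array(l2) == v))
            if pij > 0:
                pi = np.mean(np.array(l1) == u)
                pj = np.mean(np.array(l2) == v)
                mi += pij * np.log(pij / (pi * pj))
    return h1 + h2 - 2 * mi


def ccc_oracle(x, y):
    mx, my = np.mean(x), np.mean(y)
    return 2 * np.mean((x - mx) * (y - my)) / (np.var(x) + np.var(y) + (mx - my) ** 2)


# ---------------------------------------------------------------------------
# index unit tests
# ---------------------------------------------------------------------------

def test_ari_known_values_match_oracle():
    assert tf.adjusted_rand_index([1, 1, 2, 2], [1, 1, 2, 2]) == 1.0
    assert tf.adjusted_rand_index([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(-0.5)
    assert ari_pair_counting([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(-0.5)
    assert tf.adjusted_rand_index([1, 1, 1, 1], [1, 1, 2, 2]) == pytest.approx(0.0)
    assert ari_pair_counting([1, 1, 1, 1], [1, 1, 2, 2]) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        tf.adjusted_rand_index([1, 2], [1, 2, 3])


def test_vi_known_values_match_oracle():
    assert tf.variation_of_information([1, 1, 2, 2], [1, 1, 2, 2]) == 0.0
    assert tf.variation_of_information([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(
        2 * np.log(2)
    )
    assert tf.variation_of_information([1, 1, 2, 2], [1, 1, 1, 1]) == pytest.approx(
        np.log(2)
    )
    assert vi_entropy_oracle([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(2 * np.log(2))


@settings(max_examples=100, derandomize=True, deadline=None)
@given(
    st.lists(st.integers(0, 3), min_size=2, max_size=12),
    st.data(),
)
def test_ari_vi_agree_with_oracles_and_are_symmetric(l1, data):
    l2 = data.draw(st.lists(st.integers(0, 3), min_size=len(l1), max_size=len(l1)))
    vi = tf.variation_of_information(l1, l2)
    assert vi == pytest.approx(vi_entropy_oracle(l1, l2), abs=1e-12)
    assert vi == pytest.approx(tf.variation_of_information(l2, l1), abs=1e-12)
    assert vi >= 0
    ari = tf.adjusted_rand_index(l1, l2)
    assert ari == pytest.approx(tf.adjusted_rand_index(l2, l1), abs=1e-12)
    if len(set(l1)) > 1 and len(set(l2)) > 1:
        assert ari == pytest.approx(ari_pair_counting(l1, l2), abs=1e-12)


def test_vi_triangle_inequality_on_random_triples():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n = rng.integers(4, 15)
        a, b, c = (rng.integers(0, 4, n) for _ in range(3))
        assert tf.variation_of_information(a, c) <= (
            tf.variation_of_information(a, b) + tf.variation_of_information(b, c) + 1e-10
        )


def test_concordance_index_identity_permutation_and_oracle():
    rng = np.random.default_rng(3)
    W1 = np.abs(rng.normal(size=(20, 3)))
    assert concordance_index(W1, W1) == pytest.approx(1.0)
    assert concordance_index(W1, W1[:, [2, 0, 1]]) == pytest.approx(1.0)
    W2 = np.abs(rng.normal(size=(20, 3)))
    iu = np.triu_indices(20, k=1)

    def cosmat(W):
        U = W / np.linalg.norm(W, axis=1, keepdims=True)
        return (U @ U.T)[iu]

    assert concordance_index(W1, W2) == pytest.approx(
        ccc_oracle(cosmat(W1), cosmat(W2)), abs=1e-12
    )
    assert concordance_index(W1, W2) == pytest.approx(concordance_index(W2, W1))
    with pytest.raises(ValueError):
        concordance_index(W1, W2[:-1])


def test_concordance_index_rank_mismatch_allowed():
    rng = np.random.default_rng(4)
    W1 = np.abs(rng.normal(size=(15, 2)))
    W2 = np.abs(rng.normal(size=(15, 5)))
    assert -1 <= concordance_index(W1, W2) <= 1


def test_ire_identities(big5_clean):
    X = big5_clean["X"]
    model = tf.fit_opnmf(X, 5)
    assert increased_reconstruction_error(model.W, model.W, X) == 0.0
    # a fitted basis is locally optimal on its own data
    rng = np.random.default_rng(2)
    for seed in range(5):
        other = np.abs(rng.normal(size=model.W.shape))
        other /= np.linalg.norm(other, axis=0)
        assert increased_reconstruction_error(other, model.W, X) >= -1e-6


def test_item_variability_by_enumeration():
    p1 = [0, 0, 1, 1]  # factors: {0,1}, {2,3}
    p2 = [0, 1, 0, 1]  # factors: {0,2}, {1,3}
    iv = item_variability([p1, p2])
    assert np.allclose(iv, 2 / 3)  # J = 1/3 for every item here
    assert np.allclose(item_variability([p1, p1]), 0.0)
    singleton = [0, 1, 1]
    assert item_variability([singleton, singleton])[0] == 0.0
    with pytest.raises(ValueError):
        item_variability([p1])


def test_run_crossvalidation_identical_populations(big5_clean):
    truth = big5_clean["truth"]
    Ra, _ = tf.simulate_responses(truth, 300)
    Rb, _ = tf.simulate_responses(truth, 300)
    rec = tf.run_crossvalidation(
        tf.apply_reverse_scoring(Ra), ranks=[5], scheme="cross_sample_bootstrap",
        n_reps=3, R2=tf.apply_reverse_scoring(Rb), seed=0,
    )
    assert all(r.ari == 1.0 for r in rec)
    assert all(abs(r.ire) < 0.01 for r in rec)


def test_group_stratified_folds_never_split_groups(big2_noisy):
    R = big2_noisy["R"]
    rng = np.random.default_rng(1)
    R.subject_meta["culture"] = rng.choice([f"c{i}" for i in range(10)], size=600)
    from traitfactor.utils import make_folds

    folds = make_folds(600, 4, np.random.default_rng(0),
                       groups=R.subject_meta["culture"].to_numpy())
    for tr, te in folds:
        tr_groups = set(R.subject_meta["culture"].iloc[tr])
        te_groups = set(R.subject_meta["culture"].iloc[te])
        assert not (tr_groups & te_groups)
    rec = tf.run_crossvalidation(R, ranks=[2], scheme="group_stratified_kfold",
                                 group_field="culture", n_reps=1, n_folds=4, seed=0)
    assert len(rec) == 4
    R.subject_meta["one"] = "same"
    with pytest.raises(ValueError):
        tf.run_crossvalidation(R, ranks=[2], scheme="group_stratified_kfold",
                               group_field="one", n_reps=1, n_folds=4, seed=0)


def test_records_frame_is_long_format(big2_noisy):
    rec = tf.run_crossvalidation(big2_noisy["R"], ranks=[2, 3], n_reps=1,
                                 n_folds=3, seed=2)
    df = records_to_frame(rec)
    assert set(df.columns) == {"repetition", "fold", "rank", "index", "value"}
    assert len(df) == len(rec) * 4


def test_summarize_rank_selection_rules(big2_noisy):
    rec = tf.run_crossvalidation(big2_noisy["R"], ranks=[2, 3, 4], n_reps=2,
                                 n_folds=3, seed=3)
    summary = summarize_rank_selection(rec, n_boot=50, seed=0)
    comp = summary.composite
    assert ((comp >= 0) & (comp <= 1)).all()
    assert summary.optimal_ranks  # non-empty
    assert set(summary.iv_per_rank) == {2, 3, 4}
    for iv in summary.iv_per_rank.values():
        assert ((iv >= 0) & (iv <= 1)).all()
    with pytest.raises(ValueError):
        summarize_rank_selection([r for r in rec if r.rank == 2])


def test_degenerate_index_contributes_half():
    from traitfactor.modeval import _normalize_across_ranks
    import pandas as pd

    med = pd.DataFrame(
        {"ari": [0.5, 0.5], "vi": [1.0, 2.0], "ci": [0.1, 0.9], "ire": [0.0, 0.0]},
        index=[2, 3],
    )
    norm = _normalize_across_ranks(med)
    assert (norm["ari"] == 0.5).all()
    assert (norm["ire"] == 0.5).all()
    assert norm.loc[2, "vi"] == 1.0  # lower VI is better


def test_pca_baseline_recovers_blocks_and_is_orthogonal(big5_clean):
    L, part = fit_linear_baseline(big5_clean["X"], 5, method="pca")
    assert tf.adjusted_rand_index(part.labels, big5_clean["labels"]) == 1.0
    G = L.T @ L
    assert np.abs(G - np.diag(np.diag(G))).max() < 1e-8


def test_efa_baseline_recovers_blocks(big5_clean):
    L, part = fit_linear_baseline(big5_clean["X"], 5, method="efa")
    assert tf.adjusted_rand_index(part.labels, big5_clean["labels"]) == 1.0


def test_split_poles():
    L = np.array([[0.5, 0.2], [-0.3, 0.4], [0.0, -0.1]])
    poles = split_poles(L)
    assert poles[0] == ([0], [1])
    assert poles[1] == ([0, 1], [2])
    flipped = split_poles(-L)
    assert flipped[0] == ([1], [0])
    all_pos = split_poles(np.abs(L[:2]))
    assert all_pos[0][1] == []


def test_per_fold_imputation_matches_full_when_no_missing(big5_clean):
    full = tf.run_crossvalidation(big5_clean["R"], ranks=[5], n_reps=1,
                                  n_folds=3, seed=6)
    per_fold = tf.run_crossvalidation(big5_clean["R"], ranks=[5], n_reps=1,
                                      n_folds=3, seed=6, impute_per_fold=True)
    assert [r.ari for r in full] == [r.ari for r in per_fold]
    assert [r.ire for r in full] == [r.ire for r in per_fold]


def test_per_fold_imputation_runs_with_missing_cells():
    truth = tf.build_true_loadings(4, "big5", 0.0, seed=8, noise_sd=0.3,
                                   missing_rate=0.1)
    R, _ = tf.simulate_responses(truth, 300)
    rec = tf.run_crossvalidation(tf.apply_reverse_scoring(R), ranks=[5],
                                 n_reps=1, n_folds=3, seed=0,
                                 impute_per_fold=True)
    assert all(r.ari > 0.8 for r in rec)
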