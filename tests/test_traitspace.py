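"""Big Two plane: projections, variance profile, T-PLS, scan, bootstrap."""

import numpy as np
import pandas as pd
import pytest

import traitfactor as tf
from traitfactor.traitspace import (
    PhenotypeMatrix,
    _fit_tpls_fixed,
    threshold_count,
)


def test_standardize_scores_contract():
    rng = np.random.default_rng(0)
    S = rng.normal([3, -2], [4, 0.5], size=(50, 2))
    z = tf.standardize_scores(S)
    assert np.abs(z.values.mean(axis=0)).max() < 1e-10
    assert np.abs(z.values.std(axis=0) - 1).max() < 1e-10
    # affine invariance
    z2 = tf.standardize_scores(S * 7.0 + 11.0)
    assert np.allclose(z.values, z2.values)
    with pytest.raises(ValueError):
        tf.standardize_scores(S[:2])
    with pytest.raises(ValueError):
        tf.standardize_scores(np.column_stack([S[:, 0], np.ones(50)]))


def test_directional_projection_axis_cases():
    rng = np.random.default_rng(1)
    z = tf.standardize_scores(rng.normal(size=(100, 2)))
    assert np.allclose(tf.directional_projection(z, 90), z.values[:, 1])
    assert np.allclose(tf.directional_projection(z, 180), -z.values[:, 0])
    with pytest.raises(ValueError):
        tf.directional_projection(z, 0)
    with pytest.raises(ValueError):
        tf.directional_projection(z, 181)


def test_projection_linearity_and_orthogonality():
    rng = np.random.default_rng(2)
    raw = rng.normal(size=(200, 2))
    # exactly orthogonalize in-sample
    q, _ = np.linalg.qr(raw - raw.mean(0))
    z = tf.standardize_scores(q)
    for theta in (30, 77, 147):
        p = tf.directional_projection(z, theta)
        expect = (
            np.cos(np.deg2rad(theta)) * z.values[:, 0]
            + np.sin(np.deg2rad(theta)) * z.values[:, 1]
        )
        assert np.allclose(p, expect)
        p90 = tf.directional_projection(z, theta + 90 if theta + 90 <= 180 else theta - 90)
        assert abs(np.corrcoef(p, p90)[0, 1]) < 1e-10


def test_variance_profile_matches_closed_form():
    rng = np.random.default_rng(3)
    for rho, peak_expect in ((0.4, 45), (-0.4, 135)):
        A = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=400)
        # force the empirical correlation to exactly rho
        q, _ = np.linalg.qr(A - A.mean(0))
        q /= q.std(0)
        B = np.column_stack([q[:, 0], rho * q[:, 0] + np.sqrt(1 - rho**2) * q[:, 1]])
        z = tf.standardize_scores(B)
        prof, peak = tf.direction_variance_profile(z)
        th = np.deg2rad(prof.index.to_numpy(dtype=float))
        closed = np.sqrt(1 + rho * np.sin(2 * th))
        assert np.abs(prof.to_numpy() - closed).max() < 1e-12
        assert peak == peak_expect
    with pytest.raises(ValueError):
        tf.direction_variance_profile(tf.standardize_scores(rng.normal(size=(50, 2))), [])


def test_tpls_equals_plain_pls_at_eta_one():
    from sklearn.cross_decomposition import PLSRegression

    rng = np.random.default_rng(4)
    n, p = 150, 25
    X = rng.standard_normal((n, p))
    y = X[:, :4] @ np.array([1.5, -2.0, 0.5, 1.0]) + 0.2 * rng.standard_normal(n)
    for K in (1, 2, 3, 5, 8):
        ours = _fit_tpls_fixed(X, y, K, 1.0)
        sk = PLSRegression(n_components=K, scale=True).fit(X, y)
        assert np.abs(ours.predict(X) - sk.predict(X).ravel()).max() < 1e-8


def test_tpls_threshold_count_is_exact():
    rng = np.random.default_rng(5)
    X = rng.standard_normal((100, 40))
    y = rng.standard_normal(100)
    for eta in (0.05, 0.1, 0.33, 0.5, 1.0):
        model = _fit_tpls_fixed(X, y, 3, eta)
        assert model.n_nonzero <= threshold_count(eta, 40)
        # generic data: no exact zero coefficients before thresholding
        assert model.n_nonzero == threshold_count(eta, 40)


def test_fit_tpls_recovers_planted_sparse_weights(planted_phenotypes):
    d = planted_phenotypes
    y = tf.directional_projection(d["scores"], 91)
    model = tf.fit_tpls(d["pheno"], y, K_grid=[1, 2, 3, 5],
                        eta_grid=[5 / 60, 0.25, 1.0], seed=1)
    chosen = set(np.where(model.beta != 0)[0])
    truth = set(np.where(d["w_true"] != 0)[0])
    assert truth <= chosen
    assert np.corrcoef(model.predict(d["pheno"]), y)[0, 1] > 0.99
    with pytest.raises(ValueError):
        tf.fit_tpls(d["pheno"], y, K_grid=[500])
    with pytest.raises(ValueError):
        tf.fit_tpls(d["pheno"], y, K_grid=[])


def test_direction_scan_recovers_planted_angle(planted_phenotypes):
    d = planted_phenotypes
    res = tf.direction_scan(d["pheno"], d["scores"], n_reps=2, n_folds=5,
                            n_perm=200, seed=2, K_grid=[1, 2], eta_grid=[0.25, 1.0])
    assert sorted(res.table["angle"]) == list(range(1, 181))
    assert abs(res.peak_angle - 91) <= 10
    tab = res.table.set_index("angle")
    assert tab.loc[res.peak_angle, "fdr_significant"]
    assert tab.loc[res.peak_angle, "accuracy"] > 0.95
    assert (res.table["p_value"] >= 1 / 201).all()
    with pytest.raises(ValueError):
        tf.direction_scan(d["pheno"], d["scores"], n_perm=0)


def test_perfect_features_give_near_perfect_accuracy_at_90():
    rng = np.random.default_rng(6)
    S = rng.normal(size=(200, 2))
    z = tf.standardize_scores(S)
    y90 = tf.directional_projection(z, 90)
    F = PhenotypeMatrix(values=pd.DataFrame({"exact": y90, "noise": rng.normal(size=200)}))
    res = tf.direction_scan(F, z, n_reps=1, n_folds=5, n_perm=50, seed=3,
                            K_grid=[1], eta_grid=[0.5, 1.0])
    assert res.table.set_index("angle").loc[90, "accuracy"] > 0.99


def test_bootstrap_z_contract(planted_phenotypes):
    d = planted_phenotypes
    y = tf.directional_projection(d["scores"], 91)
    bz = tf.bootstrap_feature_z(d["pheno"], y, (2, 0.25), n_boot=200, seed=4)
    truth = set(np.where(d["w_true"] != 0)[0])
    assert int(bz["z"].abs().idxmax()) in truth
    bz2 = tf.bootstrap_feature_z(d["pheno"], y, (2, 0.25), n_boot=200, seed=4)
    assert np.array_equal(bz["z"], bz2["z"])  # seed-reproducible
    assert ((bz["p_value"] >= 0) & (bz["p_value"] <= 1)).all()
    with pytest.raises(ValueError):
        tf.bootstrap_feature_z(d["pheno"], y, (2, 0.25), n_boot=10)


def test_signature_response_linearity(planted_phenotypes):
    d = planted_phenotypes
    F = d["pheno"]
    z = np.zeros(60)
    assert np.allclose(tf.signature_response(z, F), 0.0)
    z[7] = 1.0
    Fs = (F.values - F.values.mean()) / F.values.std(ddof=1)
    assert np.allclose(tf.signature_response(z, F), Fs.iloc[:, 7])
    assert np.allclose(tf.signature_response(2 * z, F), 2 * tf.signature_response(z, F))
    with pytest.raises(ValueError):
        tf.signature_response(z[:-1], F)


def test_correlate_signatures(planted_phenotypes):
    d = planted_phenotypes
    traits = pd.DataFrame(
        {"SA": d["scores"].values[:, 0], "SM": d["scores"].values[:, 1],
         "flat": np.ones(300)}
    )
    out = tf.correlate_signatures(traits["SM"].to_numpy(), traits).set_index("trait")
    assert out.loc["SM", "r"] == pytest.approx(1.0)
    assert out.loc["flat", "undefined"]
    rng = np.random.default_rng(8)
    noise = rng.normal(size=300)
    out2 = tf.correlate_signatures(noise, traits[["SA", "SM"]]).set_index("trait")
    assert out2["r"].abs().max() < 0.15


def test_compare_targets_contract(planted_phenotypes):
    d = planted_phenotypes
    y = tf.directional_projection(d["scores"], 91)
    T = pd.DataFrame({"a": y, "b": y, "sa": d["scores"].values[:, 0]})
    comp = tf.compare_targets(d["pheno"], T, n_reps=2, n_folds=4, seed=5,
                              K_grid=[1, 2], eta_grid=[0.25, 1.0])
    assert comp.weight_similarity.loc["a", "b"] == pytest.approx(1.0)
    assert len(comp.accuracies) == 3 * 2 * 4  # targets x reps x folds
    dup = pd.DataFrame(np.column_stack([y, y]), columns=["x", "x"])
    with pytest.raises(ValueError, match="duplicate"):
        tf.compare_targets(d["pheno"], dup, n_reps=1, n_folds=3)


def test_disjoint_feature_targets_have_uncorrelated_weights():
    rng = np.random.default_rng(9)
    n, p = 300, 40
    u = rng.standard_normal(n)
    v = rng.standard_normal(n)
    F = rng.standard_normal((n, p))
    F[:, :5] = np.outer(u, np.ones(5)) + 0.2 * rng.standard_normal((n, 5))
    F[:, 5:10] = np.outer(v, np.ones(5)) + 0.2 * rng.standard_normal((n, 5))
    Fm = PhenotypeMatrix(values=pd.DataFrame(F, columns=[f"f{i}" for i in range(p)]))
    T = pd.DataFrame({"u": u, "v": v})
    comp = tf.compare_targets(Fm, T, n_reps=1, n_folds=3, seed=6,
                              K_grid=[1, 2], eta_grid=[0.25, 1.0])
    assert abs(comp.weight_similarity.loc["u", "v"]) < 0.3
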