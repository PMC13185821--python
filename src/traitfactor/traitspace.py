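"""The 2D Big Two trait space and directional predictive modeling.

Subjects are embedded in a plane spanned by the two broad traits (Social
Adaptation on the x-axis at 0 degrees, Spontaneous Mentation on the y-axis at
90 degrees, counterclockwise). A direction theta defines a scalar target
score p_i = cos(theta) * SA_i + sin(theta) * SM_i for each subject; scanning
theta over 1..180 degrees and predicting each target from a phenotype feature
table with thresholded partial least squares (T-PLS) maps which trait
orientations carry predictable signal. Significance per direction comes from
permutation tests with Benjamini-Hochberg FDR across the 180 angles; feature
reliability comes from bootstrap z-scores of the T-PLS coefficients.

The PLS core is a Krylov-subspace formulation of univariate PLS (PLS1): the
K-component PLS1 coefficient vector is the least-squares minimizer restricted
to the Krylov space span{b, Ab, ..., A^(K-1) b} with A = Xs'Xs and b = Xs'y.
This runs on Gram matrices only and is batched across the 180 directions,
which is what makes the permutation scan tractable. T-PLS sparsifies the
back-projected coefficient vector to its ceil(eta * p) largest-magnitude
entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .utils import bh_fdr, derive_seed, make_folds

_EPS = 1e-12


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeMatrix:
    """Subjects x features table with a domain tag and optional family ids."""

    values: pd.DataFrame
    domain: str = "synthetic"
    family_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("phenotype matrix contains missing values")
        if self.family_id is not None:
            self.family_id = np.asarray(self.family_id)
            if len(self.family_id) != len(self.values):
                raise ValueError("family_id length does not match subject count")

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class TraitScores2D:
    """Per-subject (SA, SM) coordinates; angle 0 = +SA, 90 = +SM."""

    values: np.ndarray  # subjects x 2
    standardized: bool = False
    family_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 2:
            raise ValueError("trait scores must be subjects x 2 (SA, SM)")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]


@dataclass
class TPLSModel:
    """Fitted thresholded-PLS model (coefficients in standardized feature space)."""

    n_components: int
    eta: float
    beta: np.ndarray
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    cv_scores: pd.DataFrame | None = None
    feature_names: list = field(default_factory=list)

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.beta))

    def predict(self, F) -> np.ndarray:
        X = _feature_array(F)
        Xs = (X - self.x_mean) / self.x_std
        return Xs @ self.beta + self.y_mean


@dataclass
class DirectionScanResult:
    """Per-angle predictive accuracy, permutation p, FDR flag, and peak angle."""

    table: pd.DataFrame  # angle, accuracy, accuracy_sd, K, eta, p_value, fdr_significant
    peak_angle: int
    n_perm: int
    alpha_fdr: float

    @property
    def peak_accuracy(self) -> float:
        return float(self.table.set_index("angle").loc[self.peak_angle, "accuracy"])


# ---------------------------------------------------------------------------
# scores and projections
# ---------------------------------------------------------------------------

def _feature_array(F) -> np.ndarray:
    if isinstance(F, PhenotypeMatrix):
        return F.values.to_numpy(dtype=float)
    if isinstance(F, pd.DataFrame):
        return F.to_numpy(dtype=float)
    return np.asarray(F, dtype=float)


def standardize_scores(raw, family_id=None) -> TraitScores2D:
    """Z-score each axis of raw (SA, SM) scores."""
    if isinstance(raw, TraitScores2D):
        family_id = raw.family_id if family_id is None else family_id
        raw = raw.values
    S = np.asarray(raw, dtype=float)
    if S.ndim != 2 or S.shape[1] != 2:
        raise ValueError("raw scores must be subjects x 2")
    if S.shape[0] < 3:
        raise ValueError("need at least 3 subjects to standardize")
    sd = S.std(axis=0)
    if (sd < _EPS).any():
        raise ValueError("zero-variance axis cannot be standardized")
    Z = (S - S.mean(axis=0)) / sd
    return TraitScores2D(values=Z, standardized=True, family_id=family_id)


def directional_projection(scores: TraitScores2D, theta_deg: float) -> np.ndarray:
    """p_i = cos(theta) * SA_i + sin(theta) * SM_i for theta in (0, 180] degrees."""
    if not 0 < theta_deg <= 180:
        raise ValueError("theta must be in (0, 180] degrees")
    if not scores.standardized:
        raise ValueError("standardize scores before projecting (standardize_scores)")
    th = np.deg2rad(theta_deg)
    return np.cos(th) * scores.values[:, 0] + np.sin(th) * scores.values[:, 1]


def direction_variance_profile(scores: TraitScores2D, angles=None):
    """Empirical SD of the directional projection per angle, plus the peak angle.

    For exactly z-scored axes with correlation rho the population profile is
    sqrt(1 + rho * sin(2 theta)), peaking at 45 degrees for rho > 0 and at
    135 degrees for rho < 0.
    """
    if angles is None:
        angles = np.arange(1, 181)
    angles = np.asarray(list(angles), dtype=float)
    if angles.size == 0:
        raise ValueError("empty angle list")
    if not scores.standardized:
        raise ValueError("standardize scores first")
    th = np.deg2rad(angles)
    P = scores.values @ np.vstack([np.cos(th), np.sin(th)])
    sd = P.std(axis=0)
    profile = pd.Series(sd, index=angles.astype(int), name="sd")
    peak = int(profile.idxmax())
    return profile, peak


# ---------------------------------------------------------------------------
# Krylov PLS1 engine (batched over target columns)
# ---------------------------------------------------------------------------

def _standardize_train(X: np.ndarray, tr: np.ndarray):
    mu = X[tr].mean(axis=0)
    sd = X[tr].std(axis=0, ddof=1)
    sd = np.where(sd < _EPS, 1.0, sd)
    return mu, sd


def _krylov_bases(A: np.ndarray, B: np.ndarray, kmax: int):
    """Orthonormal Krylov bases of span{b, Ab, ...} for every column b of B.

    Returns V (kmax, p, q) with orthonormal columns per problem and
    AV (kmax, p, q) = A @ V[k]. Exhausted directions are zero vectors.
    """
    p, q = B.shape
    V = np.zeros((kmax, p, q))
    AV = np.zeros((kmax, p, q))
    nb = np.linalg.norm(B, axis=0)
    alive = nb > _EPS
    v = np.where(alive, B / np.where(alive, nb, 1.0), 0.0)
    V[0] = v
    AV[0] = A @ v
    for k in range(1, kmax):
        w = AV[k - 1].copy()
        for _ in range(2):  # re-orthogonalize for stability
            for j in range(k):
                w -= V[j] * (V[j] * w).sum(axis=0)
        nw = np.linalg.norm(w, axis=0)
        alive = nw > 1e-10 * np.maximum(nb, 1.0)
        V[k] = np.where(alive, w / np.where(alive, nw, 1.0), 0.0)
        AV[k] = A @ V[k]
    return V, AV


def _betas_for_k(V, AV, B, k: int) -> np.ndarray:
    """Batched K-component PLS1 coefficients (p x q) from Krylov bases."""
    p, q = B.shape
    Vk, AVk = V[:k], AV[:k]
    M = np.einsum("ipq,jpq->qij", Vk, AVk)
    c = np.einsum("ipq,pq->qi", Vk, B)
    M = M + 1e-12 * np.eye(k)[None, :, :]
    coef = np.linalg.solve(M, c[:, :, None])[:, :, 0]
    return np.einsum("kpq,qk->pq", Vk, coef)


def threshold_count(eta: float, p: int) -> int:
    """Number of coefficients retained at fraction eta: ceil(eta * p)."""
    return int(np.ceil(eta * p - 1e-12))


def _threshold_beta(beta: np.ndarray, keep: np.ndarray) -> np.ndarray:
    """Zero all but the top keep[q] coefficients by |value| in each column."""
    rank_desc = (-np.abs(beta)).argsort(axis=0).argsort(axis=0)
    return np.where(rank_desc < keep[None, :], beta, 0.0)


def _batched_pearson(Y: np.ndarray, Yhat: np.ndarray) -> np.ndarray:
    """Columnwise Pearson r between Y and Yhat (zero-variance columns -> 0)."""
    Yc = Y - Y.mean(axis=0)
    Hc = Yhat - Yhat.mean(axis=0)
    num = (Yc * Hc).sum(axis=0)
    den = np.linalg.norm(Yc, axis=0) * np.linalg.norm(Hc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > _EPS, num / np.maximum(den, _EPS), 0.0)
    return r


def _grid_cv_scores(X, Y, folds, K_grid, eta_grid):
    """Mean out-of-fold Pearson r for every (K, eta) and target column.

    Returns an array (nK, nEta, q) averaged over folds.
    """
    nK, nEta, q = len(K_grid), len(eta_grid), Y.shape[1]
    p = X.shape[1]
    keep_all = np.array([threshold_count(e, p) for e in eta_grid])
    acc = np.zeros((nK, nEta, q))
    kmax = max(K_grid)
    for tr, te in folds:
        mu, sd = _standardize_train(X, tr)
        Xs_tr = (X[tr] - mu) / sd
        Xs_te = (X[te] - mu) / sd
        A = Xs_tr.T @ Xs_tr
        Bmat = Xs_tr.T @ Y[tr]
        V, AV = _krylov_bases(A, Bmat, kmax)
        for ik, K in enumerate(K_grid):
            beta = _betas_for_k(V, AV, Bmat, K)
            for ie in range(nEta):
                keep = np.full(q, keep_all[ie])
                bt = beta if keep_all[ie] >= p else _threshold_beta(beta, keep)
                acc[ik, ie] += _batched_pearson(Y[te], Xs_te @ bt)
    return acc / len(folds)


def _select_combo(scores_kq: np.ndarray):
    """Argmax over the (K, eta) grid, ties to the first combo (K asc, eta asc)."""
    nK, nEta = scores_kq.shape[:2]
    flat = scores_kq.reshape(nK * nEta, -1)
    best = flat.argmax(axis=0)
    return best // nEta, best % nEta


def _validate_grids(K_grid, eta_grid, n, p):
    if K_grid is None:
        K_grid = [k for k in (1, 2, 3, 5, 8, 13, 20, 25) if k <= min(n - 1, p)]
    K_grid = sorted(int(k) for k in K_grid)
    if not K_grid:
        raise ValueError("empty K grid")
    if K_grid[-1] > min(n - 1, p):
        raise ValueError(f"K={K_grid[-1]} exceeds min(n-1, p)={min(n - 1, p)}")
    if K_grid[0] < 1:
        raise ValueError("K must be >= 1")
    if eta_grid is None:
        eta_grid = [round(0.05 * i, 2) for i in range(1, 21)]
    eta_grid = sorted(float(e) for e in eta_grid)
    if not eta_grid:
        raise ValueError("empty eta grid")
    if eta_grid[0] <= 0 or eta_grid[-1] > 1:
        raise ValueError("eta values must be in (0, 1]")
    return K_grid, eta_grid


def fit_tpls(
    F,
    y,
    K_grid=None,
    eta_grid=None,
    n_folds: int = 5,
    family_id=None,
    seed: int = 0,
) -> TPLSModel:
    """Fit T-PLS with (K, eta) chosen by grouped inner cross-validation.

    Features are column-standardized internally and y centered; for each
    (K, eta) the inner-CV Pearson correlation between held-out targets and
    predictions is scored, the best combination is selected (ties to the
    smallest K, then smallest eta), and the model is refitted on all data.
    """
    X = _feature_array(F)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError("y length does not match subject count")
    if family_id is None and isinstance(F, PhenotypeMatrix):
        family_id = F.family_id
    K_grid, eta_grid = _validate_grids(K_grid, eta_grid, n, p)

    rng = np.random.default_rng([seed, 131])
    folds = make_folds(n, n_folds, rng, groups=family_id)
    scores = _grid_cv_scores(X, y[:, None], folds, K_grid, eta_grid)
    ik, ie = _select_combo(scores)
    K, eta = K_grid[int(ik[0])], eta_grid[int(ie[0])]

    cv_table = pd.DataFrame(
        [(K_grid[a], eta_grid[b], scores[a, b, 0]) for a in range(len(K_grid)) for b in range(len(eta_grid))],
        columns=["K", "eta", "cv_r"],
    )
    model = _fit_tpls_fixed(X, y, K, eta)
    model.cv_scores = cv_table
    model.feature_names = list(F.feature_names) if isinstance(F, PhenotypeMatrix) else []
    return model


def _fit_tpls_fixed(X: np.ndarray, y: np.ndarray, K: int, eta: float) -> TPLSModel:
    n, p = X.shape
    tr = np.arange(n)
    mu, sd = _standardize_train(X, tr)
    Xs = (X - mu) / sd
    b = Xs.T @ y
    A = Xs.T @ Xs
    V, AV = _krylov_bases(A, b[:, None], K)
    beta = _betas_for_k(V, AV, b[:, None], K)[:, 0]
    keep = threshold_count(eta, p)
    if keep < p:
        beta = _threshold_beta(beta[:, None], np.array([keep]))[:, 0]
    return TPLSModel(
        n_components=K,
        eta=eta,
        beta=beta,
        x_mean=mu,
        x_std=sd,
        y_mean=float(y.mean()),
    )


# ---------------------------------------------------------------------------
# the 180-direction scan
# ---------------------------------------------------------------------------

def _angle_targets(scores: TraitScores2D, angles: np.ndarray) -> np.ndarray:
    th = np.deg2rad(angles.astype(float))
    return scores.values @ np.vstack([np.cos(th), np.sin(th)])


def direction_scan(
    F,
    scores: TraitScores2D,
    n_reps: int = 30,
    n_folds: int = 5,
    n_perm: int = 5000,
    alpha_fdr: float = 0.05,
    seed: int = 0,
    K_grid=None,
    eta_grid=None,
    inner_folds: int = 3,
) -> DirectionScanResult:
    """Predictive accuracy of T-PLS over the 180 directional targets.

    Accuracy per angle is the mean out-of-fold Pearson r over n_reps
    repetitions of n_folds-fold CV, with (K, eta) selected by nested inner CV
    within each training fold. The permutation null permutes target values
    across subjects and recomputes a single CV pass at the per-angle modal
    (K, eta); p = (1 + #{null >= observed}) / (1 + n_perm), followed by
    Benjamini-Hochberg FDR across the 180 angles.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = _feature_array(F)
    n, p = X.shape
    if not scores.standardized:
        scores = standardize_scores(scores.values, family_id=scores.family_id)
    if scores.n_subjects != n:
        raise ValueError("scores and features cover different subject counts")
    family_id = scores.family_id
    if family_id is None and isinstance(F, PhenotypeMatrix):
        family_id = F.family_id
    if K_grid is None:
        K_grid = [k for k in (1, 2, 3, 5, 8) if k <= min(n - 1, p)]
    if eta_grid is None:
        eta_grid = [0.1, 0.25, 0.5, 1.0]
    K_grid, eta_grid = _validate_grids(K_grid, eta_grid, n, p)

    angles = np.arange(1, 181)
    Y = _angle_targets(scores, angles)  # n x 180
    q = Y.shape[1]
    keep_eta = np.array([threshold_count(e, p) for e in eta_grid])

    # --- phase 1: nested-CV accuracy ----------------------------------------
    acc_values = np.zeros((n_reps * n_folds, q))
    combo_votes = np.zeros((len(K_grid) * len(eta_grid), q), dtype=int)
    row = 0
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, 211, rep])
        folds = make_folds(n, n_folds, rng, groups=family_id)
        for tr, te in folds:
            inner_rng = np.random.default_rng([seed, 223, rep, row])
            inner = make_folds(
                len(tr), min(inner_folds, max(2, len(tr) // 2)), inner_rng,
                groups=None if family_id is None else family_id[tr],
            )
            sel = _grid_cv_scores(X[tr], Y[tr], inner, K_grid, eta_grid)
            ik, ie = _select_combo(sel)
            combo_votes[ik * len(eta_grid) + ie, np.arange(q)] += 1

            mu, sd = _standardize_train(X, tr)
            Xs_tr = (X[tr] - mu) / sd
            Xs_te = (X[te] - mu) / sd
            A = Xs_tr.T @ Xs_tr
            Bmat = Xs_tr.T @ Y[tr]
            V, AV = _krylov_bases(A, Bmat, max(K_grid))
            beta = np.empty((p, q))
            for a, K in enumerate(K_grid):
                cols = np.where(ik == a)[0]
                if cols.size:
                    beta[:, cols] = _betas_for_k(V[:, :, cols], AV[:, :, cols], Bmat[:, cols], K)
            beta = _threshold_beta(beta, keep_eta[ie])
            acc_values[row] = _batched_pearson(Y[te], Xs_te @ beta)
            row += 1

    accuracy = acc_values.mean(axis=0)
    accuracy_sd = acc_values.std(axis=0, ddof=1) if acc_values.shape[0] > 1 else np.zeros(q)
    modal_combo = combo_votes.argmax(axis=0)
    modal_K = np.array([K_grid[c // len(eta_grid)] for c in modal_combo])
    modal_eta = np.array([eta_grid[c % len(eta_grid)] for c in modal_combo])
    modal_keep = np.array([threshold_count(e, p) for e in modal_eta])

    # --- phase 2: permutation null at fixed per-angle hyperparameters -------
    perm_rng = np.random.default_rng([seed, 227])
    folds = make_folds(n, n_folds, perm_rng, groups=family_id)
    preps = []
    for tr, te in folds:
        mu, sd = _standardize_train(X, tr)
        preps.append((tr, te, (X[tr] - mu) / sd, (X[te] - mu) / sd))
    A_by_fold = [Xs_tr.T @ Xs_tr for _, _, Xs_tr, _ in preps]
    kmax = int(modal_K.max())
    k_groups = {K: np.where(modal_K == K)[0] for K in np.unique(modal_K)}

    exceed = np.zeros(q)
    for _ in range(n_perm):
        perm = perm_rng.permutation(n)
        Yp = Y[perm]
        null_acc = np.zeros(q)
        for (tr, te, Xs_tr, Xs_te), A in zip(preps, A_by_fold):
            Bmat = Xs_tr.T @ Yp[tr]
            V, AV = _krylov_bases(A, Bmat, kmax)
            beta = np.empty((p, q))
            for K, cols in k_groups.items():
                beta[:, cols] = _betas_for_k(V[:, :, cols], AV[:, :, cols], Bmat[:, cols], K)
            beta = _threshold_beta(beta, modal_keep)
            null_acc += _batched_pearson(Yp[te], Xs_te @ beta)
        null_acc /= len(preps)
        exceed += null_acc >= accuracy
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    fdr = bh_fdr(pvals, alpha_fdr)

    table = pd.DataFrame(
        {
            "angle": angles,
            "accuracy": accuracy,
            "accuracy_sd": accuracy_sd,
            "K": modal_K,
            "eta": modal_eta,
            "p_value": pvals,
            "fdr_significant": fdr,
        }
    )
    peak = int(angles[accuracy.argmax()])
    return DirectionScanResult(table=table, peak_angle=peak, n_perm=n_perm, alpha_fdr=alpha_fdr)


# ---------------------------------------------------------------------------
# bootstrap feature reliability, signatures, target comparison
# ---------------------------------------------------------------------------

def bootstrap_feature_z(
    F,
    y,
    model_spec,
    n_boot: int = 5000,
    seed: int = 0,
    alpha_fdr: float = 0.05,
) -> pd.DataFrame:
    """Bootstrap z-scores of T-PLS coefficients at fixed (K, eta).

    Subjects are resampled with replacement, the model refitted, and
    z_j = mean_b(beta_jb) / SD_b(beta_jb) (z = 0 where the SD is zero, e.g.
    for constant features). Two-tailed normal p-values are FDR-corrected
    across features.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    X = _feature_array(F)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if isinstance(model_spec, TPLSModel):
        K, eta = model_spec.n_components, model_spec.eta
    else:
        K, eta = int(model_spec[0]), float(model_spec[1])
    rng = np.random.default_rng([seed, 311])
    betas = np.empty((n_boot, p))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        betas[b] = _fit_tpls_fixed(X[idx], y[idx], K, eta).beta
    mean_b = betas.mean(axis=0)
    sd_b = betas.std(axis=0, ddof=1)
    z = np.where(sd_b > _EPS, mean_b / np.where(sd_b > _EPS, sd_b, 1.0), 0.0)
    pvals = 2.0 * sps.norm.sf(np.abs(z))
    names = F.feature_names if isinstance(F, PhenotypeMatrix) else [f"feat{j}" for j in range(p)]
    return pd.DataFrame(
        {
            "feature": names,
            "z": z,
            "p_value": pvals,
            "fdr_significant": bh_fdr(pvals, alpha_fdr),
            "mean_beta": mean_b,
            "sd_beta": sd_b,
            "degenerate": sd_b <= _EPS,
        }
    )


def signature_response(z_weights, F) -> np.ndarray:
    """Per-subject dot product of z-weights with column-standardized features."""
    X = _feature_array(F)
    if isinstance(z_weights, pd.DataFrame):
        z = z_weights["z"].to_numpy(dtype=float)
    else:
        z = np.asarray(z_weights, dtype=float).ravel()
    if len(z) != X.shape[1]:
        raise ValueError(f"{len(z)} weights for {X.shape[1]} features")
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd < _EPS, 1.0, sd)
    Xs = (X - X.mean(axis=0)) / sd
    return Xs @ z


def correlate_signatures(signatures, trait_scores: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between signature responses and each trait column."""
    s = np.asarray(signatures, dtype=float).ravel()
    if len(s) != len(trait_scores):
        raise ValueError("signatures and trait scores cover different subjects")
    rows = []
    for col in trait_scores.columns:
        t = trait_scores[col].to_numpy(dtype=float)
        if t.std() < _EPS or s.std() < _EPS:
            rows.append({"trait": col, "r": np.nan, "undefined": True})
        else:
            rows.append({"trait": col, "r": float(np.corrcoef(s, t)[0, 1]), "undefined": False})
    return pd.DataFrame(rows)


@dataclass
class TargetComparison:
    accuracies: pd.DataFrame  # target, repetition, fold, r
    weight_similarity: pd.DataFrame  # targets x targets Pearson r of coefficients
    models: dict


def compare_targets(
    F,
    targets: pd.DataFrame,
    n_reps: int = 30,
    n_folds: int = 5,
    seed: int = 0,
    K_grid=None,
    eta_grid=None,
    family_id=None,
    inner_folds: int = 3,
) -> TargetComparison:
    """Identical CV protocol for several named targets, plus weight similarity.

    Each target column gets n_reps x n_folds out-of-fold accuracies with
    nested hyperparameter selection; weight similarity is the Pearson
    correlation between the full-data T-PLS coefficient vectors of each pair.
    """
    if targets.columns.duplicated().any():
        dup = targets.columns[targets.columns.duplicated()].tolist()
        raise ValueError(f"duplicate target names: {dup}")
    X = _feature_array(F)
    n, p = X.shape
    if len(targets) != n:
        raise ValueError("targets and features cover different subjects")
    if family_id is None and isinstance(F, PhenotypeMatrix):
        family_id = F.family_id
    if K_grid is None:
        K_grid = [k for k in (1, 2, 3, 5, 8) if k <= min(n - 1, p)]
    if eta_grid is None:
        eta_grid = [0.1, 0.25, 0.5, 1.0]
    K_grid, eta_grid = _validate_grids(K_grid, eta_grid, n, p)
    keep_eta = np.array([threshold_count(e, p) for e in eta_grid])

    Y = targets.to_numpy(dtype=float)
    q = Y.shape[1]
    rows = []
    fold_row = 0
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, 401, rep])
        folds = make_folds(n, n_folds, rng, groups=family_id)
        for fold_i, (tr, te) in enumerate(folds):
            inner_rng = np.random.default_rng([seed, 409, rep, fold_row])
            inner = make_folds(
                len(tr), min(inner_folds, max(2, len(tr) // 2)), inner_rng,
                groups=None if family_id is None else family_id[tr],
            )
            sel = _grid_cv_scores(X[tr], Y[tr], inner, K_grid, eta_grid)
            ik, ie = _select_combo(sel)
            mu, sd = _standardize_train(X, tr)
            Xs_tr = (X[tr] - mu) / sd
            Xs_te = (X[te] - mu) / sd
            A = Xs_tr.T @ Xs_tr
            Bmat = Xs_tr.T @ Y[tr]
            V, AV = _krylov_bases(A, Bmat, max(K_grid))
            beta = np.empty((p, q))
            for a, K in enumerate(K_grid):
                cols = np.where(ik == a)[0]
                if cols.size:
                    beta[:, cols] = _betas_for_k(V[:, :, cols], AV[:, :, cols], Bmat[:, cols], K)
            beta = _threshold_beta(beta, keep_eta[ie])
            r = _batched_pearson(Y[te], Xs_te @ beta)
            for t_i, name in enumerate(targets.columns):
                rows.append({"target": name, "repetition": rep, "fold": fold_i, "r": r[t_i]})
            fold_row += 1

    models = {
        name: fit_tpls(X, Y[:, t_i], K_grid=K_grid, eta_grid=eta_grid,
                       n_folds=n_folds, family_id=family_id, seed=derive_seed(seed, 419, t_i))
        for t_i, name in enumerate(targets.columns)
    }
    W = np.column_stack([models[name].beta for name in targets.columns])
    sim = np.corrcoef(W.T)
    sim_df = pd.DataFrame(sim, index=targets.columns, columns=targets.columns)
    return TargetComparison(
        accuracies=pd.DataFrame(rows), weight_similarity=sim_df, models=models
    )
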