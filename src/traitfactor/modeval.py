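"""Cross-validated evaluation of factor decompositions.

Stability and generalizability of an item-level decomposition are scored by
five indices computed between models fitted independently on a main sample
(k-1 folds) and a hold sample (1 fold):

* aRI — chance-adjusted agreement of the two hard item partitions;
* VI  — variation of information between the partitions (nats);
* CI  — Lin's concordance between the item-item cosine-similarity matrices
        of the two basis matrices (loading-pattern agreement);
* iRE — increase in normalized reconstruction error on the hold data when
        the main-sample basis replaces the hold-sample basis;
* IV  — per-item instability of factor affiliation across the resampled
        partitions (one minus the mean pairwise Jaccard overlap of the item
        sets the item is assigned to).

Each repetition reshuffles the folds; medians over repetitions x folds
summarize each rank, and an oriented, min-max-normalized composite of
aRI/VI/CI/iRE selects the optimal rank(s). PCA and principal-axis EFA
baselines can be swapped in for the same protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score, mutual_info_score

from .ingest import ResponseMatrix, impute_missing
from .opnmf import Partition, assign_items, fit_opnmf, reconstruction_error
from .utils import make_folds


# ---------------------------------------------------------------------------
# evaluation indices
# ---------------------------------------------------------------------------

def _labels(p) -> np.ndarray:
    if isinstance(p, Partition):
        return np.asarray(p.labels)
    return np.asarray(p)


def _check_same_items(l1, l2) -> None:
    if len(l1) != len(l2):
        raise ValueError(f"partitions cover different item sets ({len(l1)} vs {len(l2)})")


def adjusted_rand_index(p1, p2) -> float:
    """Hubert-Arabie adjusted Rand index between two item partitions."""
    l1, l2 = _labels(p1), _labels(p2)
    _check_same_items(l1, l2)
    return float(adjusted_rand_score(l1, l2))


def variation_of_information(p1, p2) -> float:
    """VI = H(p1) + H(p2) - 2 I(p1; p2) in nats; 0 iff identical partitions."""
    l1, l2 = _labels(p1), _labels(p2)
    _check_same_items(l1, l2)
    h1 = sps.entropy(np.bincount(np.unique(l1, return_inverse=True)[1]))
    h2 = sps.entropy(np.bincount(np.unique(l2, return_inverse=True)[1]))
    mi = mutual_info_score(l1, l2)
    return float(max(h1 + h2 - 2.0 * mi, 0.0))


def _cosine_matrix(W: np.ndarray) -> np.ndarray:
    """Item x item cosine similarities of loading rows (zero rows -> 0)."""
    norms = np.linalg.norm(W, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    U = W / safe[:, None]
    S = U @ U.T
    S[norms == 0, :] = 0.0
    S[:, norms == 0] = 0.0
    return S


def _lin_ccc(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient (population moments)."""
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = ((x - mx) * (y - my)).mean()
    denom = vx + vy + (mx - my) ** 2
    if denom <= 0:
        return 1.0 if np.allclose(x, y) else 0.0
    return float(2.0 * cov / denom)


def concordance_index(W1, W2, method: str = "ccc", absolute: bool = False) -> float:
    """Agreement between the item-item cosine-similarity matrices of two bases.

    ``absolute=True`` compares |loading| cosine matrices (for signed PCA/EFA
    loadings, where polarity would conflate with structure). Ranks may differ.
    """
    A1 = np.asarray(W1, dtype=float)
    A2 = np.asarray(W2, dtype=float)
    if A1.shape[0] != A2.shape[0]:
        raise ValueError(f"item counts differ ({A1.shape[0]} vs {A2.shape[0]})")
    if absolute:
        A1, A2 = np.abs(A1), np.abs(A2)
    iu = np.triu_indices(A1.shape[0], k=1)
    s1 = _cosine_matrix(A1)[iu]
    s2 = _cosine_matrix(A2)[iu]
    if method == "ccc":
        return _lin_ccc(s1, s2)
    if method == "pearson":
        return float(np.corrcoef(s1, s2)[0, 1])
    raise ValueError(f"unknown concordance method {method!r}")


def increased_reconstruction_error(W_train, W_test, X_test) -> float:
    """iRE = RE(W_train, X_test) - RE(W_test, X_test), both normalized."""
    return reconstruction_error(W_train, X_test) - reconstruction_error(W_test, X_test)


def item_variability(partitions) -> np.ndarray:
    """Per-item instability of factor affiliation across partitions.

    For item i and partitions (A, B): J = |S_A(i) & S_B(i)| / |S_A(i) | S_B(i)|
    where S_P(i) is the set of items sharing i's factor in P;
    IV_i = 1 - mean(J) over all unordered pairs.
    """
    parts = [_labels(p) for p in partitions]
    if len(parts) < 2:
        raise ValueError("item_variability needs at least 2 partitions")
    m = len(parts[0])
    for p in parts:
        _check_same_items(parts[0], p)
    acc = np.zeros(m)
    n_pairs = 0
    for a in range(len(parts)):
        la = parts[a]
        for b in range(a + 1, len(parts)):
            lb = parts[b]
            # contingency-based Jaccard: J(i) depends only on (la[i], lb[i])
            ka, kb = la.max() + 1, lb.max() + 1
            cont = np.zeros((ka, kb))
            np.add.at(cont, (la, lb), 1.0)
            size_a = cont.sum(axis=1)
            size_b = cont.sum(axis=0)
            inter = cont[la, lb]
            union = size_a[la] + size_b[lb] - inter
            acc += inter / union
            n_pairs += 1
    return 1.0 - acc / n_pairs


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVRecord:
    repetition: int
    fold: int
    rank: int
    ari: float
    vi: float
    ci: float
    ire: float
    partition_hold: np.ndarray = field(repr=False, default=None)


@dataclass
class CVSummary:
    table: pd.DataFrame  # per-rank medians, normalized indices, composite, CI
    composite: pd.Series
    optimal_ranks: list
    iv_per_rank: dict  # rank -> per-item IV vector
    n_records: int

    def to_json_dict(self) -> dict:
        return {
            "per_rank": self.table.reset_index().to_dict(orient="records"),
            "optimal_ranks": [int(r) for r in self.optimal_ranks],
            "n_records": int(self.n_records),
        }


def _prepare_X(R) -> np.ndarray:
    if isinstance(R, ResponseMatrix):
        if not R.reverse_scored:
            raise ValueError("apply_reverse_scoring before cross-validation")
        return impute_missing(R).X
    from .ingest import DataMatrixX

    if isinstance(R, DataMatrixX):
        return R.X
    return np.asarray(R, dtype=float)


def _fit_partition(X, rank, method, max_iter, tol, svd=None, gram=None):
    """Fit one model on X (items x subjects); return (loadings, labels)."""
    if method == "opnmf":
        model = fit_opnmf(X, rank, max_iter=max_iter, tol=tol, _gram=gram, _svd=svd)
        return model.W, assign_items(model).labels
    loadings, part = fit_linear_baseline(X, rank, method=method)
    return loadings, part.labels


def _baseline_re(loadings, X_hold_centered) -> float:
    """Normalized RE from projecting row-centered data on the loading span."""
    Q, _ = np.linalg.qr(loadings)
    R = X_hold_centered - Q @ (Q.T @ X_hold_centered)
    denom = max(float(np.linalg.norm(X_hold_centered)), 1e-16)
    return float(np.linalg.norm(R)) / denom


def run_crossvalidation(
    R,
    ranks=tuple(range(2, 9)),
    scheme: str = "kfold",
    n_reps: int = 1000,
    n_folds: int = 5,
    seed: int = 0,
    method: str = "opnmf",
    group_field: str | None = None,
    R2=None,
    max_iter: int = 50_000,
    tol: float = 1e-5,
    impute_per_fold: bool = False,
) -> list[CVRecord]:
    """Repeated main/hold-sample evaluation at each rank.

    Per repetition the folds are reshuffled; per fold, models are fitted
    independently on the main sample (k-1 folds) and hold sample (1 fold)
    and compared by aRI/VI/CI, plus iRE of the main basis on the hold data.
    ``scheme='group_stratified_kfold'`` keeps all subjects sharing
    ``group_field`` in the same fold; ``'cross_sample_bootstrap'`` resamples
    subjects from R (main) and R2 (hold), which must share items. Missing
    cells are item-mean imputed once on the full table by default;
    ``impute_per_fold=True`` recomputes the item means within each sample
    instead (no cross-fold leakage, slower).
    """
    X = _prepare_X(R)
    ranks = [int(r) for r in ranks]
    n_subjects = X.shape[1]

    groups = None
    if scheme == "group_stratified_kfold":
        if not isinstance(R, ResponseMatrix) or R.subject_meta is None or group_field is None:
            raise ValueError("group_stratified_kfold needs subject metadata and group_field")
        groups = R.subject_meta[group_field].to_numpy()
        if len(np.unique(groups)) < 2:
            raise ValueError("group_stratified_kfold needs at least 2 groups")
        if len(np.unique(groups)) < n_folds:
            raise ValueError("fewer groups than folds")
    X2 = None
    if scheme == "cross_sample_bootstrap":
        if R2 is None:
            raise ValueError("cross_sample_bootstrap needs a second response table R2")
        X2 = _prepare_X(R2)
        if X2.shape[0] != X.shape[0]:
            raise ValueError("the two samples must share the same items")
    elif scheme != "kfold" and scheme != "group_stratified_kfold":
        raise ValueError(f"unknown scheme {scheme!r}")

    if scheme != "cross_sample_bootstrap" and n_subjects // n_folds < max(ranks):
        raise ValueError("folds too small for the largest rank")

    def _subsample(Xfull, source, idx):
        if not (impute_per_fold and isinstance(source, ResponseMatrix)):
            return Xfull[:, idx]
        A = source.values.to_numpy(dtype=float)[idx]
        mu = np.nanmean(A, axis=0)
        r_i, c_i = np.where(np.isnan(A))
        A[r_i, c_i] = mu[c_i]
        return A.T

    records: list[CVRecord] = []
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, 59, rep])
        if scheme == "cross_sample_bootstrap":
            main_idx = rng.integers(0, X.shape[1], size=X.shape[1])
            hold_idx = rng.integers(0, X2.shape[1], size=X2.shape[1])
            splits = [(main_idx, hold_idx)]
        else:
            splits = make_folds(n_subjects, n_folds, rng, groups=groups)

        for fold_i, (main_idx, hold_idx) in enumerate(splits):
            X_main = _subsample(X, R, main_idx)
            X_hold = (
                _subsample(X2, R2, hold_idx)
                if X2 is not None
                else _subsample(X, R, hold_idx)
            )
            if method == "opnmf":
                svd_m = np.linalg.svd(X_main, full_matrices=False)
                svd_h = np.linalg.svd(X_hold, full_matrices=False)
                gram_m = X_main @ X_main.T
                gram_h = X_hold @ X_hold.T
            else:
                Xc_hold = X_hold - X_hold.mean(axis=1, keepdims=True)
            for rank in ranks:
                if method == "opnmf":
                    Wm, lm = _fit_partition(X_main, rank, method, max_iter, tol, svd_m, gram_m)
                    Wh, lh = _fit_partition(X_hold, rank, method, max_iter, tol, svd_h, gram_h)
                    ci = concordance_index(Wm, Wh)
                    ire = increased_reconstruction_error(Wm, Wh, X_hold)
                else:
                    Wm, lm = _fit_partition(X_main, rank, method, max_iter, tol)
                    Wh, lh = _fit_partition(X_hold, rank, method, max_iter, tol)
                    ci = concordance_index(Wm, Wh, absolute=True)
                    ire = _baseline_re(Wm, Xc_hold) - _baseline_re(Wh, Xc_hold)
                records.append(
                    CVRecord(
                        repetition=rep,
                        fold=fold_i,
                        rank=rank,
                        ari=adjusted_rand_index(lm, lh),
                        vi=variation_of_information(lm, lh),
                        ci=ci,
                        ire=ire,
                        partition_hold=lh,
                    )
                )
    return records


def records_to_frame(records) -> pd.DataFrame:
    """Long-format table (repetition, fold, rank, index, value)."""
    rows = []
    for r in records:
        for name in ("ari", "vi", "ci", "ire"):
            rows.append((r.repetition, r.fold, r.rank, name, getattr(r, name)))
    return pd.DataFrame(rows, columns=["repetition", "fold", "rank", "index", "value"])


_UP = ("ari", "ci")
_DOWN = ("vi", "ire")


def _normalize_across_ranks(medians: pd.DataFrame) -> pd.DataFrame:
    """Orient (higher-better) then min-max normalize each index across ranks.

    A degenerate (constant) index contributes 0.5 at every rank.
    """
    out = {}
    for name in (*_UP, *_DOWN):
        v = medians[name].to_numpy(dtype=float)
        if name in _DOWN:
            v = -v
        rng = v.max() - v.min()
        out[name] = np.full_like(v, 0.5) if rng < 1e-12 else (v - v.min()) / rng
    return pd.DataFrame(out, index=medians.index)


def summarize_rank_selection(records, n_boot: int = 200, seed: int = 0) -> CVSummary:
    """Per-rank medians, normalized composite with bootstrap 95% CI, optimal ranks."""
    df = pd.DataFrame(
        [(r.rank, r.ari, r.vi, r.ci, r.ire) for r in records],
        columns=["rank", "ari", "vi", "ci", "ire"],
    )
    ranks = sorted(df["rank"].unique())
    if len(ranks) < 2:
        raise ValueError("rank selection needs records for at least 2 ranks")
    medians = df.groupby("rank").median()
    norm = _normalize_across_ranks(medians)
    composite = norm.mean(axis=1)

    rng = np.random.default_rng([seed, 101])
    by_rank = {rk: df[df["rank"] == rk].reset_index(drop=True) for rk in ranks}
    boots = np.empty((n_boot, len(ranks)))
    for b in range(n_boot):
        med_b = {}
        for rk in ranks:
            sub = by_rank[rk]
            take = rng.integers(0, len(sub), size=len(sub))
            med_b[rk] = sub.iloc[take][["ari", "vi", "ci", "ire"]].median()
        med_b = pd.DataFrame(med_b).T
        boots[b] = _normalize_across_ranks(med_b).mean(axis=1).to_numpy()
    ci_low = np.percentile(boots, 2.5, axis=0)
    ci_high = np.percentile(boots, 97.5, axis=0)

    iv_per_rank = {}
    for rk in ranks:
        parts = [r.partition_hold for r in records if r.rank == rk and r.partition_hold is not None]
        if len(parts) >= 2:
            iv_per_rank[rk] = item_variability(parts)

    table = medians.copy()
    table.columns = [f"median_{c}" for c in table.columns]
    for c in norm.columns:
        table[f"norm_{c}"] = norm[c]
    table["composite"] = composite
    table["composite_ci_low"] = ci_low
    table["composite_ci_high"] = ci_high
    if iv_per_rank:
        table["mean_iv"] = [iv_per_rank.get(rk, np.array([np.nan])).mean() for rk in ranks]

    best = composite.max()
    optimal = [int(rk) for rk in ranks if composite.loc[rk] >= best - 1e-12]
    return CVSummary(
        table=table,
        composite=composite,
        optimal_ranks=optimal,
        iv_per_rank=iv_per_rank,
        n_records=len(records),
    )


# ---------------------------------------------------------------------------
# PCA / EFA baselines
# ---------------------------------------------------------------------------

def _varimax(L: np.ndarray) -> np.ndarray:
    from statsmodels.multivariate.factor_rotation import rotate_factors

    L_rot, _ = rotate_factors(L, "varimax")
    return L_rot


def fit_linear_baseline(X, rank: int, method: str = "pca"):
    """Signed linear-baseline loadings plus a partition by maximal |loading|.

    PCA: singular vectors of the item-centered data, scaled by singular
    values. EFA: principal-axis factoring of the item correlation matrix with
    varimax rotation.
    """
    from .opnmf import _as_matrix

    Xm = _as_matrix(X)
    m, n = Xm.shape
    if not 1 <= rank <= min(m, n):
        raise ValueError(f"rank must be in [1, {min(m, n)}]")
    Xc = Xm - Xm.mean(axis=1, keepdims=True)

    if method == "pca":
        U, s, _ = np.linalg.svd(Xc, full_matrices=False)
        from .opnmf import _fix_signs

        U = _fix_signs(U[:, :rank])
        loadings = U * (s[:rank] / np.sqrt(max(n - 1, 1)))
    elif method == "efa":
        sd = Xc.std(axis=1, ddof=1)
        sd[sd == 0] = 1.0
        Rm = (Xc / sd[:, None]) @ (Xc / sd[:, None]).T / max(n - 1, 1)
        np.fill_diagonal(Rm, 1.0)
        loadings = _principal_axis(Rm, rank)
        if rank > 1:
            loadings = _varimax(loadings)
        from .opnmf import _fix_signs

        loadings = _fix_signs(loadings)
    else:
        raise ValueError(f"unknown baseline method {method!r}")

    labels = np.argmax(np.abs(loadings), axis=1)
    winning = loadings[np.arange(m), labels]
    return loadings, Partition(labels=labels, winning_loading=winning)


def _principal_axis(Rm: np.ndarray, rank: int, max_iter: int = 200, tol: float = 1e-6):
    """Iterated principal-axis factoring with SMC-initialized communalities."""
    m = Rm.shape[0]
    try:
        inv = np.linalg.inv(Rm + 1e-10 * np.eye(m))
        h2 = 1.0 - 1.0 / np.diag(inv)
    except np.linalg.LinAlgError:
        h2 = np.full(m, 0.5)
    h2 = np.clip(h2, 0.0, 1.0)
    for it in range(max_iter):
        Ra = Rm.copy()
        np.fill_diagonal(Ra, h2)
        vals, vecs = np.linalg.eigh(Ra)
        order = np.argsort(vals)[::-1][:rank]
        lam = np.clip(vals[order], 0.0, None)
        L = vecs[:, order] * np.sqrt(lam)
        h2_new = np.clip((L**2).sum(axis=1), 0.0, 1.0)
        if np.max(np.abs(h2_new - h2)) < tol:
            return L
        h2 = h2_new
    raise ValueError(
        f"EFA communalities did not converge within {max_iter} iterations "
        f"(last max change {np.max(np.abs(h2_new - h2)):.2e})"
    )


def split_poles(signed_loadings) -> dict:
    """Per-factor positive/negative item index lists; zero loadings excluded."""
    L = np.asarray(signed_loadings, dtype=float)
    out = {}
    for j in range(L.shape[1]):
        col = L[:, j]
        out[j] = (
            [int(i) for i in np.where(col > 0)[0]],
            [int(i) for i in np.where(col < 0)[0]],
        )
    return out
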