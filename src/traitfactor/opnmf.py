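"""Orthogonal projective non-negative matrix factorization (OPNMF).

Approximates a non-negative items x subjects matrix X as W @ W.T @ X with a
non-negative, approximately orthonormal basis W (items x rank). The
multiplicative update

    W <- W * (C W) / (W (W' C W)),   C = X X'

followed by division of W by its spectral norm each iteration, monotonically
decreases ||X - W W' X||_F in practice. Because the objective depends on X
only through the item-level Gram matrix C, the per-iteration cost is
independent of the number of subjects once C is formed, which makes the
repeated cross-validated fits of the evaluation framework cheap.

The projective parameterization gives out-of-sample factor scores H = W' X_new
directly, so a basis learned in one sample transfers to held-out data without
refitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ingest import DataMatrixX

_EPS = 1e-16


@dataclass
class FactorModel:
    W: np.ndarray  # items x rank, non-negative, unit-norm columns after finalization
    rank: int
    objective_trace: np.ndarray
    n_iter: int
    converged: bool
    normalization: np.ndarray  # column scaling removed at finalization
    init: str = "nndsvd"
    seed: int | None = None

    @property
    def n_items(self) -> int:
        return self.W.shape[0]


@dataclass
class Partition:
    """Hard item -> factor assignment by maximal loading."""

    labels: np.ndarray  # factor index per item
    winning_loading: np.ndarray
    item_ids: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.labels)


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, DataMatrixX):
        return X.X
    return np.asarray(X, dtype=float)


def _spectral_norm(W: np.ndarray) -> float:
    return float(np.linalg.svd(W, compute_uv=False)[0])


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Resolve SVD sign ambiguity deterministically (largest-|entry| positive)."""
    flip = U[np.abs(U).argmax(axis=0), np.arange(U.shape[1])] < 0
    U = U.copy()
    U[:, flip] *= -1
    return U


def nndsvd_init(X: np.ndarray, rank: int, svd=None) -> np.ndarray:
    """Non-negative double SVD initialization (deterministic).

    Zeros are filled with mean(X)/100 so multiplicative updates can move
    every entry.
    """
    if svd is None:
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
    else:
        U, s, Vt = svd
    U = _fix_signs(U[:, :rank])
    Vt = _fix_signs(Vt[:rank].T).T
    s = s[:rank]
    m = X.shape[0]
    W = np.zeros((m, rank))
    W[:, 0] = np.sqrt(s[0]) * np.abs(U[:, 0])
    for j in range(1, rank):
        u, v = U[:, j], Vt[j]
        up, un = np.clip(u, 0, None), np.clip(-u, 0, None)
        vp, vn = np.clip(v, 0, None), np.clip(-v, 0, None)
        nup, nun, nvp, nvn = map(np.linalg.norm, (up, un, vp, vn))
        termp, termn = nup * nvp, nun * nvn
        if termp >= termn and nup > 0:
            W[:, j] = np.sqrt(s[j] * termp) * up / nup
        elif nun > 0:
            W[:, j] = np.sqrt(s[j] * termn) * un / nun
    fill = max(X.mean() / 100.0, _EPS)
    W[W <= 0] = fill
    return W


def _random_init(X: np.ndarray, rank: int, seed) -> np.ndarray:
    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(X.mean(), _EPS))
    return rng.uniform(0.1, 1.0, size=(X.shape[0], rank)) * scale


def _opnmf_core_numpy(C: np.ndarray, W0: np.ndarray, max_iter: int, tol: float):
    """Multiplicative updates on the item Gram matrix C = X X'."""
    trC = float(np.trace(C))
    W = W0 / max(_spectral_norm(W0), _EPS)
    trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        CW = C @ W
        WtCW = W.T @ CW
        obj2 = trC - 2.0 * float(np.trace(WtCW)) + float(((W.T @ W) * WtCW).sum())
        trace.append(np.sqrt(max(obj2, 0.0)))
        Wn = W * (CW / (W @ WtCW + _EPS))
        Wn /= max(_spectral_norm(Wn), _EPS)
        dW = np.linalg.norm(Wn - W) / max(np.linalg.norm(W), _EPS)
        W = Wn
        if dW < tol:
            converged = True
            break
    CW = C @ W
    WtCW = W.T @ CW
    obj2 = trC - 2.0 * float(np.trace(WtCW)) + float(((W.T @ W) * WtCW).sum())
    trace.append(np.sqrt(max(obj2, 0.0)))
    return W, np.asarray(trace), it, converged


try:  # compiled inner loop: the update is tiny (m x r matmuls) and
    # interpreter overhead would otherwise dominate the repeated CV fits
    from numba import njit

    @njit(cache=True)
    def _opnmf_core_nb(C, W0, max_iter, tol, eps):  # pragma: no cover - thin kernel
        trC = np.trace(C)
        G = W0.T @ W0
        s = np.sqrt(max(np.linalg.eigvalsh(G)[-1], eps))
        W = W0 / max(s, eps)
        trace = np.empty(max_iter + 2)
        n_rec = 0
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            CW = C @ W
            WtCW = W.T @ CW
            G = W.T @ W
            obj2 = trC - 2.0 * np.trace(WtCW) + np.sum(G * WtCW)
            trace[n_rec] = np.sqrt(max(obj2, 0.0))
            n_rec += 1
            Wn = W * CW / (W @ WtCW + eps)
            Gn = Wn.T @ Wn
            sn = np.sqrt(max(np.linalg.eigvalsh(Gn)[-1], eps))
            Wn = Wn / sn
            dW = np.sqrt(np.sum((Wn - W) ** 2)) / max(np.sqrt(np.sum(W**2)), eps)
            W = Wn
            if dW < tol:
                converged = True
                break
        CW = C @ W
        WtCW = W.T @ CW
        G = W.T @ W
        obj2 = trC - 2.0 * np.trace(WtCW) + np.sum(G * WtCW)
        trace[n_rec] = np.sqrt(max(obj2, 0.0))
        n_rec += 1
        return W, trace[:n_rec].copy(), it, converged

    def _opnmf_core(C, W0, max_iter, tol):
        W, trace, it, converged = _opnmf_core_nb(
            np.ascontiguousarray(C), np.ascontiguousarray(W0), max_iter, tol, _EPS
        )
        return W, trace, it, converged

except ImportError:  # pragma: no cover
    _opnmf_core = _opnmf_core_numpy


def fit_opnmf(
    X,
    rank: int,
    init: str = "nndsvd",
    max_iter: int = 50_000,
    tol: float = 1e-5,
    seed: int | None = None,
    _gram: np.ndarray | None = None,
    _svd=None,
) -> FactorModel:
    """Fit OPNMF at the given rank.

    ``tol`` is on the relative Frobenius change of W between iterations.
    ``_gram`` and ``_svd`` allow callers that fit many ranks on the same data
    to reuse X X' and the SVD used by the NNDSVD initialization.
    """
    Xm = _as_matrix(X)
    if np.isnan(Xm).any():
        raise ValueError("X contains missing entries")
    if (Xm < 0).any():
        raise ValueError("X contains negative entries")
    m, n = Xm.shape
    if not 1 <= rank <= min(m, n):
        raise ValueError(f"rank must be in [1, {min(m, n)}], got {rank}")

    if init == "nndsvd":
        W0 = nndsvd_init(Xm, rank, svd=_svd)
    elif init == "random":
        W0 = _random_init(Xm, rank, seed)
    else:
        raise ValueError(f"unknown init {init!r}; expected 'nndsvd' or 'random'")

    C = _gram if _gram is not None else Xm @ Xm.T
    W, trace, n_iter, converged = _opnmf_core(C, W0, max_iter, tol)

    norms = np.linalg.norm(W, axis=0)
    norms[norms == 0] = 1.0
    Wf = W / norms
    return FactorModel(
        W=Wf,
        rank=rank,
        objective_trace=trace,
        n_iter=n_iter,
        converged=converged,
        normalization=norms,
        init=init,
        seed=seed,
    )


def project_scores(model: FactorModel, X_new) -> np.ndarray:
    """Out-of-sample factor scores H = W' X_new (rank x subjects)."""
    Xm = _as_matrix(X_new)
    if Xm.ndim == 1:
        Xm = Xm[:, None]
    if Xm.shape[0] != model.n_items:
        raise ValueError(
            f"X_new has {Xm.shape[0]} items but the model expects {model.n_items}"
        )
    return model.W.T @ Xm


def reconstruction_error(model, X, normalized: bool = True) -> float:
    """||X - W W' X||_F, divided by ||X||_F when normalized."""
    W = model.W if isinstance(model, FactorModel) else np.asarray(model, dtype=float)
    Xm = _as_matrix(X)
    if Xm.shape[0] != W.shape[0]:
        raise ValueError(f"X has {Xm.shape[0]} items but W has {W.shape[0]} rows")
    R = Xm - W @ (W.T @ Xm)
    err = float(np.linalg.norm(R))
    if normalized:
        err /= max(float(np.linalg.norm(Xm)), _EPS)
    return err


def assign_items(model, item_ids: list | None = None) -> Partition:
    """Per-item argmax over basis columns; ties go to the lowest factor index."""
    W = model.W if isinstance(model, FactorModel) else np.asarray(model, dtype=float)
    labels = np.argmax(W, axis=1)
    winning = W[np.arange(W.shape[0]), labels]
    return Partition(labels=labels, winning_loading=winning, item_ids=item_ids or [])


def save_model(model: FactorModel, outdir, item_ids=None, extra_meta=None):
    """Serialize W as CSV plus a JSON metadata sidecar."""
    import json
    from pathlib import Path

    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cols = [f"factor{j + 1}" for j in range(model.rank)]
    idx = item_ids if item_ids else [f"item{i:03d}" for i in range(model.n_items)]
    w_path = outdir / f"W_rank{model.rank}.csv"
    pd.DataFrame(model.W, index=idx, columns=cols).to_csv(w_path, index_label="item_id")
    meta = {
        "rank": model.rank,
        "n_iter": model.n_iter,
        "converged": bool(model.converged),
        "init": model.init,
        "seed": model.seed,
        "final_objective": float(model.objective_trace[-1]),
    }
    if extra_meta:
        meta.update(extra_meta)
    meta_path = outdir / f"W_rank{model.rank}.json"
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    return {"W": str(w_path), "meta": str(meta_path)}
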