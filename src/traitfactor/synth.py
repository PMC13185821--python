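"""Synthetic Likert questionnaire and phenotype generators.

The generators plant the statistical structure the downstream analysis
assumes: non-negative item loadings in five blocks (one per Big Five
dimension, N/E/O/A/C), optionally with a hierarchical "Big Two"
super-structure in which the latent scores of the {E, A, C} blocks and of the
{N, O} blocks are positively coupled; reverse-keyed items; per-subject
acquiescence shifts; missing cells; heterogeneous subgroups with perturbed
loadings or extra noise; and phenotype feature tables whose predictable
signal is aligned with a chosen direction in the 2D factor-score plane.

All outputs are deterministic functions of the planted truth and its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ingest import DIMENSIONS, ResponseMatrix
from .traitspace import PhenotypeMatrix

SA_DIMS = ("E", "A", "C")  # Social Adaptation super-group
SM_DIMS = ("N", "O")  # Spontaneous Mentation super-group

# Latent scores are drawn from a normal with this mean and truncated at zero.
# The mean sits 3 latent SDs above zero so truncation binds with probability
# ~1.3e-3 and the empirical covariance of the scores matches score_cov.
_LATENT_MEAN = 3.0


@dataclass
class GroupSpec:
    """One synthetic subgroup: size, loading perturbation, extra-noise multiplier."""

    name: str
    n: int
    loading_perturbation: float = 0.0
    noise_multiplier: float = 1.0


@dataclass
class SyntheticTruth:
    """Planted ground truth for a synthetic questionnaire."""

    W_true: np.ndarray  # items x r_true, non-negative
    score_cov: np.ndarray  # r_true x r_true latent score covariance
    dimension_of_item: list  # theoretical Big Five label per item
    keyed_direction: np.ndarray  # +1 / -1 per item
    structure: str = "big5"
    noise_sd: float = 0.5  # Likert units
    missing_rate: float = 0.0
    acquiescence_sd: float = 0.0
    group_spec: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        self.W_true = np.asarray(self.W_true, dtype=float)
        self.score_cov = np.asarray(self.score_cov, dtype=float)
        if (self.W_true < 0).any():
            raise ValueError("W_true must be non-negative")
        if not np.allclose(self.score_cov, self.score_cov.T):
            raise ValueError("score_cov must be symmetric")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def n_items(self) -> int:
        return self.W_true.shape[0]

    @property
    def rank(self) -> int:
        return self.W_true.shape[1]

    def item_key(self, instrument: str = "synthetic") -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item_id": [f"item{i:03d}" for i in range(self.n_items)],
                "instrument": instrument,
                "theoretical_dimension": self.dimension_of_item,
                "keyed_direction": ["+" if k == 1 else "-" for k in self.keyed_direction],
            }
        )


def build_true_loadings(
    n_items_per_dimension: int,
    structure: str = "big5",
    cross_loading: float = 0.0,
    seed: int = 0,
    *,
    noise_sd: float = 0.5,
    missing_rate: float = 0.0,
    acquiescence_sd: float = 0.0,
    reverse_fraction: float = 0.5,
    within_group_corr: float = 0.6,
    group_spec: list | None = None,
) -> SyntheticTruth:
    """Plant a non-negative block loading matrix over the five dimensions.

    ``structure='big5'`` gives independent latent scores; ``'big2_hier'``
    couples the latent scores of the {E,A,C} and {N,O} blocks with
    correlation ``within_group_corr``, planting the Big Two super-structure.
    Dominant-block entries are drawn from U(0.8, 1.2) and cross-loadings from
    cross_loading * U(0.3, 1.0), so dominant entries strictly exceed
    cross-loadings for cross_loading < 0.5.
    """
    if n_items_per_dimension < 2:
        raise ValueError("need at least 2 items per dimension")
    if not 0 <= cross_loading < 0.5:
        raise ValueError("cross_loading must be in [0, 0.5)")
    if structure not in ("big5", "big2_hier"):
        raise ValueError(f"unknown structure {structure!r}; expected 'big5' or 'big2_hier'")

    rng = np.random.default_rng([seed, 11])
    n = n_items_per_dimension
    m = 5 * n
    W = np.zeros((m, 5))
    dims: list[str] = []
    keyed = np.ones(m, dtype=int)
    n_rev = int(round(reverse_fraction * n))
    for j, dim in enumerate(DIMENSIONS):
        rows = slice(j * n, (j + 1) * n)
        W[rows, j] = rng.uniform(0.8, 1.2, size=n)
        if cross_loading > 0:
            others = [k for k in range(5) if k != j]
            W[rows, others] = cross_loading * rng.uniform(0.3, 1.0, size=(n, 4))
        dims.extend([dim] * n)
        if n_rev:
            keyed[j * n + (n - n_rev) : (j + 1) * n] = -1

    cov = np.eye(5)
    if structure == "big2_hier":
        for group in (SA_DIMS, SM_DIMS):
            idx = [DIMENSIONS.index(d) for d in group]
            for a in idx:
                for b in idx:
                    if a != b:
                        cov[a, b] = within_group_corr

    return SyntheticTruth(
        W_true=W,
        score_cov=cov,
        dimension_of_item=dims,
        keyed_direction=keyed,
        structure=structure,
        noise_sd=noise_sd,
        missing_rate=missing_rate,
        acquiescence_sd=acquiescence_sd,
        group_spec=list(group_spec) if group_spec else [],
        seed=seed,
    )


def _draw_latent_scores(truth: SyntheticTruth, n_subjects: int, rng) -> np.ndarray:
    """r x n latent scores: MVN(mean=3, score_cov) truncated at zero."""
    eigvals = np.linalg.eigvalsh(truth.score_cov)
    if eigvals.min() < -1e-10:
        raise ValueError("score_cov is not positive semi-definite")
    L = np.linalg.cholesky(truth.score_cov + 1e-12 * np.eye(truth.rank))
    Z = rng.standard_normal((truth.rank, n_subjects))
    H = _LATENT_MEAN + L @ Z
    np.clip(H, 0.0, None, out=H)
    return H


def _discretize(latent: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Affine-rescale each item's values to [1, 5] by its 1st/99th percentiles."""
    lo = np.percentile(latent, 1, axis=1)
    hi = np.percentile(latent, 99, axis=1)
    span = hi - lo
    span[span < 1e-12] = 1.0
    scaled = 1.0 + 4.0 * (latent - lo[:, None]) / span[:, None]
    return scaled, lo, span


def _render_responses(
    truth: SyntheticTruth,
    W: np.ndarray,
    H: np.ndarray,
    noise_sd: float,
    rng,
) -> np.ndarray:
    """Likert-discretized responses (items x subjects) in instrument keying."""
    n_subjects = H.shape[1]
    latent = W @ H
    scaled, _, _ = _discretize(latent)
    if truth.acquiescence_sd > 0:
        scaled = scaled + rng.normal(0.0, truth.acquiescence_sd, size=n_subjects)[None, :]
    if noise_sd > 0:
        scaled = scaled + rng.normal(0.0, noise_sd, size=scaled.shape)
    V = np.rint(np.clip(scaled, 1.0, 5.0))
    rev = truth.keyed_direction == -1
    V[rev, :] = 6.0 - V[rev, :]
    return V


def _insert_missing(V: np.ndarray, missing_rate: float, rng) -> np.ndarray:
    if missing_rate > 0:
        mask = rng.random(V.shape) < missing_rate
        V = V.copy()
        V[mask] = np.nan
    return V


def _subject_meta(n_subjects: int, rng, group: str | None = None) -> pd.DataFrame:
    meta = pd.DataFrame(
        {
            "sex": rng.choice(["F", "M"], size=n_subjects),
            "age_group": rng.choice(["teen", "adult", "senior"], size=n_subjects, p=[0.2, 0.6, 0.2]),
            "culture": "synthetic",
            "family_id": np.arange(n_subjects),
        }
    )
    if group is not None:
        meta["group"] = group
    return meta


def _to_response_matrix(truth, V, meta) -> ResponseMatrix:
    values = pd.DataFrame(V.T, columns=[f"item{i:03d}" for i in range(V.shape[0])])
    return ResponseMatrix(values=values, item_key=truth.item_key(), subject_meta=meta)


def simulate_responses(
    truth: SyntheticTruth, n_subjects: int
) -> tuple[ResponseMatrix, np.ndarray]:
    """Generate raw-keyed Likert responses plus the true latent scores.

    Continuous latents W_true @ H_true (+ acquiescence + noise, both on the
    Likert scale after per-item rescaling) are discretized to integers 1..5,
    reverse-keyed items are flipped so the stored table mimics raw instrument
    keying, and missing cells are inserted uniformly at random.
    """
    if n_subjects < 2 * truth.rank:
        raise ValueError(f"need at least {2 * truth.rank} subjects for rank {truth.rank}")
    rng = np.random.default_rng([truth.seed, 23])
    H = _draw_latent_scores(truth, n_subjects, rng)
    V = _render_responses(truth, truth.W_true, H, truth.noise_sd, rng)
    V = _insert_missing(V, truth.missing_rate, rng)
    meta = _subject_meta(n_subjects, rng)
    return _to_response_matrix(truth, V, meta), H


def simulate_subgroups(truth: SyntheticTruth) -> tuple[ResponseMatrix, np.ndarray]:
    """Generate responses for heterogeneous subgroups defined in ``truth.group_spec``.

    Each group is drawn with its own perturbed loadings
    (clip(W_true + perturbation * N(0,1), 0)) and noise multiplier; the group
    label is attached to the subject metadata (column 'group').
    """
    if not truth.group_spec:
        raise ValueError("truth.group_spec is empty")
    for g in truth.group_spec:
        if g.n < truth.rank:
            raise ValueError(f"group {g.name!r} has {g.n} subjects < rank {truth.rank}")
    blocks, metas, scores = [], [], []
    for gi, g in enumerate(truth.group_spec):
        rng = np.random.default_rng([truth.seed, 31, gi])
        Wg = truth.W_true
        if g.loading_perturbation > 0:
            Wg = np.clip(Wg + g.loading_perturbation * rng.standard_normal(Wg.shape), 0.0, None)
        H = _draw_latent_scores(truth, g.n, rng)
        V = _render_responses(truth, Wg, H, truth.noise_sd * g.noise_multiplier, rng)
        V = _insert_missing(V, truth.missing_rate, rng)
        blocks.append(V)
        metas.append(_subject_meta(g.n, rng, group=g.name))
        scores.append(H)
    V_all = np.concatenate(blocks, axis=1)
    meta = pd.concat(metas, ignore_index=True)
    meta["family_id"] = np.arange(len(meta))
    return _to_response_matrix(truth, V_all, meta), np.concatenate(scores, axis=1)


def true_big_two_scores(truth: SyntheticTruth, H_true: np.ndarray) -> np.ndarray:
    """Subjects x 2 matrix of planted (SA, SM) scores from the latent block scores."""
    sa_idx = [DIMENSIONS.index(d) for d in SA_DIMS]
    sm_idx = [DIMENSIONS.index(d) for d in SM_DIMS]
    sa = H_true[sa_idx, :].mean(axis=0)
    sm = H_true[sm_idx, :].mean(axis=0)
    return np.column_stack([sa, sm])


def simulate_phenotypes(
    true_scores_2d: np.ndarray,
    theta_true: float,
    n_features: int,
    signal_fraction: float = 1.0,
    noise_sd: float = 0.5,
    family_size: int = 1,
    seed: int = 0,
) -> tuple[PhenotypeMatrix, np.ndarray]:
    """Phenotype features whose signal is aligned with direction theta_true.

    A round(signal_fraction * n_features) subset of features equals
    w_j * proj(theta_true) + noise_sd * N(0,1) where proj is the projection of
    the z-scored true (SA, SM) scores onto theta_true (degrees; 0 = +SA,
    90 = +SM); the remaining features are pure N(0,1) noise. Subjects are
    grouped into families of ``family_size`` consecutive subjects for
    grouped-CV tests. Returns the feature table and the true weight vector.
    """
    if not 0 < theta_true <= 180:
        raise ValueError("theta_true must be in (0, 180] degrees")
    if not 0 < signal_fraction <= 1:
        raise ValueError("signal_fraction must be in (0, 1]")
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    S = np.asarray(true_scores_2d, dtype=float)
    if S.ndim != 2 or S.shape[1] != 2:
        raise ValueError("true_scores_2d must be subjects x 2")
    n = S.shape[0]
    rng = np.random.default_rng([seed, 47])
    Z = (S - S.mean(axis=0)) / S.std(axis=0)
    th = np.deg2rad(theta_true)
    y = np.cos(th) * Z[:, 0] + np.sin(th) * Z[:, 1]

    n_sig = int(round(signal_fraction * n_features))
    idx = np.sort(rng.choice(n_features, size=n_sig, replace=False))
    w_true = np.zeros(n_features)
    w_true[idx] = rng.choice([-1.0, 1.0], size=n_sig) * rng.uniform(0.8, 1.2, size=n_sig)

    F = rng.standard_normal((n, n_features))
    F[:, idx] = np.outer(y, w_true[idx])
    if noise_sd > 0:
        F[:, idx] += noise_sd * rng.standard_normal((n, n_sig))
    family_id = np.arange(n) // max(int(family_size), 1)
    table = pd.DataFrame(F, columns=[f"feat{j:03d}" for j in range(n_features)])
    pheno = PhenotypeMatrix(values=table, domain="synthetic", family_id=family_id)
    return pheno, w_true


def write_synthetic_dataset(outdir, truth: SyntheticTruth, R: ResponseMatrix, H_true, spec_extra=None):
    """Write responses, item key, metadata, true scores, and a JSON spec sidecar."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    R.values.to_csv(outdir / "responses.csv", index=False)
    paths["responses"] = str(outdir / "responses.csv")
    R.item_key.to_csv(outdir / "item_key.csv", index=False)
    paths["item_key"] = str(outdir / "item_key.csv")
    if R.subject_meta is not None:
        R.subject_meta.to_csv(outdir / "subject_meta.csv", index=False)
        paths["subject_meta"] = str(outdir / "subject_meta.csv")
    pd.DataFrame(H_true.T, columns=list(DIMENSIONS)[: H_true.shape[0]]).to_csv(
        outdir / "true_scores.csv", index=False
    )
    paths["true_scores"] = str(outdir / "true_scores.csv")
    spec = {
        "structure": truth.structure,
        "n_items": truth.n_items,
        "rank": truth.rank,
        "noise_sd": truth.noise_sd,
        "missing_rate": truth.missing_rate,
        "acquiescence_sd": truth.acquiescence_sd,
        "groups": [
            {"name": g.name, "n": g.n, "loading_perturbation": g.loading_perturbation,
             "noise_multiplier": g.noise_multiplier}
            for g in truth.group_spec
        ],
        "seed": truth.seed,
        "score_cov": truth.score_cov.tolist(),
    }
    if spec_extra:
        spec.update(spec_extra)
    with open(outdir / "synthetic_spec.json", "w") as fh:
        json.dump(spec, fh, indent=2, sort_keys=True)
    paths["spec"] = str(outdir / "synthetic_spec.json")
    return paths
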