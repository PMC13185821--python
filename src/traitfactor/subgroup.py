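"""Generalizability of an overall factor model to demographic/cultural subgroups.

The overall model's fit to a subgroup is compared against a permutation null
in which the group labels are shuffled globally (every group keeps its sample
size). Generalizability is the mean actual-minus-null difference in
normalized reconstruction error under the overall basis; intra-group
heterogeneity is the analogous difference when the model is refitted within
the (actual or null) group; model similarity is the concordance index between
the overall and group-specific bases. Univariate regressions then ask which
of heterogeneity, similarity, or sample size accounts for generalizability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .modeval import concordance_index, _prepare_X
from .opnmf import FactorModel, fit_opnmf


@dataclass
class SubgroupReport:
    group_label: str
    n: int
    generalizability: float | None = None
    heterogeneity: float | None = None
    similarity: float | None = None
    t_stat: float | None = None
    p_value: float | None = None
    p_perm: float | None = None  # empirical two-sided permutation p (calibrated)


def _group_re_from_residuals(res_sq: np.ndarray, x_sq: np.ndarray, idx) -> float:
    """Normalized RE restricted to the subject columns in idx."""
    num = res_sq[idx].sum()
    den = max(x_sq[idx].sum(), 1e-32)
    return float(np.sqrt(num / den))


def subgroup_generalizability(
    model_overall: FactorModel,
    R,
    label_field: str = "group",
    n_null: int = 100,
    seed: int = 0,
) -> list[SubgroupReport]:
    """Actual-vs-null reconstruction error of the overall model per subgroup.

    For each group the actual normalized RE of the overall basis on the
    group's columns is compared with ``n_null`` label shuffles that preserve
    every group's size. Reported: mean(actual - null), a two-tailed
    one-sample t-test of the n_null differences against zero, and an
    empirical two-sided permutation p-value (``p_perm``). The t-test treats
    only the null REs as random and is therefore anti-conservative as a test
    of "this group behaves like a random group" (its statistic inflates by
    roughly sqrt(n_null)); p_perm ranks the actual RE within the null
    distribution and is calibrated, so it is the one to use for false-positive
    control.
    """
    if n_null < 2:
        raise ValueError("n_null must be >= 2")
    X = _prepare_X(R)
    labels = np.asarray(R.subject_meta[label_field])
    uniq = [u for u in pd.unique(labels)]
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")

    W = model_overall.W
    Res = X - W @ (W.T @ X)
    res_sq = (Res**2).sum(axis=0)
    x_sq = (X**2).sum(axis=0)

    rng = np.random.default_rng([seed, 71])
    n_sub = X.shape[1]
    perms = [rng.permutation(n_sub) for _ in range(n_null)]

    reports = []
    for g in uniq:
        idx = np.where(labels == g)[0]
        if len(idx) < 2:
            warnings.warn(f"group {g!r} has fewer than 2 subjects; skipped")
            continue
        actual = _group_re_from_residuals(res_sq, x_sq, idx)
        nulls = np.array(
            [_group_re_from_residuals(res_sq, x_sq, p[idx]) for p in perms]
        )
        diffs = actual - nulls
        t, p = sps.ttest_1samp(diffs, 0.0)
        p_hi = (1.0 + np.sum(nulls >= actual)) / (n_null + 1.0)
        p_lo = (1.0 + np.sum(nulls <= actual)) / (n_null + 1.0)
        reports.append(
            SubgroupReport(
                group_label=str(g),
                n=int(len(idx)),
                generalizability=float(diffs.mean()),
                t_stat=float(t),
                p_value=float(p),
                p_perm=float(min(1.0, 2.0 * min(p_hi, p_lo))),
            )
        )
    return reports


def intra_group_heterogeneity(
    R,
    label_field: str = "group",
    rank: int = 2,
    n_null: int = 100,
    seed: int = 0,
    max_iter: int = 50_000,
    tol: float = 1e-5,
) -> dict:
    """Within-group model fit error, adjusted by equal-size null groups.

    Per group: OPNMF is fitted on the group alone and its normalized RE on
    itself recorded; null groups of the same size are drawn by globally
    shuffled membership and refitted. Returns {label: mean(actual - null)}.
    """
    X = _prepare_X(R)
    labels = np.asarray(R.subject_meta[label_field])
    uniq = [u for u in pd.unique(labels)]
    rng = np.random.default_rng([seed, 73])
    n_sub = X.shape[1]
    perms = [rng.permutation(n_sub) for _ in range(n_null)]

    def fit_re(idx) -> float:
        Xg = X[:, idx]
        model = fit_opnmf(Xg, rank, max_iter=max_iter, tol=tol)
        from .opnmf import reconstruction_error

        return reconstruction_error(model, Xg)

    out = {}
    for g in uniq:
        idx = np.where(labels == g)[0]
        if len(idx) < rank:
            warnings.warn(f"group {g!r} too small to fit rank {rank}; skipped")
            continue
        actual = fit_re(idx)
        nulls = np.array([fit_re(p[idx]) for p in perms])
        out[str(g)] = float(actual - nulls.mean())
    return out


def model_similarity(model_overall, model_group) -> float:
    """Concordance index between the overall and a group-specific basis."""
    W1 = model_overall.W if isinstance(model_overall, FactorModel) else model_overall
    W2 = model_group.W if isinstance(model_group, FactorModel) else model_group
    return concordance_index(W1, W2)


def group_models(
    R, label_field: str = "group", rank: int = 2, max_iter: int = 50_000, tol: float = 1e-5
) -> dict:
    """Fit one OPNMF model per subgroup at the given rank."""
    X = _prepare_X(R)
    labels = np.asarray(R.subject_meta[label_field])
    out = {}
    for g in pd.unique(labels):
        idx = np.where(labels == g)[0]
        if len(idx) < rank:
            warnings.warn(f"group {g!r} too small to fit rank {rank}; skipped")
            continue
        out[str(g)] = fit_opnmf(X[:, idx], rank, max_iter=max_iter, tol=tol)
    return out


def analyze_subgroups(
    model_overall: FactorModel,
    R,
    label_field: str = "group",
    rank: int | None = None,
    n_null: int = 100,
    seed: int = 0,
) -> list[SubgroupReport]:
    """Full per-group report: generalizability, heterogeneity, similarity."""
    rank = rank if rank is not None else model_overall.rank
    reports = subgroup_generalizability(model_overall, R, label_field, n_null=n_null, seed=seed)
    het = intra_group_heterogeneity(R, label_field, rank=rank, n_null=n_null, seed=seed)
    gm = group_models(R, label_field, rank=rank)
    for rep in reports:
        rep.heterogeneity = het.get(rep.group_label)
        if rep.group_label in gm:
            rep.similarity = model_similarity(model_overall, gm[rep.group_label])
    return reports


def reports_to_frame(reports) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": r.group_label,
                "n": r.n,
                "generalizability": r.generalizability,
                "heterogeneity": r.heterogeneity,
                "similarity": r.similarity,
                "t_stat": r.t_stat,
                "p_value": r.p_value,
                "p_perm": r.p_perm,
            }
            for r in reports
        ]
    )


def explain_generalizability(reports) -> pd.DataFrame:
    """Univariate regressions of generalizability on heterogeneity/similarity/n.

    Accepts a list of SubgroupReport or a DataFrame with columns
    generalizability, heterogeneity, similarity, n. Returns one row per
    predictor with r^2 and two-tailed p; a zero-variance predictor is
    reported as r^2 = 0 with the ``degenerate`` flag set.
    """
    df = reports if isinstance(reports, pd.DataFrame) else reports_to_frame(reports)
    if len(df) < 4:
        raise ValueError("need at least 4 groups for the explanatory regressions")
    y = df["generalizability"].to_numpy(dtype=float)
    rows = []
    for pred in ("heterogeneity", "similarity", "n"):
        x = df[pred].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if np.std(x[ok]) < 1e-14:
            rows.append({"predictor": pred, "r2": 0.0, "p_value": np.nan,
                         "slope": 0.0, "degenerate": True})
            continue
        res = sps.linregress(x[ok], y[ok])
        rows.append(
            {
                "predictor": pred,
                "r2": float(res.rvalue**2),
                "p_value": float(res.pvalue),
                "slope": float(res.slope),
                "degenerate": False,
            }
        )
    return pd.DataFrame(rows)
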