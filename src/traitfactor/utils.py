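"""Small shared helpers: deterministic fold construction and FDR."""

from __future__ import annotations

import numpy as np


def make_folds(n: int, n_folds: int, rng, groups=None) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic shuffled k-fold splits as (train_idx, test_idx) pairs.

    When ``groups`` is given, whole groups are assigned to folds so no group
    is split between the main and hold sample of any fold.
    """
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if groups is None:
        order = rng.permutation(n)
        chunks = np.array_split(order, n_folds)
    else:
        groups = np.asarray(groups)
        uniq = np.unique(groups)
        if len(uniq) < n_folds:
            raise ValueError(f"{len(uniq)} groups cannot fill {n_folds} folds")
        gorder = rng.permutation(len(uniq))
        gchunks = np.array_split(uniq[gorder], n_folds)
        chunks = [np.where(np.isin(groups, gc))[0] for gc in gchunks]
    out = []
    all_idx = np.arange(n)
    for test in chunks:
        test = np.sort(np.asarray(test))
        train = np.setdiff1d(all_idx, test, assume_unique=False)
        out.append((train, test))
    return out


def bh_fdr(pvals: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg rejection flags at level alpha."""
    from statsmodels.stats.multitest import multipletests

    reject, _, _, _ = multipletests(np.asarray(pvals, dtype=float), alpha=alpha, method="fdr_bh")
    return reject


def derive_seed(*parts: int) -> int:
    """A reproducible sub-seed (< 2**31) from integer parts."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31))
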