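"""Reading, validation, and preprocessing of Likert questionnaire tables.

The analysis operates on subjects x items tables of 1-5 Likert responses with
an item key (instrument, theoretical Big Five dimension, keying direction) and
optional per-subject metadata. Preprocessing follows the conventional order
for inventory data: reverse-score negatively keyed items, handle missing
responses, and (optionally) remove per-subject acquiescence by within-subject
mean-centering before handing a non-negative items x subjects matrix to the
factorization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

LIKERT_MIN = 1
LIKERT_MAX = 5

DIMENSIONS = ("N", "E", "O", "A", "C")

_KEY_COLUMNS = ("item_id", "instrument", "theoretical_dimension", "keyed_direction")


@dataclass
class ResponseMatrix:
    """Subjects x items Likert responses plus item key and subject metadata.

    ``values`` holds floats so missing cells can be NaN; all non-missing
    entries are integers in [1, 5]. ``reverse_scored`` records whether the
    standard-key flip (x -> 6 - x for negatively keyed items) has been
    applied; the flip is applied at most once.
    """

    values: pd.DataFrame
    item_key: pd.DataFrame
    subject_meta: pd.DataFrame | None = None
    reverse_scored: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in _KEY_COLUMNS if c not in self.item_key.columns]
        if missing:
            raise ValueError(f"item key lacks required columns: {missing}")
        key_ids = list(self.item_key["item_id"])
        if len(set(key_ids)) != len(key_ids):
            raise ValueError("item_id values in the item key are not unique")
        unknown = [c for c in self.values.columns if c not in set(key_ids)]
        if unknown:
            raise ValueError(f"response columns absent from item key: {unknown}")
        if list(self.values.columns) != key_ids:
            # align the key to the response column order
            self.item_key = (
                self.item_key.set_index("item_id").loc[list(self.values.columns)].reset_index()
            )
        if self.subject_meta is not None and len(self.subject_meta) != len(self.values):
            raise ValueError(
                f"subject metadata has {len(self.subject_meta)} rows for "
                f"{len(self.values)} subjects"
            )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def keyed_direction(self) -> np.ndarray:
        """Per-item keying as +1/-1, accepting '+'/'-' or numeric encodings."""
        raw = self.item_key["keyed_direction"].to_numpy()
        out = np.empty(len(raw), dtype=int)
        for i, v in enumerate(raw):
            if v in ("+", "+1", 1, 1.0):
                out[i] = 1
            elif v in ("-", "−", "-1", -1, -1.0):
                out[i] = -1
            else:
                raise ValueError(f"unrecognized keyed_direction {v!r} for item index {i}")
        return out


@dataclass
class DataMatrixX:
    """Non-negative items x subjects matrix, the orientation the factorization uses."""

    X: np.ndarray
    item_ids: list[str] = field(default_factory=list)
    subject_index: pd.Index | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional (items x subjects)")
        if np.isnan(self.X).any():
            raise ValueError("X contains missing entries")
        if (self.X < 0).any():
            raise ValueError("X contains negative entries")


def load_responses(
    responses_path,
    item_key_path,
    subject_meta_path=None,
) -> ResponseMatrix:
    """Read and validate a responses CSV against its item-key CSV.

    Missing cells may be empty or "NA". Every non-missing cell must be an
    integer in [1, 5]; violations raise ValueError naming the row and column.
    Reverse scoring is NOT applied here.
    """
    key = pd.read_csv(item_key_path, dtype={"item_id": str})
    raw = pd.read_csv(responses_path, na_values=["NA"], keep_default_na=True)
    raw.columns = [str(c) for c in raw.columns]

    key_ids = set(key["item_id"])
    for col in raw.columns:
        if col not in key_ids:
            raise ValueError(f"response column {col!r} not present in the item key")

    values = raw.astype(float)
    arr = values.to_numpy()
    obs = ~np.isnan(arr)
    frac = arr[obs] - np.round(arr[obs])
    if np.any(np.abs(frac) > 0):
        r, c = np.argwhere(obs & (np.abs(arr - np.round(arr)) > 0))[0]
        raise ValueError(
            f"non-integer response {arr[r, c]!r} at row {r}, column {values.columns[c]!r}"
        )
    bad = obs & ((arr < LIKERT_MIN) | (arr > LIKERT_MAX))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"out-of-range response {arr[r, c]:g} at row {r}, column {values.columns[c]!r} "
            f"(expected {LIKERT_MIN}..{LIKERT_MAX})"
        )

    meta = pd.read_csv(subject_meta_path) if subject_meta_path is not None else None
    return ResponseMatrix(values=values, item_key=key, subject_meta=meta)


def apply_reverse_scoring(R: ResponseMatrix) -> ResponseMatrix:
    """Map negatively keyed items x -> 6 - x; refuse a second application."""
    if R.reverse_scored:
        raise ValueError("reverse scoring has already been applied to this matrix")
    flip = R.keyed_direction == -1
    values = R.values.copy()
    cols = values.columns[flip]
    values[cols] = (LIKERT_MIN + LIKERT_MAX) - values[cols]
    return replace(R, values=values, reverse_scored=True)


def impute_missing(R: ResponseMatrix, strategy: str = "item_mean") -> DataMatrixX:
    """Replace missing cells by the item's observed mean; transpose to items x subjects."""
    if not R.reverse_scored:
        raise ValueError("apply_reverse_scoring before imputation")
    if strategy != "item_mean":
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    arr = R.values.to_numpy(dtype=float).copy()
    n_obs = (~np.isnan(arr)).sum(axis=0)
    if (n_obs == 0).any():
        dead = [R.values.columns[i] for i in np.where(n_obs == 0)[0]]
        raise ValueError(f"items with no observed responses cannot be imputed: {dead}")
    col_means = np.nanmean(arr, axis=0)
    miss_r, miss_c = np.where(np.isnan(arr))
    arr[miss_r, miss_c] = col_means[miss_c]
    return DataMatrixX(
        X=arr.T,
        item_ids=list(R.values.columns),
        subject_index=R.values.index,
        provenance={"imputation": strategy, "n_imputed": int(len(miss_r))},
    )


def center_within_subject(R: ResponseMatrix) -> DataMatrixX:
    """Remove per-subject mean response (acquiescence), then restore non-negativity.

    Each subject's row mean is subtracted after item-mean imputation; a global
    shift of +|minimum| makes the matrix non-negative again so the
    factorization's constraints apply. The shift is recorded in provenance.
    """
    D = impute_missing(R)
    X = D.X  # items x subjects
    subj_means = X.mean(axis=0)
    Xc = X - subj_means[None, :]
    shift = float(-Xc.min()) if Xc.size else 0.0
    shift = max(shift, 0.0)
    Xc = Xc + shift
    Xc[Xc < 0] = 0.0  # guard against roundoff
    prov = dict(D.provenance)
    prov.update({"centered_within_subject": True, "shift": shift})
    return DataMatrixX(X=Xc, item_ids=D.item_ids, subject_index=D.subject_index, provenance=prov)
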