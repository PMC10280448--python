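"""Data-preparation chain for the interval matrix.

Order of operations: mean-impute missing cells on raw intervals, divide the
point columns by the beat's own RR (removes between-subject heart-rate
differences), scale each point column to unit sum of squares over the pooled
datasets (so one model fits recordings from different devices), then emit
per-(subject, subtype) sequences and a random 70/15/15 row split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .icg_data import (
    POINT_COLUMNS,
    RR_COLUMN,
    IntervalMatrix,
    ValidationError,
)


class StateError(ValueError):
    """Raised when a normalization step is applied in the wrong state."""


@dataclass(frozen=True)
class SplitIndices:
    """Random partition of rows into train/validation/test sets."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        sets = [set(self.train), set(self.val), set(self.test)]
        total = len(self.train) + len(self.val) + len(self.test)
        if len(sets[0] | sets[1] | sets[2]) != total:
            raise ValidationError("split sets must be disjoint")

    @property
    def n(self) -> int:
        return len(self.train) + len(self.val) + len(self.test)


def impute_nan_with_available_mean(
    m: IntervalMatrix,
) -> tuple[IntervalMatrix, pd.DataFrame]:
    """Replace each missing cell by the mean of the available cells of the
    same column, within the same (subject, subtype) group.

    Falls back to the same-dataset column mean when the group has no
    observed value for that column.  Returns the imputed matrix and a
    boolean mask of the cells that were filled.  Non-missing cells are left
    bit-identical.
    """
    out = m.copy()
    mask = out.values[POINT_COLUMNS].isna()
    if not mask.to_numpy().any():
        return out, mask

    vals = out.values
    meta = out.row_meta
    group_key = list(zip(meta["subject_id"], meta["subtype"]))
    dataset_key = meta["dataset_id"].to_numpy()

    for col in POINT_COLUMNS:
        col_vals = vals[col].to_numpy(copy=True)
        col_missing = np.isnan(col_vals)
        if not col_missing.any():
            continue
        # dataset-level fallback means
        ds_means: dict[str, float] = {}
        for ds in np.unique(dataset_key):
            in_ds = dataset_key == ds
            observed = col_vals[in_ds & ~col_missing]
            if observed.size == 0:
                raise ValidationError(
                    f"column {col!r} is entirely missing in dataset {ds!r}; "
                    "cannot impute"
                )
            ds_means[ds] = float(observed.mean())
        # group means
        grp_means: dict[tuple, float] = {}
        for idx in np.flatnonzero(col_missing):
            key = group_key[idx]
            if key not in grp_means:
                in_grp = np.fromiter(
                    (k == key for k in group_key), dtype=bool, count=len(group_key)
                )
                observed = col_vals[in_grp & ~col_missing]
                grp_means[key] = (
                    float(observed.mean()) if observed.size else np.nan
                )
            fill = grp_means[key]
            if np.isnan(fill):
                fill = ds_means[dataset_key[idx]]
            col_vals[idx] = fill
        vals[col] = col_vals
    return out, mask


def normalize_by_rr(m: IntervalMatrix) -> IntervalMatrix:
    """Divide each point column row-wise by the RR interval.

    The RR column itself is retained unchanged (in seconds) so the ratios
    can later be inverted back to times.
    """
    if m.state != "raw":
        raise StateError(f"normalize_by_rr requires state 'raw', got {m.state!r}")
    rr = m.values[RR_COLUMN].to_numpy()
    bad = np.flatnonzero(~(rr > 0))
    if bad.size:
        raise ValidationError(f"non-positive RR interval at row(s) {bad.tolist()[:5]}")
    out = m.copy()
    out.values[POINT_COLUMNS] = out.values[POINT_COLUMNS].to_numpy() / rr[:, None]
    out.state = "rr_normalized"
    return out


def denormalize_rr(m: IntervalMatrix) -> IntervalMatrix:
    """Inverse of :func:`normalize_by_rr`: multiply point columns by RR."""
    if m.state != "rr_normalized":
        raise StateError(
            f"denormalize_rr requires state 'rr_normalized', got {m.state!r}"
        )
    rr = m.values[RR_COLUMN].to_numpy()
    out = m.copy()
    out.values[POINT_COLUMNS] = out.values[POINT_COLUMNS].to_numpy() * rr[:, None]
    out.state = "raw"
    return out


def sum_of_squares_normalize(
    m: IntervalMatrix, scale: pd.Series | None = None
) -> IntervalMatrix:
    """Scale each point column so its sum of squares equals 1.

    The Euclidean norm is computed over the pooled rows of all datasets so a
    single model fits data from different acquisition devices.  Pass a
    previously recorded ``scale`` to re-apply training-time scales to new
    data instead of renormalizing.
    """
    if m.state != "rr_normalized":
        raise StateError(
            f"sum_of_squares_normalize requires state 'rr_normalized', got {m.state!r}"
        )
    pts = m.values[POINT_COLUMNS].to_numpy()
    if np.isnan(pts).any():
        raise ValidationError("sum_of_squares_normalize requires no missing cells")
    if scale is None:
        norms = np.sqrt((pts**2).sum(axis=0))
        if np.any(norms == 0):
            zero = [c for c, nz in zip(POINT_COLUMNS, norms == 0) if nz]
            raise ValidationError(f"zero-norm column(s) {zero}")
        scale = pd.Series(norms, index=POINT_COLUMNS)
    else:
        scale = scale.reindex(POINT_COLUMNS)
        if scale.isna().any() or (scale <= 0).any():
            raise ValidationError("provided ss_scale must be positive for all columns")
    out = m.copy()
    out.values[POINT_COLUMNS] = pts / scale.to_numpy()[None, :]
    out.state = "ss_normalized"
    out.ss_scale = scale
    return out


def invert_sum_of_squares(m: IntervalMatrix) -> IntervalMatrix:
    """Inverse of :func:`sum_of_squares_normalize` using the stored scales."""
    if m.state != "ss_normalized" or m.ss_scale is None:
        raise StateError("invert_sum_of_squares requires an ss_normalized matrix")
    out = m.copy()
    out.values[POINT_COLUMNS] = (
        out.values[POINT_COLUMNS].to_numpy() * m.ss_scale.to_numpy()[None, :]
    )
    out.state = "rr_normalized"
    out.ss_scale = None
    return out


def split_data(
    n_rows: int,
    seed: int,
    ratios: tuple[float, float, float] = (0.70, 0.15, 0.15),
) -> SplitIndices:
    """Randomly partition row indices into train/val/test.

    Sizes are ``floor(r_train * n)`` and ``floor(r_val * n)``; the remainder
    goes to test.  Deterministic under ``seed``.
    """
    if n_rows < 10:
        raise ValidationError(f"need at least 10 rows to split, got {n_rows}")
    if not np.isclose(sum(ratios), 1.0):
        raise ValidationError(f"split ratios must sum to 1, got {ratios}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_rows)
    n_train = int(np.floor(ratios[0] * n_rows))
    n_val = int(np.floor(ratios[1] * n_rows))
    return SplitIndices(
        train=perm[:n_train],
        val=perm[n_train : n_train + n_val],
        test=perm[n_train + n_val :],
        seed=seed,
    )


def split_by_subject(
    subject_ids: pd.Series, seed: int, ratios: tuple[float, float, float] = (0.70, 0.15, 0.15)
) -> SplitIndices:
    """Leakage-aware alternative: assign whole subjects to partitions."""
    subjects = sorted(subject_ids.unique())
    if len(subjects) < 3:
        raise ValidationError("subject-level split needs at least 3 subjects")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(subjects))
    n_train = max(1, int(np.floor(ratios[0] * len(subjects))))
    n_val = max(1, int(np.floor(ratios[1] * len(subjects))))
    train_s = {subjects[i] for i in perm[:n_train]}
    val_s = {subjects[i] for i in perm[n_train : n_train + n_val]}
    idx = np.arange(len(subject_ids))
    in_train = subject_ids.isin(train_s).to_numpy()
    in_val = subject_ids.isin(val_s).to_numpy()
    return SplitIndices(
        train=idx[in_train],
        val=idx[in_val],
        test=idx[~in_train & ~in_val],
        seed=seed,
    )


@dataclass
class Stream:
    """A time-ordered sequence of 8-channel ratio vectors for one
    (subject, subtype) pair; the per-row RR is carried as metadata."""

    subject_id: str
    dataset_id: str
    subtype: str
    row_indices: np.ndarray  # positions in the source IntervalMatrix
    series: np.ndarray  # n_beats x 8, point-column order
    rr: np.ndarray  # n_beats, seconds


def to_sequences(m: IntervalMatrix, group_by_subtype: bool = True) -> list[Stream]:
    """Emit per-(subject, subtype) streams of 8-vectors in beat order.

    Streams never cross a subject boundary, so no delay line mixes beats
    from different people.  With ``group_by_subtype=False`` the streams are
    per subject only (all subtypes interleaved in time).
    """
    if m.state != "ss_normalized":
        raise StateError(f"to_sequences requires state 'ss_normalized', got {m.state!r}")
    meta = m.row_meta
    keys = ["subject_id", "subtype"] if group_by_subtype else ["subject_id"]
    streams: list[Stream] = []
    for key, grp in meta.groupby(keys, sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        order = grp.sort_values("beat_index").index.to_numpy()
        pos = meta.index.get_indexer(order)
        streams.append(
            Stream(
                subject_id=key[0],
                dataset_id=str(grp["dataset_id"].iloc[0]),
                subtype=key[1] if group_by_subtype else "all",
                row_indices=pos,
                series=m.values[POINT_COLUMNS].to_numpy()[pos],
                rr=m.values[RR_COLUMN].to_numpy()[pos],
            )
        )
    return streams
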