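"""Domain types and I/O for annotated impedance-cardiography (ICG) beats.

One heartbeat of the dZ/dt signal is annotated by up to eight characteristic
points (A, B, E, X1, X2, Y, O, Z), each referenced to the R peak of the
simultaneously recorded ECG.  The central container is the interval matrix:
one row per beat, columns RR (R-to-R interval) plus the latency of each
characteristic point relative to its own R peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


class PointLabel(str, Enum):
    """The eight annotated characteristic points, in within-beat time order."""

    A = "A"
    B = "B"
    E = "E"
    X1 = "X1"
    X2 = "X2"
    Y = "Y"
    O = "O"
    Z = "Z"

    @property
    def order(self) -> int:
        return list(PointLabel).index(self)


class SubtypeLabel(str, Enum):
    """Morphological classes of the dZ/dt complex.

    ``ABEXYOZ0`` is the typical complex with all points present;
    ``ABEXYOZu`` carries no detectable characteristic points at all.
    """

    ABEXYOZ0 = "ABEXYOZ0"
    ABEXYOZ1 = "ABEXYOZ1"
    ABEXYOZ2 = "ABEXYOZ2"
    ABEXYOZ3 = "ABEXYOZ3"
    ABEXYOZ4 = "ABEXYOZ4"
    ABEXYOZ5 = "ABEXYOZ5"
    ABEXYOZu = "ABEXYOZu"


#: Column order of the interval matrix.
RR_COLUMN = "RR"
POINT_COLUMNS = ["RA", "RB", "RE", "RX1", "RX2", "RY", "RO", "RZ"]
ALL_COLUMNS = [RR_COLUMN] + POINT_COLUMNS

#: interval column <-> characteristic point
POINT_FOR_COLUMN = dict(zip(POINT_COLUMNS, PointLabel))
COLUMN_FOR_POINT = {p: c for c, p in POINT_FOR_COLUMN.items()}

#: Point groups that appear and disappear together across subtypes.
CO_MISSING_GROUPS = {
    "ABE": (PointLabel.A, PointLabel.B, PointLabel.E),
    "YOZ": (PointLabel.Y, PointLabel.O, PointLabel.Z),
}

_ANNOTATION_HEADER = [
    "subject_id",
    "dataset_id",
    "beat_index",
    "subtype",
    "r_time",
] + [f"t_{p.value}" for p in PointLabel]


class AnnotationFormatError(ValueError):
    """Raised when an annotation file does not match the expected dialect."""


class ValidationError(ValueError):
    """Raised when annotation content violates a structural invariant."""


@dataclass(frozen=True)
class AnnotatedComplex:
    """A single annotated heartbeat.

    ``point_times`` maps each characteristic point to its absolute time in
    seconds; absent points are simply not in the mapping (or map to NaN).
    """

    subject_id: str
    dataset_id: str
    beat_index: int
    r_time: float
    point_times: Mapping[PointLabel, float]
    subtype: SubtypeLabel

    def __post_init__(self) -> None:
        if self.beat_index < 0:
            raise ValidationError(f"beat_index must be >= 0, got {self.beat_index}")
        if not np.isfinite(self.r_time) or self.r_time < 0:
            raise ValidationError(f"r_time must be finite and >= 0, got {self.r_time}")
        clean = {}
        for p, t in self.point_times.items():
            if t is None or (isinstance(t, float) and np.isnan(t)):
                continue
            if not np.isfinite(t):
                raise ValidationError(f"point time for {p.value} is not finite")
            clean[PointLabel(p)] = float(t)
        object.__setattr__(self, "point_times", clean)


@dataclass
class IntervalMatrix:
    """Beats x 9 grid of R-peak-anchored intervals.

    ``values`` holds the RR interval and the eight point latencies (NaN marks
    a missing point); ``row_meta`` carries per-row subject, dataset, subtype
    and beat index.  ``state`` tracks the normalization stage:

    - ``raw``            : all entries in seconds
    - ``rr_normalized``  : point columns divided by the row's RR (RR kept, s)
    - ``ss_normalized``  : point columns additionally scaled to unit sum of
      squares; the per-column scale factors live in ``ss_scale`` so the
      transform can be inverted exactly.
    """

    values: pd.DataFrame
    row_meta: pd.DataFrame
    state: str = "raw"
    ss_scale: pd.Series | None = None

    def __post_init__(self) -> None:
        if list(self.values.columns) != ALL_COLUMNS:
            raise ValidationError(
                f"interval matrix must have columns {ALL_COLUMNS}, "
                f"got {list(self.values.columns)}"
            )
        if self.state not in {"raw", "rr_normalized", "ss_normalized"}:
            raise ValidationError(f"unknown state {self.state!r}")
        if (self.state == "ss_normalized") != (self.ss_scale is not None):
            raise ValidationError("ss_scale must be present iff state is ss_normalized")
        if len(self.values) != len(self.row_meta):
            raise ValidationError("values and row_meta must have equal row counts")

    def __len__(self) -> int:
        return len(self.values)

    def copy(self) -> "IntervalMatrix":
        return IntervalMatrix(
            values=self.values.copy(),
            row_meta=self.row_meta.copy(),
            state=self.state,
            ss_scale=None if self.ss_scale is None else self.ss_scale.copy(),
        )

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Boolean mask over the point columns; True where the cell is missing."""
        return self.values[POINT_COLUMNS].isna()


def _parse_float(token, line_no: int, col: str) -> float:
    if token is None or (isinstance(token, float) and np.isnan(token)):
        return float("nan")
    s = str(token).strip()
    if s == "" or s.lower() in {"nan", "na", "missing"}:
        return float("nan")
    try:
        return float(s)
    except ValueError as exc:
        raise AnnotationFormatError(
            f"line {line_no}: cannot parse {col}={token!r} as a number"
        ) from exc


def read_annotations(path: str | Path) -> list[AnnotatedComplex]:
    """Read annotated beats from a delimited-text file.

    The file is CSV with header ``subject_id, dataset_id, beat_index,
    subtype, r_time, t_A ... t_Z``; an empty cell (or ``NaN``) marks a
    missing point.  Beats are returned grouped and ordered by
    ``(subject_id, beat_index)``.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing_cols = [c for c in _ANNOTATION_HEADER if c not in df.columns]
    if missing_cols:
        raise AnnotationFormatError(
            f"{path.name}: missing mandatory column(s) {missing_cols}"
        )
    beats: list[AnnotatedComplex] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = dict(zip(df.columns, row))
        try:
            subtype = SubtypeLabel(row["subtype"].strip())
        except ValueError as exc:
            raise ValidationError(
                f"line {i}: unknown subtype {row['subtype']!r}"
            ) from exc
        point_times = {
            p: _parse_float(row[f"t_{p.value}"], i, f"t_{p.value}") for p in PointLabel
        }
        point_times = {p: t for p, t in point_times.items() if not np.isnan(t)}
        beats.append(
            AnnotatedComplex(
                subject_id=row["subject_id"].strip(),
                dataset_id=row["dataset_id"].strip(),
                beat_index=int(row["beat_index"]),
                r_time=_parse_float(row["r_time"], i, "r_time"),
                point_times=point_times,
                subtype=subtype,
            )
        )
    beats.sort(key=lambda b: (b.subject_id, b.beat_index))
    _check_monotone_r_times(beats)
    return beats


def _check_monotone_r_times(beats: Iterable[AnnotatedComplex]) -> None:
    last: dict[str, float] = {}
    for b in beats:
        prev = last.get(b.subject_id)
        if prev is not None and b.r_time <= prev:
            raise ValidationError(
                f"subject {b.subject_id!r}: r_time not strictly increasing "
                f"at beat {b.beat_index} ({b.r_time} <= {prev})"
            )
        last[b.subject_id] = b.r_time


def write_annotations(beats: Iterable[AnnotatedComplex], path: str | Path) -> None:
    """Write beats back to the CSV dialect accepted by :func:`read_annotations`."""
    rows = []
    for b in beats:
        row = {
            "subject_id": b.subject_id,
            "dataset_id": b.dataset_id,
            "beat_index": b.beat_index,
            "subtype": b.subtype.value,
            "r_time": repr(b.r_time),
        }
        for p in PointLabel:
            t = b.point_times.get(p)
            row[f"t_{p.value}"] = "" if t is None else repr(t)
        rows.append(row)
    pd.DataFrame(rows, columns=_ANNOTATION_HEADER).to_csv(path, index=False)


def build_interval_matrix(beats: list[AnnotatedComplex]) -> IntervalMatrix:
    """Turn annotated beats into the RR/latency interval matrix.

    RR(i) is the forward interval ``r_time(i+1) - r_time(i)``, so each
    subject's last beat is dropped (it has no successor); the forward
    convention keeps every point latency inside its own RR window when the
    columns are later divided by RR.  Subjects with a single beat are
    skipped with a warning.
    """
    _check_monotone_r_times(sorted(beats, key=lambda b: (b.subject_id, b.beat_index)))
    groups: dict[str, list[AnnotatedComplex]] = {}
    for b in beats:
        groups.setdefault(b.subject_id, []).append(b)

    rows, meta = [], []
    for subject_id in sorted(groups):
        sub = sorted(groups[subject_id], key=lambda b: b.beat_index)
        if len(sub) < 2:
            warnings.warn(
                f"subject {subject_id!r} has a single beat; skipped "
                "(RR needs a successor R peak)",
                stacklevel=2,
            )
            continue
        for cur, nxt in zip(sub[:-1], sub[1:]):
            rr = nxt.r_time - cur.r_time
            row = {RR_COLUMN: rr}
            for col, p in POINT_FOR_COLUMN.items():
                t = cur.point_times.get(p)
                if t is None:
                    row[col] = np.nan
                else:
                    latency = t - cur.r_time
                    if latency < 0:
                        raise ValidationError(
                            f"subject {cur.subject_id!r} beat {cur.beat_index}: "
                            f"negative interval for {p.value} ({latency:.4f} s)"
                        )
                    row[col] = latency
            rows.append(row)
            meta.append(
                {
                    "subject_id": cur.subject_id,
                    "dataset_id": cur.dataset_id,
                    "subtype": cur.subtype.value,
                    "beat_index": cur.beat_index,
                }
            )

    values = pd.DataFrame(rows, columns=ALL_COLUMNS, dtype=float)
    row_meta = pd.DataFrame(meta, columns=["subject_id", "dataset_id", "subtype", "beat_index"])
    return IntervalMatrix(values=values, row_meta=row_meta, state="raw")


@dataclass
class MissingnessSummary:
    """Percent-missing tables per characteristic point and per co-missing group."""

    per_point: pd.DataFrame  # point label x dataset_id -> percent missing
    co_missing: pd.DataFrame  # group name x dataset_id -> percent jointly missing

    def overall(self, point: PointLabel | str) -> float:
        p = PointLabel(point).value
        return float(self.per_point.loc[p].mean())


def missingness_summary(beats: list[AnnotatedComplex]) -> MissingnessSummary:
    """Percentage of beats per dataset in which each point (and each
    co-missing group, ABE and YOZ) is absent."""
    if not beats:
        raise ValidationError("missingness_summary requires a non-empty beat list")
    datasets = sorted({b.dataset_id for b in beats})
    per_point = pd.DataFrame(
        index=[p.value for p in PointLabel], columns=datasets, dtype=float
    )
    co = pd.DataFrame(index=list(CO_MISSING_GROUPS), columns=datasets, dtype=float)
    for ds in datasets:
        ds_beats = [b for b in beats if b.dataset_id == ds]
        n = len(ds_beats)
        for p in PointLabel:
            n_missing = sum(1 for b in ds_beats if p not in b.point_times)
            per_point.loc[p.value, ds] = 100.0 * n_missing / n
        for name, grp in CO_MISSING_GROUPS.items():
            n_joint = sum(
                1 for b in ds_beats if all(p not in b.point_times for p in grp)
            )
            co.loc[name, ds] = 100.0 * n_joint / n
    return MissingnessSummary(per_point=per_point, co_missing=co)
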