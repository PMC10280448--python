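"""Applying a trained NARX network: closed-loop imputation of missing
characteristic points, X-candidate selection, and denormalization back to
seconds.

Imputation runs the network along each (subject, subtype) stream in a
hybrid closed loop: feedback taps read the observed value of a channel when
the annotation exists and the network's own previous prediction when it
does not, so free-running never discards usable observations.  Observed
cells are never overwritten.  ABEXYOZu complexes carry no points at all and
are flagged unforecastable, as are the first ``d_max`` rows of each stream
(nothing fills their delay lines) and streams shorter than the delay
horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .icg_data import (
    POINT_COLUMNS,
    RR_COLUMN,
    IntervalMatrix,
    PointLabel,
    SubtypeLabel,
    ValidationError,
)
from .metrics import EvalReport, MetricError
from .narx import NarxModel, step
from .preprocess import StateError, Stream, invert_sum_of_squares, denormalize_rr, to_sequences

OBSERVED, IMPUTED, UNFORECASTABLE = "observed", "imputed", "unforecastable"


@dataclass
class ImputationResult:
    """Completed matrix plus per-cell provenance and held-out diagnostics."""

    completed: IntervalMatrix
    provenance: pd.DataFrame  # rows x point columns, values in {observed, imputed, unforecastable}
    per_subtype: list[EvalReport] = field(default_factory=list)
    predictions: pd.DataFrame | None = None  # model forecast for every forecastable cell

    @property
    def n_imputed(self) -> int:
        return int((self.provenance == IMPUTED).to_numpy().sum())


def impute_missing_points(
    model: NarxModel,
    m: IntervalMatrix,
    missing_mask: pd.DataFrame,
    group_by_subtype: bool = True,
) -> ImputationResult:
    """Fill originally-missing cells with closed-loop network forecasts.

    ``m`` must be sum-of-squares normalized with the model's own stored
    scales (the cells flagged in ``missing_mask`` hold mean-imputed
    placeholders from preprocessing; they are replaced by forecasts).
    """
    if not model.fitted:
        raise ValidationError("impute_missing_points requires a fitted model")
    if m.state != "ss_normalized":
        raise StateError("matrix must be ss_normalized with the model's scales")
    if model.ss_scale is not None:
        if m.ss_scale is None or not np.allclose(
            m.ss_scale.reindex(POINT_COLUMNS), model.ss_scale.reindex(POINT_COLUMNS)
        ):
            raise ValidationError(
                "matrix normalization scales do not match the model's stored scales"
            )
    cfg = model._base_config()  # tap arithmetic in base alignment
    d_max = cfg.d_max
    missing = missing_mask[POINT_COLUMNS].to_numpy(dtype=bool)

    out = m.copy()
    values = out.values[POINT_COLUMNS].to_numpy()
    prov = np.full(values.shape, OBSERVED, dtype=object)
    prov[missing] = UNFORECASTABLE  # upgraded to "imputed" where a forecast lands
    pred_grid = np.full(values.shape, np.nan)

    for stream in to_sequences(m, group_by_subtype=group_by_subtype):
        rows = stream.row_indices
        if group_by_subtype and stream.subtype == SubtypeLabel.ABEXYOZu.value:
            continue
        if len(rows) < d_max + 1:
            continue
        series = values[rows]  # placeholders present where missing
        stream_missing = missing[rows]
        # hybrid working series: observed values, overwritten by forecasts
        y_work = series.copy()
        for t in range(d_max, len(rows)):
            xin = np.concatenate([y_work[t - d] for d in cfg.input_delays])
            yin = np.concatenate([y_work[t - d] for d in cfg.feedback_delays])
            pred = step(model.weights, cfg, xin[None, :], yin[None, :])[0]
            pred_grid[rows[t]] = pred
            fill = stream_missing[t]
            y_work[t, fill] = pred[fill]
            values[rows[t], fill] = pred[fill]
            prov[rows[t], fill] = IMPUTED

    out.values[POINT_COLUMNS] = values
    provenance = pd.DataFrame(prov, columns=POINT_COLUMNS, index=m.values.index)
    predictions = pd.DataFrame(pred_grid, columns=POINT_COLUMNS, index=m.values.index)

    # held-out check: forecast accuracy on cells that were actually observed
    per_subtype: list[EvalReport] = []
    obs_ok = ~missing & ~np.isnan(pred_grid)
    for st in pd.unique(m.row_meta["subtype"]):
        in_st = (m.row_meta["subtype"] == st).to_numpy()
        cell = obs_ok & in_st[:, None]
        if cell.sum() < 2:
            continue
        try:
            per_subtype.append(
                EvalReport.from_pair(
                    str(st), m.values[POINT_COLUMNS].to_numpy()[cell], pred_grid[cell]
                )
            )
        except MetricError:
            continue
    return ImputationResult(
        completed=out,
        provenance=provenance,
        per_subtype=per_subtype,
        predictions=predictions,
    )


@dataclass
class XSelection:
    """Which X candidate tracks the typical-beat reference best, per scope."""

    per_scope: pd.DataFrame  # index scope, columns sd_x1, sd_x2, chosen, n

    def chosen(self, scope: str) -> str:
        return str(self.per_scope.loc[scope, "chosen"])


def select_x(
    m: IntervalMatrix,
    scope_by: tuple[str, ...] = ("dataset_id",),
    reference: dict[str, dict[str, float]] | None = None,
) -> XSelection:
    """Pick the true X among the X1/X2 candidates, per scope.

    For each candidate the deviation of its RR-ratio from a reference ratio
    is measured as the root-mean-square about the reference (a plain SD
    would be blind to a constant offset); the candidate with the smaller
    deviation is chosen, ties going to X2 (the true X of typical beats).
    The default reference is the candidate's own mean RR-ratio over the
    typical (ABEXYOZ0) beats of the same dataset; pass ``reference`` as
    ``{dataset_id: {"RX1": r1, "RX2": r2}}`` to override.
    """
    if m.state == "raw":
        ratios = m.values[["RX1", "RX2"]].to_numpy() / m.values[[RR_COLUMN]].to_numpy()
    else:
        # rr_normalized / ss_normalized matrices already hold ratios
        # (undo the ss scale if present so both candidates are comparable)
        vals = m.values[["RX1", "RX2"]].to_numpy()
        if m.state == "ss_normalized":
            vals = vals * m.ss_scale[["RX1", "RX2"]].to_numpy()[None, :]
        ratios = vals
    if np.isnan(ratios).any():
        raise ValidationError("select_x requires both X candidates populated in scope")

    meta = m.row_meta
    typical = (meta["subtype"] == SubtypeLabel.ABEXYOZ0.value).to_numpy()
    rows = []
    for key, grp in meta.groupby(list(scope_by), sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        scope = "/".join(str(k) for k in key)
        pos = meta.index.get_indexer(grp.index)
        if len(pos) < 2:
            raise ValidationError(f"scope {scope!r} has fewer than 2 rows; sd undefined")
        ds = str(grp["dataset_id"].iloc[0])
        devs = {}
        for j, col in enumerate(("RX1", "RX2")):
            if reference is not None:
                ref = reference[ds][col]
            else:
                in_ds_typ = typical & (meta["dataset_id"] == ds).to_numpy()
                if not in_ds_typ.any():
                    raise ValidationError(
                        f"dataset {ds!r} has no typical (ABEXYOZ0) beats for the reference"
                    )
                ref = float(np.mean(ratios[in_ds_typ, j]))
            devs[col] = float(np.sqrt(np.mean((ratios[pos, j] - ref) ** 2)))
        chosen = "X1" if devs["RX1"] < devs["RX2"] else "X2"
        rows.append(
            {"scope": scope, "sd_x1": devs["RX1"], "sd_x2": devs["RX2"], "chosen": chosen,
             "n": len(pos)}
        )
    return XSelection(per_scope=pd.DataFrame(rows).set_index("scope"))


def denormalize(m: IntervalMatrix, ss_scale: pd.Series | None = None) -> IntervalMatrix:
    """Invert both normalization steps: multiply the point columns by the
    stored sum-of-squares scales, then by the row's RR.  Round-trips with
    the forward chain to within 1e-12."""
    if m.state != "ss_normalized":
        raise StateError(f"denormalize requires state 'ss_normalized', got {m.state!r}")
    work = m
    if ss_scale is not None:
        if (ss_scale <= 0).any():
            raise ValidationError("ss_scale must be positive")
        work = m.copy()
        work.ss_scale = ss_scale.reindex(POINT_COLUMNS)
    return denormalize_rr(invert_sum_of_squares(work))
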