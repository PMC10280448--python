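"""Evaluation suite: MSE/RMSE/MAE, Pearson R, VEcv, Lin's CCC, and the
detection-rate bookkeeping used to quantify how many characteristic points
a forecaster recovers.

VEcv (variance explained in cross-validation) is

    VEcv = 100 · (1 − Σ(tᵢ − pᵢ)² / Σ(tᵢ − t̄)²)

in percent; it is ≤ 100, can go negative, and carries a five-band verbal
scale (very poor … excellent).  Lin's concordance correlation coefficient,

    CCC = 2·cov(t, p) / (var(t) + var(p) + (t̄ − p̄)²),

penalizes both decorrelation and mean/scale shifts, so |CCC| ≤ |R| always.
Population (1/n) moments are used throughout, following Lin's original
definition; Pearson R is a moment ratio and unaffected by the choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class MetricError(ValueError):
    """Raised when a metric is undefined for the given inputs."""


def _flatten_pair(target, predicted) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(target, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if t.size != p.size:
        raise MetricError(f"length mismatch: target {t.size} vs predicted {p.size}")
    if t.size == 0:
        raise MetricError("empty series")
    return t, p


def basic_errors(target, predicted) -> tuple[float, float, float]:
    """(MSE, RMSE, MAE), pooled over all channels for multichannel input."""
    t, p = _flatten_pair(target, predicted)
    resid = p - t
    mse = float(np.mean(resid**2))
    return mse, float(np.sqrt(mse)), float(np.mean(np.abs(resid)))


def pearson_r(target, predicted) -> float:
    """Product-moment correlation between target and prediction."""
    t, p = _flatten_pair(target, predicted)
    t_c = t - t.mean()
    p_c = p - p.mean()
    denom = np.sqrt(float(t_c @ t_c) * float(p_c @ p_c))
    if denom == 0.0:
        raise MetricError("pearson_r undefined: a series has zero variance")
    return float(t_c @ p_c / denom)


def vecv(target, predicted) -> float:
    """Variance explained in cross-validation, in percent (≤ 100)."""
    t, p = _flatten_pair(target, predicted)
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    if ss_tot == 0.0:
        raise MetricError("vecv undefined: target has zero variance")
    ss_err = float(np.sum((t - p) ** 2))
    return 100.0 * (1.0 - ss_err / ss_tot)


#: (upper bound inclusive, label) — scanned in order; above the last bound
#: the label is "excellent".
VECV_BANDS = [
    (10.0, "very poor"),
    (30.0, "poor"),
    (50.0, "average"),
    (80.0, "good"),
]


def vecv_category(v: float) -> str:
    """Map a VEcv percentage to its five-band verbal label
    (very poor ≤ 10 < poor ≤ 30 < average ≤ 50 < good ≤ 80 < excellent)."""
    if not np.isfinite(v):
        raise MetricError(f"vecv_category requires a finite value, got {v}")
    for upper, label in VECV_BANDS:
        if v <= upper:
            return label
    return "excellent"


def lin_ccc(target, predicted) -> float:
    """Lin's concordance correlation coefficient (population moments)."""
    t, p = _flatten_pair(target, predicted)
    n = t.size
    t_mean, p_mean = t.mean(), p.mean()
    var_t = float(np.mean((t - t_mean) ** 2))
    var_p = float(np.mean((p - p_mean) ** 2))
    if var_t == 0.0 and var_p == 0.0:
        raise MetricError("lin_ccc undefined: both series have zero variance")
    cov = float(np.mean((t - t_mean) * (p - p_mean)))
    return 2.0 * cov / (var_t + var_p + (t_mean - p_mean) ** 2)


@dataclass
class EvalReport:
    """Metric bundle for one evaluation scope (all / dataset / subtype / point)."""

    scope: str
    n: int
    mse: float
    rmse: float
    mae: float
    pearson_r: float
    vecv: float
    ccc: float

    @classmethod
    def from_pair(cls, scope: str, target, predicted) -> "EvalReport":
        t, p = _flatten_pair(target, predicted)
        mse, rmse, mae = basic_errors(t, p)
        return cls(
            scope=scope,
            n=t.size,
            mse=mse,
            rmse=rmse,
            mae=mae,
            pearson_r=pearson_r(t, p),
            vecv=vecv(t, p),
            ccc=lin_ccc(t, p),
        )

    @property
    def vecv_category(self) -> str:
        return vecv_category(self.vecv)

    def to_dict(self) -> dict:
        return {
            "scope": self.scope,
            "n": self.n,
            "vecv": self.vecv,
            "mse": self.mse,
            "rmse": self.rmse,
            "mae": self.mae,
            "r": self.pearson_r,
            "ccc": self.ccc,
            "category": self.vecv_category,
        }


def eval_table(reports: list[EvalReport]) -> pd.DataFrame:
    """Scope-by-metric table (VEcv %, MSE, RMSE, MAE, R, CCC)."""
    return pd.DataFrame([r.to_dict() for r in reports]).set_index("scope")


def grouped_eval(
    target: np.ndarray,
    predicted: np.ndarray,
    groups: pd.Series | np.ndarray,
    prefix: str = "",
) -> list[EvalReport]:
    """One EvalReport per group label (rows of multichannel arrays pooled)."""
    target = np.asarray(target, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    groups = np.asarray(groups)
    out = []
    for g in pd.unique(groups):
        m = groups == g
        out.append(EvalReport.from_pair(f"{prefix}{g}", target[m], predicted[m]))
    return out


@dataclass
class DetectionRates:
    """Detection percentages before/after imputation, per point, plus the
    effective complex-level rate (ABEXYOZu complexes excluded from the
    denominator because they carry no points to detect)."""

    per_point: pd.DataFrame  # index point label, columns before/after (% detected)
    effective_rate: float  # % of non-u complexes fully detected after imputation
    n_complexes: int
    n_u: int
    warnings: list[str] = field(default_factory=list)


def detection_rates(
    before_missing: pd.Series,
    after_missing: pd.Series,
    n_complexes: int,
    n_u: int,
    n_detected_complexes: int,
) -> DetectionRates:
    """Convert missing-percent tables to detected-percent tables.

    ``before_missing``/``after_missing`` give percent-missing per point
    label; ``n_detected_complexes`` counts complexes with every forecastable
    point present after imputation.
    """
    before_missing = before_missing.astype(float)
    after_missing = after_missing.reindex(before_missing.index).astype(float)
    warns = []
    worse = after_missing[after_missing > before_missing]
    for label, val in worse.items():
        warns.append(
            f"point {label}: missing rate rose from "
            f"{before_missing[label]:.1f}% to {val:.1f}% (imputation should only add points)"
        )
    per_point = pd.DataFrame(
        {"before": 100.0 - before_missing, "after": 100.0 - after_missing}
    )
    denom = n_complexes - n_u
    if denom <= 0:
        raise MetricError("no non-ABEXYOZu complexes; effective rate undefined")
    eff = 100.0 * n_detected_complexes / denom
    return DetectionRates(
        per_point=per_point,
        effective_rate=eff,
        n_complexes=n_complexes,
        n_u=n_u,
        warnings=warns,
    )
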