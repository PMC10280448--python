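"""NARX recurrent network: topology, forward passes, delay removal, Jacobian.

The model is a nonlinear autoregression with exogenous inputs,

    y(t) = W_o · tanh(W_x·[x(t−1); x(t−2)] + W_y·[y(t−1); y(t−2)] + b_h) + b_o,

with a single tanh hidden layer and a linear output layer.  In the ICG
application the exogenous line carries the same eight ratio channels as the
target line (x ≡ y), making this an order-2 nonlinear autoregression with
duplicated tap banks.  Two operating modes exist:

- *open loop* (series-parallel): feedback taps read the true recorded
  targets — teacher forcing, used for training; each time step is then an
  independent feed-forward sample, so no backpropagation through time is
  needed.
- *closed loop* (parallel): feedback taps read the network's own previous
  predictions — free-running multi-step forecasting.

"Removing the delay" shifts every tap index by −1 so the network emits each
forecast one time step ahead of the original alignment; the weights are
untouched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class NarxConfig:
    """Network topology: channel counts, hidden size and tap delays."""

    n_in: int = 8
    n_out: int = 8
    n_hidden: int = 10
    input_delays: tuple[int, ...] = (1, 2)
    feedback_delays: tuple[int, ...] = (1, 2)
    hidden_activation: str = "tanh"

    def __post_init__(self) -> None:
        for name, delays in (
            ("input_delays", self.input_delays),
            ("feedback_delays", self.feedback_delays),
        ):
            if not delays or any(d < 0 or d != int(d) for d in delays):
                raise ValueError(f"{name} must be non-empty non-negative integers")
        if self.n_hidden < 1 or self.n_in < 1 or self.n_out < 1:
            raise ValueError("n_in, n_out and n_hidden must all be >= 1")
        if self.hidden_activation not in {"tanh", "linear"}:
            raise ValueError(f"unknown hidden_activation {self.hidden_activation!r}")

    @property
    def d_max(self) -> int:
        return max(max(self.input_delays), max(self.feedback_delays))

    @property
    def d_min(self) -> int:
        return min(min(self.input_delays), min(self.feedback_delays))

    @property
    def n_xin(self) -> int:
        return self.n_in * len(self.input_delays)

    @property
    def n_yin(self) -> int:
        return self.n_out * len(self.feedback_delays)


@dataclass
class NarxWeights:
    """All trainable parameters; flattenable to one vector for the optimizers."""

    W_x: np.ndarray  # n_hidden x n_xin
    W_y: np.ndarray  # n_hidden x n_yin
    b_h: np.ndarray  # n_hidden
    W_o: np.ndarray  # n_out x n_hidden
    b_o: np.ndarray  # n_out

    def check(self, cfg: NarxConfig) -> None:
        expected = {
            "W_x": (cfg.n_hidden, cfg.n_xin),
            "W_y": (cfg.n_hidden, cfg.n_yin),
            "b_h": (cfg.n_hidden,),
            "W_o": (cfg.n_out, cfg.n_hidden),
            "b_o": (cfg.n_out,),
        }
        for name, shape in expected.items():
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite entries")

    def to_vector(self) -> np.ndarray:
        return np.concatenate(
            [self.W_x.ravel(), self.W_y.ravel(), self.b_h, self.W_o.ravel(), self.b_o]
        )

    @classmethod
    def from_vector(cls, v: np.ndarray, cfg: NarxConfig) -> "NarxWeights":
        sizes = [
            cfg.n_hidden * cfg.n_xin,
            cfg.n_hidden * cfg.n_yin,
            cfg.n_hidden,
            cfg.n_out * cfg.n_hidden,
            cfg.n_out,
        ]
        if v.size != sum(sizes):
            raise ValueError(f"weight vector has size {v.size}, expected {sum(sizes)}")
        parts = np.split(v, np.cumsum(sizes)[:-1])
        return cls(
            W_x=parts[0].reshape(cfg.n_hidden, cfg.n_xin),
            W_y=parts[1].reshape(cfg.n_hidden, cfg.n_yin),
            b_h=parts[2].copy(),
            W_o=parts[3].reshape(cfg.n_out, cfg.n_hidden),
            b_o=parts[4].copy(),
        )

    def copy(self) -> "NarxWeights":
        return NarxWeights(
            self.W_x.copy(), self.W_y.copy(), self.b_h.copy(), self.W_o.copy(), self.b_o.copy()
        )


def n_weights(cfg: NarxConfig) -> int:
    return (
        cfg.n_hidden * (cfg.n_xin + cfg.n_yin + 1) + cfg.n_out * (cfg.n_hidden + 1)
    )


def init_weights(cfg: NarxConfig, seed: int, method: str = "nguyen-widrow") -> NarxWeights:
    """Seeded layer initialization.

    ``nguyen-widrow`` scales the hidden-layer rows so the tanh units start
    in their active region with receptive fields spread over the input
    space; ``uniform`` is a plain U(−0.5, 0.5) fallback.
    """
    rng = np.random.default_rng(seed)
    n_inputs = cfg.n_xin + cfg.n_yin
    if method == "nguyen-widrow":
        beta = 0.7 * cfg.n_hidden ** (1.0 / n_inputs)
        W = rng.uniform(-1.0, 1.0, size=(cfg.n_hidden, n_inputs))
        norms = np.linalg.norm(W, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        W = beta * W / norms
        b_h = rng.uniform(-beta, beta, size=cfg.n_hidden)
    elif method == "uniform":
        W = rng.uniform(-0.5, 0.5, size=(cfg.n_hidden, n_inputs))
        b_h = rng.uniform(-0.5, 0.5, size=cfg.n_hidden)
    else:
        raise ValueError(f"unknown init method {method!r}")
    w = NarxWeights(
        W_x=W[:, : cfg.n_xin],
        W_y=W[:, cfg.n_xin :],
        b_h=b_h,
        W_o=rng.uniform(-0.5, 0.5, size=(cfg.n_out, cfg.n_hidden)),
        b_o=rng.uniform(-0.5, 0.5, size=cfg.n_out),
    )
    w.check(cfg)
    return w


def _activation(cfg: NarxConfig, z: np.ndarray) -> np.ndarray:
    return np.tanh(z) if cfg.hidden_activation == "tanh" else z


def step(w: NarxWeights, cfg: NarxConfig, xin: np.ndarray, yin: np.ndarray) -> np.ndarray:
    """One network evaluation; ``xin``/``yin`` are (batches of) concatenated
    tap vectors in delay order."""
    z = xin @ w.W_x.T + yin @ w.W_y.T + w.b_h
    h = _activation(cfg, z)
    return h @ w.W_o.T + w.b_o


def _tap_matrix(seq: np.ndarray, delays: tuple[int, ...], t_idx: np.ndarray) -> np.ndarray:
    """Concatenate seq[t−d] for d in delays, for each t in t_idx."""
    return np.concatenate([seq[t_idx - d] for d in delays], axis=1)


def forward_open(
    w: NarxWeights, cfg: NarxConfig, x_seq: np.ndarray, y_seq: np.ndarray
) -> np.ndarray:
    """Teacher-forced pass: feedback taps read the true targets.

    Returns a T x n_out array; rows before the delay horizon are NaN.  With
    base delays {1, 2}, row t is the network's one-step forecast of y(t);
    after delay removal (taps {0, 1}) row t is the forecast of y(t+1).
    """
    x_seq = np.atleast_2d(np.asarray(x_seq, dtype=float))
    y_seq = np.atleast_2d(np.asarray(y_seq, dtype=float))
    if x_seq.ndim == 2 and x_seq.shape[0] == 1 and cfg.n_in == 1:
        x_seq = x_seq.T
    if y_seq.ndim == 2 and y_seq.shape[0] == 1 and cfg.n_out == 1:
        y_seq = y_seq.T
    T = y_seq.shape[0]
    if x_seq.shape[0] != T:
        raise ValueError("x_seq and y_seq must have the same length")
    if T < cfg.d_max + 1:
        raise ValueError(f"sequence length {T} < d_max + 1 = {cfg.d_max + 1}")
    t_idx = np.arange(cfg.d_max, T)
    xin = _tap_matrix(x_seq, cfg.input_delays, t_idx)
    yin = _tap_matrix(y_seq, cfg.feedback_delays, t_idx)
    out = np.full((T, cfg.n_out), np.nan)
    out[t_idx] = step(w, cfg, xin, yin)
    return out


def forward_closed(
    w: NarxWeights,
    cfg: NarxConfig,
    x_seq: np.ndarray,
    y_init: np.ndarray,
    x_from_feedback: bool = False,
) -> np.ndarray:
    """Free-running pass: feedback taps read the network's own predictions.

    ``y_init`` supplies exactly ``d_max`` true values for positions
    0 … d_max−1; predictions fill positions d_max … T−1.  Requires every
    feedback delay ≥ 1 (a zero-delay feedback tap would be circular); the
    delay-removed variant is evaluated through its shift identity instead.

    With ``x_from_feedback=True`` the exogenous taps also read the working
    prediction buffer — the pure autoregressive case where the exogenous
    line carries the same series as the target (x ≡ y) and future inputs
    are unknown; ``x_seq`` then only sets the forecast length.
    """
    x_seq = np.asarray(x_seq, dtype=float).reshape(-1, cfg.n_in)
    y_init = np.asarray(y_init, dtype=float).reshape(-1, cfg.n_out)
    if min(cfg.feedback_delays) < 1:
        raise ValueError("closed-loop pass requires all feedback delays >= 1")
    if x_from_feedback and min(cfg.input_delays) < 1:
        raise ValueError("x_from_feedback requires all input delays >= 1")
    if y_init.shape[0] != cfg.d_max:
        raise ValueError(
            f"y_init must supply exactly d_max = {cfg.d_max} rows, got {y_init.shape[0]}"
        )
    T = x_seq.shape[0]
    if T < cfg.d_max + 1:
        raise ValueError(f"sequence length {T} < d_max + 1 = {cfg.d_max + 1}")
    y_work = np.full((T, cfg.n_out), np.nan)
    y_work[: cfg.d_max] = y_init
    x_work = y_work if x_from_feedback else x_seq
    for t in range(cfg.d_max, T):
        xin = np.concatenate([x_work[t - d] for d in cfg.input_delays])
        yin = np.concatenate([y_work[t - d] for d in cfg.feedback_delays])
        y_work[t] = step(w, cfg, xin[None, :], yin[None, :])[0]
    out = y_work.copy()
    out[: cfg.d_max] = np.nan
    return out


@dataclass
class NarxModel:
    """A (possibly fitted) NARX network plus the state needed to apply it:
    normalization scales for inversion and the delay-removal flag."""

    config: NarxConfig
    weights: NarxWeights
    removed_delay: bool = False
    ss_scale: pd.Series | None = None
    fitted: bool = False
    notes: dict = field(default_factory=dict)

    @property
    def output_lead(self) -> int:
        """How many steps ahead of slot t the emitted forecast refers to
        (0 for base alignment, 1 after delay removal)."""
        return 1 if self.removed_delay else 0

    def predict_open(self, series: np.ndarray, x_seq: np.ndarray | None = None) -> np.ndarray:
        """Teacher-forced predictions over a recorded series (x ≡ y unless
        an explicit exogenous series is given)."""
        x = series if x_seq is None else x_seq
        return forward_open(self.weights, self.config, x, series)

    def predict_closed(
        self, x_seq: np.ndarray, y_init: np.ndarray, x_from_feedback: bool = False
    ) -> np.ndarray:
        """Free-running forecast.  For a delay-removed model the base-tap
        network is run and its outputs shifted one slot earlier (the taps
        {0,1} read exactly the values the base taps {1,2} read one step
        later), including the one extra forecast beyond the series end."""
        if not self.removed_delay:
            return forward_closed(
                self.weights, self.config, x_seq, y_init, x_from_feedback=x_from_feedback
            )
        base = self._base_config()
        x_seq = np.asarray(x_seq, dtype=float).reshape(-1, base.n_in)
        ext = np.vstack([x_seq, x_seq[-1:]])  # slot T forecasts y(T): taps T-1, T-2 only
        preds = forward_closed(
            self.weights, base, ext, y_init, x_from_feedback=x_from_feedback
        )
        return preds[1:]

    def _base_config(self) -> NarxConfig:
        if not self.removed_delay:
            return self.config
        return replace(
            self.config,
            input_delays=tuple(d + 1 for d in self.config.input_delays),
            feedback_delays=tuple(d + 1 for d in self.config.feedback_delays),
        )

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "config": {
                "n_in": self.config.n_in,
                "n_out": self.config.n_out,
                "n_hidden": self.config.n_hidden,
                "input_delays": list(self.config.input_delays),
                "feedback_delays": list(self.config.feedback_delays),
                "hidden_activation": self.config.hidden_activation,
            },
            "weights": {
                name: getattr(self.weights, name).tolist()
                for name in ("W_x", "W_y", "b_h", "W_o", "b_o")
            },
            "removed_delay": self.removed_delay,
            "fitted": self.fitted,
            "ss_scale": None if self.ss_scale is None else self.ss_scale.to_dict(),
            "notes": self.notes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NarxModel":
        if d.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema {d.get('schema_version')!r}")
        cfg = NarxConfig(
            n_in=d["config"]["n_in"],
            n_out=d["config"]["n_out"],
            n_hidden=d["config"]["n_hidden"],
            input_delays=tuple(d["config"]["input_delays"]),
            feedback_delays=tuple(d["config"]["feedback_delays"]),
            hidden_activation=d["config"]["hidden_activation"],
        )
        w = NarxWeights(**{k: np.asarray(v, dtype=float) for k, v in d["weights"].items()})
        w.check(cfg)
        ss = d.get("ss_scale")
        return cls(
            config=cfg,
            weights=w,
            removed_delay=d.get("removed_delay", False),
            ss_scale=None if ss is None else pd.Series(ss),
            fitted=d.get("fitted", False),
            notes=d.get("notes", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "NarxModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def remove_delay(model: NarxModel) -> NarxModel:
    """Shift every tap index by −1, leaving the weights bit-identical.

    The returned model emits each forecast one time step ahead of the
    original alignment (its output at slot t refers to y(t+1)).
    """
    if not model.fitted:
        raise ValueError("remove_delay requires a fitted model")
    cfg = model.config
    if cfg.d_min < 1:
        raise ValueError("minimum delay is already 0; cannot remove another delay")
    new_cfg = replace(
        cfg,
        input_delays=tuple(d - 1 for d in cfg.input_delays),
        feedback_delays=tuple(d - 1 for d in cfg.feedback_delays),
    )
    return NarxModel(
        config=new_cfg,
        weights=model.weights.copy(),
        removed_delay=True,
        ss_scale=None if model.ss_scale is None else model.ss_scale.copy(),
        fitted=True,
        notes=dict(model.notes),
    )


# ---------------------------------------------------------------------------
# Teacher-forced sample construction and exact residual Jacobian
# ---------------------------------------------------------------------------


def build_samples(
    cfg: NarxConfig, series_list: list[np.ndarray], x_list: list[np.ndarray] | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flatten teacher-forced sequences into per-step samples.

    Returns ``(Xtap, Ytap, targets)`` with one row per predictable time
    step; teacher forcing makes each step independent, so these rows can be
    split and shuffled freely.
    """
    Xt, Yt, Tg = [], [], []
    for i, series in enumerate(series_list):
        y = np.asarray(series, dtype=float).reshape(-1, cfg.n_out)
        x = y if x_list is None else np.asarray(x_list[i], dtype=float).reshape(-1, cfg.n_in)
        T = y.shape[0]
        if T < cfg.d_max + 1:
            continue
        t_idx = np.arange(cfg.d_max, T)
        Xt.append(_tap_matrix(x, cfg.input_delays, t_idx))
        Yt.append(_tap_matrix(y, cfg.feedback_delays, t_idx))
        Tg.append(y[t_idx])
    if not Xt:
        raise ValueError("no sequence is longer than the delay horizon")
    return np.vstack(Xt), np.vstack(Yt), np.vstack(Tg)


def error_gradient(
    w: NarxWeights,
    cfg: NarxConfig,
    Xtap: np.ndarray,
    Ytap: np.ndarray,
    targets: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Residuals and their exact Jacobian w.r.t. every weight.

    Residual ordering: sample-major, channel-minor (``e = (ŷ − y).ravel()``).
    The Jacobian column order matches :meth:`NarxWeights.to_vector`.  Only
    teacher-forced (open-loop) batches are supported — the gradient through
    free-running feedback is deliberately out of scope.
    """
    N = Xtap.shape[0]
    K = cfg.n_out
    z = Xtap @ w.W_x.T + Ytap @ w.W_y.T + w.b_h  # N x h
    if cfg.hidden_activation == "tanh":
        h = np.tanh(z)
        gprime = 1.0 - h**2
    else:
        h = z
        gprime = np.ones_like(z)
    preds = h @ w.W_o.T + w.b_o
    e = (preds - targets).ravel()

    # A[i,k,j] = d yhat_ik / d z_ij = W_o[k,j] * g'(z_ij)
    A = w.W_o[None, :, :] * gprime[:, None, :]  # N x K x h

    J_Wx = np.einsum("ikj,im->ikjm", A, Xtap).reshape(N * K, -1)
    J_Wy = np.einsum("ikj,im->ikjm", A, Ytap).reshape(N * K, -1)
    J_bh = A.reshape(N * K, -1)
    # d yhat_ik / d W_o[k',j] = h_ij if k' == k else 0
    J_Wo = np.zeros((N, K, K, cfg.n_hidden))
    idx = np.arange(K)
    J_Wo[:, idx, idx, :] = h[:, None, :]
    J_Wo = J_Wo.reshape(N * K, -1)
    J_bo = np.tile(np.eye(K), (N, 1))
    return e, np.hstack([J_Wx, J_Wy, J_bh, J_Wo, J_bo])


def loss_mse(
    w: NarxWeights, cfg: NarxConfig, Xtap: np.ndarray, Ytap: np.ndarray, targets: np.ndarray
) -> float:
    """Mean squared residual over all channels jointly (unweighted)."""
    preds = step(w, cfg, Xtap, Ytap)
    return float(np.mean((preds - targets) ** 2))
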