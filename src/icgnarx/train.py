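"""Training algorithms for the NARX network.

Three optimizers are provided, matching the families commonly compared for
this architecture:

- Levenberg–Marquardt (LM): damped Gauss–Newton on the residual Jacobian;
  fast on small/medium networks, the usual first choice.
- Scaled conjugate gradient (SCG, Møller 1993): gradient-only with a
  model-trust-region scaling; uses no explicit JᵀJ, hence far less memory.
- Bayesian regularization (BR): LM on the penalized objective
  F = β·E_D + α·E_W with MacKay evidence updates of (α, β) through the
  effective number of parameters γ.

All of them train in open loop (teacher forcing), so the loss is an
ordinary sum of squares over independent per-step samples.  Early stopping
monitors a validation partition with a patience counter and always reports
the weights from the best-validation epoch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .narx import (
    NarxConfig,
    NarxModel,
    NarxWeights,
    build_samples,
    error_gradient,
    loss_mse,
    n_weights,
)
from .narx import step as narx_step
from .preprocess import SplitIndices, split_data

logger = logging.getLogger(__name__)

MU_MAX = 1e10


@dataclass(frozen=True)
class TrainOptions:
    """Optimizer settings shared by the three algorithms."""

    algorithm: str = "LM"  # LM | SCG | BR
    max_epochs: int = 1000
    max_fail: int = 6  # validation patience
    mu0: float = 1e-3
    mu_inc: float = 10.0
    mu_dec: float = 0.1
    goal: float = 0.0
    seed: int = 0
    use_validation: bool | None = None  # None -> algorithm default (BR: off)
    fix_alpha: float | None = None  # BR only: freeze alpha (0 reduces BR to LM)
    min_grad: float = 1e-10

    def __post_init__(self) -> None:
        if self.algorithm not in {"LM", "SCG", "BR"}:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if not (self.mu0 > 0 and 0 < self.mu_dec < 1 < self.mu_inc):
            raise ValueError("require mu0 > 0 and 0 < mu_dec < 1 < mu_inc")

    @property
    def validation_enabled(self) -> bool:
        if self.use_validation is None:
            return self.algorithm != "BR"
        return self.use_validation


@dataclass
class TrainReport:
    """Loss traces and the weight snapshot from the best-validation epoch."""

    algorithm: str
    seed: int
    train_trace: list[float]
    val_trace: list[float]
    test_trace: list[float]
    stop_reason: str  # max_epochs | val_fail | goal | mu_overflow | min_grad
    best_epoch: int
    weights: NarxWeights
    extras: dict = field(default_factory=dict)

    @property
    def final_train_loss(self) -> float:
        return self.train_trace[self.best_epoch]


@dataclass
class TrainingData:
    """Teacher-forced samples plus their train/val/test partition."""

    Xtap: np.ndarray
    Ytap: np.ndarray
    targets: np.ndarray
    split: SplitIndices

    @classmethod
    def from_series(
        cls,
        cfg: NarxConfig,
        series_list: list[np.ndarray],
        seed: int,
        ratios: tuple[float, float, float] = (0.70, 0.15, 0.15),
    ) -> "TrainingData":
        Xtap, Ytap, targets = build_samples(cfg, series_list)
        return cls(Xtap, Ytap, targets, split_data(len(Xtap), seed, ratios))

    def part(self, which: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        idx = getattr(self.split, which)
        return self.Xtap[idx], self.Ytap[idx], self.targets[idx]


class _Stopper:
    """Validation patience bookkeeping shared by the three trainers."""

    def __init__(self, opts: TrainOptions, cfg: NarxConfig, data: TrainingData):
        self.opts = opts
        self.cfg = cfg
        self.data = data
        self.train_trace: list[float] = []
        self.val_trace: list[float] = []
        self.test_trace: list[float] = []
        self.best_val = np.inf
        self.best_epoch = -1
        self.best_w: np.ndarray | None = None
        self.fails = 0

    def record(self, wv: np.ndarray, train_loss: float) -> str | None:
        w = NarxWeights.from_vector(wv, self.cfg)
        val = loss_mse(w, self.cfg, *self.data.part("val")) if len(self.data.split.val) else np.nan
        test = (
            loss_mse(w, self.cfg, *self.data.part("test")) if len(self.data.split.test) else np.nan
        )
        self.train_trace.append(train_loss)
        self.val_trace.append(val)
        self.test_trace.append(test)
        epoch = len(self.train_trace) - 1

        monitor = val if self.opts.validation_enabled and np.isfinite(val) else train_loss
        if monitor < self.best_val:
            self.best_val = monitor
            self.best_epoch = epoch
            self.best_w = wv.copy()
            self.fails = 0
        else:
            self.fails += 1
            if self.opts.validation_enabled and self.fails >= self.opts.max_fail:
                return "val_fail"
        if train_loss <= self.opts.goal:
            return "goal"
        return None

    def report(self, algorithm: str, stop_reason: str, extras: dict) -> TrainReport:
        assert self.best_w is not None
        return TrainReport(
            algorithm=algorithm,
            seed=self.opts.seed,
            train_trace=self.train_trace,
            val_trace=self.val_trace,
            test_trace=self.test_trace,
            stop_reason=stop_reason,
            best_epoch=self.best_epoch,
            weights=NarxWeights.from_vector(self.best_w, self.cfg),
            extras=extras,
        )


def _solve_lm_step(H: np.ndarray, g: np.ndarray, mu: float) -> np.ndarray:
    A = H + mu * np.eye(H.shape[0])
    try:
        L = np.linalg.cholesky(A)
        return -np.linalg.solve(L.T, np.linalg.solve(L, g))
    except np.linalg.LinAlgError as exc:
        raise FloatingPointError(f"singular LM system at mu={mu:g}") from exc


def train_lm(model: NarxModel, data: TrainingData, opts: TrainOptions) -> TrainReport:
    """Levenberg–Marquardt: Δw = −(JᵀJ + μI)⁻¹Jᵀe with multiplicative
    damping; a step is accepted only if the training loss decreases, so the
    accepted-step loss trace is non-increasing."""
    if opts.algorithm != "LM":
        raise ValueError("opts.algorithm must be 'LM'")
    return _train_lm_core(model, data, opts, bayes=False)


def train_br(model: NarxModel, data: TrainingData, opts: TrainOptions) -> TrainReport:
    """Bayesian regularization: the LM inner loop on F = β·E_D + α·E_W with
    MacKay evidence re-estimation of α and β each epoch.

    γ = N_w − α·tr(H⁻¹) counts the effectively used parameters; α = γ/(2E_W)
    and β = (N − γ)/(2E_D).  Validation stopping is off by default for this
    trainer (the regularizer itself controls overfitting); pass
    ``use_validation=True`` to re-enable it.
    """
    if opts.algorithm != "BR":
        raise ValueError("opts.algorithm must be 'BR'")
    return _train_lm_core(model, data, opts, bayes=True)


def _train_lm_core(
    model: NarxModel, data: TrainingData, opts: TrainOptions, bayes: bool
) -> TrainReport:
    cfg = model.config
    wv = model.weights.to_vector()
    Xt, Yt, Tg = data.part("train")
    Nw = n_weights(cfg)
    N_resid = Tg.size
    mu = opts.mu0

    if bayes:
        alpha = 0.0 if opts.fix_alpha is not None else 0.01
        if opts.fix_alpha is not None:
            alpha = opts.fix_alpha
        beta = 1.0
    else:
        alpha, beta = 0.0, 1.0

    stopper = _Stopper(opts, cfg, data)
    stop_reason = "max_epochs"
    mu_trace, alpha_trace, gamma_trace = [], [], []

    def objective(e_vec: np.ndarray, w_vec: np.ndarray) -> float:
        return beta * 0.5 * float(e_vec @ e_vec) + alpha * 0.5 * float(w_vec @ w_vec)

    e, J = error_gradient(NarxWeights.from_vector(wv, cfg), cfg, Xt, Yt, Tg)
    for epoch in range(opts.max_epochs):
        H = beta * (J.T @ J) + alpha * np.eye(Nw)
        g = beta * (J.T @ e) + alpha * wv
        if np.linalg.norm(g) < opts.min_grad:
            stopper.record(wv, float(np.mean(e**2)))
            stop_reason = "min_grad"
            break
        F = objective(e, wv)
        accepted = False
        while mu <= MU_MAX:
            try:
                dw = _solve_lm_step(H, g, mu)
            except FloatingPointError:
                mu *= opts.mu_inc
                continue
            wv_new = wv + dw
            w_new = NarxWeights.from_vector(wv_new, cfg)
            e_new = (narx_step(w_new, cfg, Xt, Yt) - Tg).ravel()
            if objective(e_new, wv_new) < F:
                wv, e = wv_new, e_new
                mu = max(mu * opts.mu_dec, 1e-20)
                accepted = True
                break
            mu *= opts.mu_inc
        if not accepted:
            stopper.record(wv, float(np.mean(e**2)))
            stop_reason = "mu_overflow"
            break

        e, J = error_gradient(NarxWeights.from_vector(wv, cfg), cfg, Xt, Yt, Tg)

        gamma = np.nan
        if bayes and opts.fix_alpha is None:
            # tr(H^-1) through the eigenvalues of the regularized Hessian;
            # H >= alpha*I so a small floor keeps this finite
            eigs = np.linalg.eigvalsh(beta * (J.T @ J) + alpha * np.eye(Nw))
            Hinv_tr = float(np.sum(1.0 / np.maximum(eigs, 1e-12)))
            E_W = 0.5 * float(wv @ wv)
            E_D = 0.5 * float(e @ e)
            gamma = Nw - alpha * Hinv_tr
            if not (0.0 <= gamma <= Nw):
                logger.warning("effective-parameter count gamma=%.3g clamped", gamma)
                gamma = float(np.clip(gamma, 0.0, Nw))
            alpha = float(np.clip(gamma / max(2.0 * E_W, 1e-12), 0.0, 1e8))
            beta = float(
                np.clip(max(N_resid - gamma, 1e-3) / max(2.0 * E_D, 1e-12), 1e-8, 1e12)
            )

        train_loss = float(np.mean(e**2))
        mu_trace.append(mu)
        alpha_trace.append(alpha)
        gamma_trace.append(gamma)
        logger.info(
            "epoch %d train_mse=%.3e mu=%.1e%s",
            epoch,
            train_loss,
            mu,
            f" alpha={alpha:.3e}" if bayes else "",
        )
        reason = stopper.record(wv, train_loss)
        if reason is not None:
            stop_reason = reason
            break

    extras = {"mu_trace": mu_trace}
    if bayes:
        extras.update(
            alpha_trace=alpha_trace, gamma_trace=gamma_trace, final_alpha=alpha, final_beta=beta
        )
    return stopper.report("BR" if bayes else "LM", stop_reason, extras)


def train_scg(model: NarxModel, data: TrainingData, opts: TrainOptions) -> TrainReport:
    """Møller's scaled conjugate gradient on the sum-of-squares loss.

    Uses only gradient (Jᵀe) products and a finite-difference curvature
    estimate along the search direction — no explicit JᵀJ is ever formed.
    """
    if opts.algorithm != "SCG":
        raise ValueError("opts.algorithm must be 'SCG'")
    cfg = model.config
    Xt, Yt, Tg = data.part("train")
    Nw = n_weights(cfg)

    def f_and_g(wv: np.ndarray) -> tuple[float, np.ndarray]:
        e, J = error_gradient(NarxWeights.from_vector(wv, cfg), cfg, Xt, Yt, Tg)
        return 0.5 * float(e @ e), J.T @ e

    wv = model.weights.to_vector()
    sigma0 = 1e-5
    lam, lam_bar = 1e-6, 0.0
    f_w, r_neg = f_and_g(wv)
    if not np.isfinite(f_w):
        raise FloatingPointError("non-finite loss at initialization")
    r = -r_neg
    p = r.copy()
    success = True
    stopper = _Stopper(opts, cfg, data)
    stop_reason = "max_epochs"
    delta = 0.0

    for epoch in range(opts.max_epochs):
        p_norm2 = float(p @ p)
        if np.sqrt(float(r @ r)) < opts.min_grad or p_norm2 == 0.0:
            stopper.record(wv, f_w * 2.0 / Tg.size)
            stop_reason = "min_grad"
            break
        if success:
            sigma = sigma0 / np.sqrt(p_norm2)
            _, g_sig = f_and_g(wv + sigma * p)
            s = (g_sig - (-r)) / sigma
            delta = float(p @ s)
        delta_adj = delta + (lam - lam_bar) * p_norm2
        if delta_adj <= 0:
            lam_bar = 2.0 * (lam - delta / p_norm2)
            delta_adj = -delta + lam * p_norm2
            lam = lam_bar
        mu_k = float(p @ r)
        alpha_k = mu_k / delta_adj
        f_new, g_new_neg = f_and_g(wv + alpha_k * p)
        if not np.isfinite(f_new):
            raise FloatingPointError("non-finite loss during SCG line step")
        comparison = 2.0 * delta_adj * (f_w - f_new) / (mu_k**2)
        if comparison >= 0:
            wv = wv + alpha_k * p
            f_w = f_new
            r_new = -g_new_neg
            lam_bar = 0.0
            success = True
            if (epoch + 1) % Nw == 0:
                p = r_new.copy()
            else:
                beta_k = (float(r_new @ r_new) - float(r_new @ r)) / mu_k
                p = r_new + beta_k * p
            r = r_new
            if comparison >= 0.75:
                lam = max(lam * 0.25, 1e-15)
        else:
            lam_bar = lam
            success = False
        if comparison < 0.25:
            lam = lam + delta_adj * (1.0 - comparison) / p_norm2

        train_loss = f_w * 2.0 / Tg.size  # back to mean-squared scale
        reason = stopper.record(wv, train_loss)
        if reason is not None:
            stop_reason = reason
            break

    return stopper.report("SCG", stop_reason, {"final_lambda": lam})


_TRAINERS = {"LM": train_lm, "SCG": train_scg, "BR": train_br}


def fit(model: NarxModel, data: TrainingData, opts: TrainOptions) -> tuple[NarxModel, TrainReport]:
    """Train and return a fitted copy of the model plus the report."""
    report = _TRAINERS[opts.algorithm](model, data, opts)
    fitted = NarxModel(
        config=model.config,
        weights=report.weights,
        removed_delay=model.removed_delay,
        ss_scale=model.ss_scale,
        fitted=True,
        notes={**model.notes, "algorithm": opts.algorithm, "seed": opts.seed},
    )
    return fitted, report


def compare_algorithms(
    model: NarxModel,
    data: TrainingData,
    opts_list: list[TrainOptions],
) -> pd.DataFrame:
    """Train the same initial model under each option set on identical
    splits and rank on the held-out test partition.

    Primary ranking key is VEcv (higher is better), ties broken by lower
    RMSE, then by declaration order.  A failed training lands at the bottom
    with its error message in the ``note`` column.
    """
    from .metrics import basic_errors, pearson_r, vecv  # local import, no cycle

    if len(opts_list) < 1:
        raise ValueError("compare_algorithms needs at least one option set")
    rows = []
    for order, opts in enumerate(opts_list):
        row = {"algorithm": opts.algorithm, "declared": order, "note": ""}
        try:
            fitted, report = fit(model, data, opts)
            Xt, Yt, Tg = data.part("test")
            preds = narx_step(fitted.weights, model.config, Xt, Yt)
            mse, rmse, mae = basic_errors(Tg, preds)
            row.update(
                vecv=vecv(Tg, preds),
                mse=mse,
                rmse=rmse,
                mae=mae,
                r=pearson_r(Tg, preds),
                stop_reason=report.stop_reason,
                failed=False,
            )
        except (FloatingPointError, np.linalg.LinAlgError, ValueError) as exc:
            row.update(
                vecv=-np.inf, mse=np.inf, rmse=np.inf, mae=np.inf, r=np.nan,
                stop_reason="failed", failed=True, note=str(exc),
            )
        rows.append(row)
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["failed", "vecv", "rmse", "declared"],
        ascending=[True, False, True, True],
        kind="stable",
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
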