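"""Hybrid parameter estimation on two timescales.

Fast timescale: per-sample recursive least squares (RLS) with a forgetting
factor updates the affine rule consequents. Slow timescale: damped
Gauss-Newton (Levenberg-Marquardt style) or momentum gradient descent
refines the membership-function parameters on a sliding window, with
consequents held fixed during the step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .anfis import ANFISModel, NoActiveRuleError

DEFAULT_FORGETTING = 0.995
DEFAULT_P0 = 1e3
DAMPING_OVERFLOW = 1e12


@dataclass
class RLSState:
    """Recursive least-squares state for one output channel."""

    theta: np.ndarray
    P: np.ndarray
    lam: float = DEFAULT_FORGETTING

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float).ravel()
        self.P = np.asarray(self.P, dtype=float)
        if not (0.0 < self.lam <= 1.0):
            raise ValueError("forgetting factor must lie in (0, 1]")
        n = self.theta.size
        if self.P.shape != (n, n):
            raise ValueError("covariance shape does not match theta")


def init_rls(n_params: int, lam: float = DEFAULT_FORGETTING, p0: float = DEFAULT_P0) -> RLSState:
    """Fresh RLS state: theta = 0, P = p0 * I."""
    return RLSState(np.zeros(n_params), p0 * np.eye(n_params), lam)


def build_regressor(wbar: np.ndarray, x: Sequence[float]) -> np.ndarray:
    """Stack normalized-strength-weighted affine features, rule-major.

    Returns ``concat_i(wbar_i * [1, x_1, ..., x_n])`` so that the model
    output of a channel equals ``a @ theta_channel`` exactly.
    """
    wbar = np.asarray(wbar, dtype=float)
    xa = np.concatenate(([1.0], np.asarray(x, dtype=float)))
    return np.outer(wbar, xa).ravel()


def rls_update(state: RLSState, a: np.ndarray, y_target: float) -> RLSState:
    """One forgetting-factor RLS step; returns a new state.

    K = P a / (lam + a' P a); theta += K (y - a' theta);
    P = (P - K a' P) / lam, re-symmetrized.
    """
    a = np.asarray(a, dtype=float).ravel()
    if not (np.all(np.isfinite(a)) and np.isfinite(y_target)):
        raise FloatingPointError("non-finite RLS input")
    Pa = state.P @ a
    denom = state.lam + a @ Pa
    K = Pa / denom
    theta = state.theta + K * (y_target - a @ state.theta)
    P = (state.P - np.outer(K, Pa)) / state.lam
    P = 0.5 * (P + P.T)
    return RLSState(theta, P, state.lam)


# -- consequent <-> flat-theta plumbing -------------------------------------


def theta_from_model(model: ANFISModel, channel: int) -> np.ndarray:
    return np.concatenate([r.consequent[channel] for r in model.rules])


def set_model_theta(model: ANFISModel, channel: int, theta: np.ndarray) -> None:
    n = model.n_inputs + 1
    theta = np.asarray(theta, dtype=float)
    for i, r in enumerate(model.rules):
        r.consequent[channel] = theta[i * n : (i + 1) * n]
    model.mark_dirty()


class ConsequentEstimator:
    """Independent RLS per output channel over shared antecedents."""

    def __init__(self, model: ANFISModel, lam: float = DEFAULT_FORGETTING, p0: float = DEFAULT_P0):
        n = model.n_rules * (model.n_inputs + 1)
        self.states = [
            RLSState(theta_from_model(model, ch), p0 * np.eye(n), lam)
            for ch in range(model.n_outputs)
        ]

    def update(self, model: ANFISModel, wbar: np.ndarray, x: Sequence[float], y: Sequence[float]) -> None:
        a = build_regressor(wbar, x)
        y = np.atleast_1d(np.asarray(y, dtype=float))
        for ch, st in enumerate(self.states):
            self.states[ch] = rls_update(st, a, float(y[ch]))
            set_model_theta(model, ch, self.states[ch].theta)


# -- slow timescale: premise refinement -------------------------------------


@dataclass
class PremiseOptState:
    """State of the membership-parameter optimizer."""

    alpha: np.ndarray
    damping: float = 1e-2
    momentum: np.ndarray | None = None
    eta: float = 0.01
    m: float = 0.9
    no_progress: bool = False

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.momentum is None:
            self.momentum = np.zeros_like(self.alpha)


def init_premise_opt(model: ANFISModel, damping: float = 1e-2, eta: float = 0.01, m: float = 0.9) -> PremiseOptState:
    return PremiseOptState(model.get_premise_params(), damping=damping, eta=eta, m=m)


def _finite_diff_jacobian(residual_fn: Callable[[np.ndarray], np.ndarray], alpha: np.ndarray, rel_step: float = 1e-6) -> tuple[np.ndarray, np.ndarray]:
    e0 = np.asarray(residual_fn(alpha), dtype=float)
    J = np.empty((e0.size, alpha.size))
    for j in range(alpha.size):
        h = rel_step * max(1.0, abs(alpha[j]))
        ap = alpha.copy()
        ap[j] += h
        J[:, j] = (np.asarray(residual_fn(ap)) - e0) / h
    return e0, J


def lma_step(
    residual_fn: Callable[[np.ndarray], np.ndarray],
    alpha: np.ndarray,
    damping: float,
) -> tuple[np.ndarray, bool, float, float]:
    """One damped Gauss-Newton step on a generic residual vector.

    Solves ``(J'J + damping * diag(J'J)) delta = J'e`` with a forward
    finite-difference Jacobian and accepts the step only if the residual
    RMS decreases. Returns ``(alpha, accepted, damping, rmse)`` where
    ``rmse`` is the post-step (accepted) or pre-step (rejected) value.
    """
    alpha = np.asarray(alpha, dtype=float)
    e0, J = _finite_diff_jacobian(residual_fn, alpha)
    rmse0 = float(np.sqrt(np.mean(e0**2)))
    if rmse0 == 0.0:
        return alpha, True, damping, 0.0
    JtJ = J.T @ J
    A = JtJ + damping * np.diag(np.maximum(np.diag(JtJ), 1e-30))
    g = J.T @ e0
    try:
        delta = np.linalg.solve(A, g)
    except np.linalg.LinAlgError:
        delta, *_ = np.linalg.lstsq(A, g, rcond=None)
    # J is the Jacobian of the residual, so the descent direction is -delta
    cand = alpha - delta
    e1 = np.asarray(residual_fn(cand), dtype=float)
    rmse1 = float(np.sqrt(np.mean(e1**2)))
    if np.isfinite(rmse1) and rmse1 < rmse0:
        return cand, True, max(damping / 10.0, 1e-12), rmse1
    return alpha, False, damping * 10.0, rmse0


def _batch_residuals(model: ANFISModel, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    res = []
    for x, y in zip(X, Y):
        try:
            out, _ = model.forward(x)
        except NoActiveRuleError:
            out = np.zeros(model.n_outputs)
        res.append(np.atleast_1d(y) - out)
    return np.concatenate(res)


def premise_step(
    model: ANFISModel,
    opt: PremiseOptState,
    batch: tuple[np.ndarray, np.ndarray],
    mode: str = "lma",
) -> tuple[ANFISModel, PremiseOptState, float]:
    """One slow-timescale refinement of the membership parameters.

    Consequents stay fixed. ``mode="lma"`` performs an accept/reject damped
    Gauss-Newton step (damping /10 on accept, x10 on reject, overflow beyond
    1e12 flags ``no_progress``); ``mode="gd_momentum"`` takes a momentum
    gradient step on the mean squared residual. Widths are projected back to
    strictly positive values by ``set_premise_params``.
    """
    X = np.atleast_2d(np.asarray(batch[0], dtype=float))
    Y = np.atleast_2d(np.asarray(batch[1], dtype=float).reshape(X.shape[0], -1))

    def residual_fn(alpha: np.ndarray) -> np.ndarray:
        model.set_premise_params(alpha)
        return _batch_residuals(model, X, Y)

    alpha0 = model.get_premise_params()
    if mode == "lma":
        alpha1, accepted, damping, rmse = lma_step(residual_fn, alpha0, opt.damping)
        model.set_premise_params(alpha1)
        # projection may have altered widths; re-read the effective vector
        alpha1 = model.get_premise_params()
        new_opt = replace(opt, alpha=alpha1, damping=damping,
                          no_progress=damping > DAMPING_OVERFLOW)
        return model, new_opt, rmse
    if mode == "gd_momentum":
        def mse_fn(alpha: np.ndarray) -> float:
            e = residual_fn(alpha)
            return float(np.mean(e**2))

        g = np.empty_like(alpha0)
        f0 = mse_fn(alpha0)
        for j in range(alpha0.size):
            h = 1e-6 * max(1.0, abs(alpha0[j]))
            ap = alpha0.copy()
            ap[j] += h
            g[j] = (mse_fn(ap) - f0) / h
        buf = opt.m * opt.momentum - opt.eta * g
        model.set_premise_params(alpha0 + buf)
        alpha1 = model.get_premise_params()
        rmse = float(np.sqrt(np.mean(residual_fn(alpha1) ** 2)))
        return model, replace(opt, alpha=alpha1, momentum=buf), rmse
    raise ValueError(f"unknown premise mode {mode!r}")


# -- dual-timescale driver --------------------------------------------------


@dataclass
class DualTimescaleHistory:
    rls_steps: int = 0
    premise_steps: int = 0
    rmse: list = field(default_factory=list)


def dual_timescale_update(
    model: ANFISModel,
    estimator: ConsequentEstimator,
    stream: Iterable[tuple[np.ndarray, np.ndarray]],
    n_premise: int = 50,
    window: int = 500,
    mode: str = "lma",
    opt: PremiseOptState | None = None,
) -> tuple[ANFISModel, ConsequentEstimator, PremiseOptState, DualTimescaleHistory]:
    """Consume a sample stream: RLS on every sample, premise refinement every
    ``n_premise`` samples on a sliding window of the most recent samples.
    Ordering per step: forward pass -> RLS -> (periodically) premise step.
    """
    if opt is None:
        opt = init_premise_opt(model)
    hist = DualTimescaleHistory()
    buf_x: list[np.ndarray] = []
    buf_y: list[np.ndarray] = []
    for t, (x, y) in enumerate(stream, start=1):
        x = np.asarray(x, dtype=float)
        y = np.atleast_1d(np.asarray(y, dtype=float))
        try:
            _, trace = model.forward(x)
        except NoActiveRuleError:
            continue
        estimator.update(model, trace.normalized, x, y)
        hist.rls_steps += 1
        buf_x.append(x)
        buf_y.append(y)
        if len(buf_x) > window:
            buf_x.pop(0)
            buf_y.pop(0)
        if t % n_premise == 0:
            model, opt, rmse = premise_step(
                model, opt, (np.array(buf_x), np.array(buf_y)), mode=mode
            )
            hist.premise_steps += 1
            hist.rmse.append(rmse)
    return model, estimator, opt, hist


# -- offline training utilities ---------------------------------------------


def batch_rmse(model: ANFISModel, X: np.ndarray, Y: np.ndarray) -> float:
    e = _batch_residuals(model, np.atleast_2d(X), np.atleast_2d(Y).reshape(len(np.atleast_2d(X)), -1))
    return float(np.sqrt(np.mean(e**2)))


def train(
    model: ANFISModel,
    X: np.ndarray,
    Y: np.ndarray,
    epochs: int = 250,
    lam: float = 1.0,
    mode: str = "lma",
    premise_every: int = 1,
    patience: int = 20,
    tol: float = 1e-10,
    history_csv=None,
) -> pd.DataFrame:
    """Offline hybrid training: one RLS sweep per epoch plus one premise
    pass every ``premise_every`` epochs; early stop on RMSE plateau.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float).reshape(X.shape[0], -1)
    estimator = ConsequentEstimator(model, lam=lam)
    opt = init_premise_opt(model)
    rows = []
    best = np.inf
    stale = 0
    for epoch in range(epochs):
        for x, y in zip(X, Y):
            try:
                _, trace = model.forward(x)
            except NoActiveRuleError:
                continue
            estimator.update(model, trace.normalized, x, y)
        accepted = True
        if premise_every and (epoch + 1) % premise_every == 0:
            prev_alpha = model.get_premise_params()
            model, opt, _ = premise_step(model, opt, (X, Y), mode=mode)
            accepted = not np.array_equal(prev_alpha, model.get_premise_params())
        rmse = batch_rmse(model, X, Y)
        rows.append({"epoch": epoch, "rmse": rmse, "accepted": accepted, "damping": opt.damping})
        if rmse < best - tol:
            best = rmse
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break
    hist = pd.DataFrame(rows)
    if history_csv is not None:
        hist.to_csv(history_csv, index=False)
    return hist


def kfold_validate(
    model_factory: Callable[[], ANFISModel],
    X: np.ndarray,
    Y: np.ndarray,
    k: int = 5,
    epochs: int = 20,
    rng: np.random.Generator | None = None,
    **train_kw,
) -> pd.DataFrame:
    """k-fold cross-validation of the hybrid trainer on a dataset."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float).reshape(X.shape[0], -1)
    n = X.shape[0]
    idx = np.arange(n)
    if rng is not None:
        rng.shuffle(idx)
    folds = np.array_split(idx, k)
    rows = []
    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(idx, test_idx)
        m = model_factory()
        train(m, X[train_idx], Y[train_idx], epochs=epochs, **train_kw)
        rows.append(
            {
                "fold": i,
                "train_rmse": batch_rmse(m, X[train_idx], Y[train_idx]),
                "test_rmse": batch_rmse(m, X[test_idx], Y[test_idx]),
            }
        )
    return pd.DataFrame(rows)
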