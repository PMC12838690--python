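"""Dual-state habituation dynamics.

Short-term component H_s charges under stimulation (at a velocity-dependent
rate) and decays quickly; the long-term component H_l integrates H_s and
decays slowly. Both carry optional Wiener-increment noise and are clamped
to [0, 1]. Integrated with fixed-step Euler-Maruyama:

    H_s += (-D_s H_s + I_s(v) S) dt + sigma_s sqrt(dt) Z_s
    H_l += (-D_l H_l + I_l H_s) dt + sigma_l sqrt(dt) Z_l
    I_s(v) = I_s0 exp(-k_v v)

The same drift, with the noise scales zeroed, serves as the controller's
habituation observer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class HabituationParams:
    """Rates are 1/s; ``dt`` is the integrator step in seconds.

    Construction enforces ``dt <= 0.1 / max(d_s, d_l)`` so the explicit
    integrator stays far from its stability limit.
    """

    d_s: float = 0.02
    d_l: float = 0.0005
    i_l: float = 0.002
    i_s0: float = 0.08
    k_v: float = 1.5
    sigma_s: float = 0.005
    sigma_l: float = 0.001
    dt: float = 0.05

    def __post_init__(self) -> None:
        vals = [self.d_s, self.d_l, self.i_l, self.i_s0, self.k_v,
                self.sigma_s, self.sigma_l, self.dt]
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("habituation parameters must be finite")
        if self.d_s <= 0 or self.d_l <= 0 or self.dt <= 0:
            raise ValueError("decay rates and dt must be positive")
        if min(self.i_l, self.i_s0, self.k_v, self.sigma_s, self.sigma_l) < 0:
            raise ValueError("increments and noise scales must be non-negative")
        if self.dt > 0.1 / max(self.d_s, self.d_l):
            raise ValueError(
                f"dt={self.dt} too large for decay rates (max "
                f"{0.1 / max(self.d_s, self.d_l):.4g} s)"
            )

    def noise_free(self) -> "HabituationParams":
        return replace(self, sigma_s=0.0, sigma_l=0.0)


@dataclass
class HabituationState:
    h_s: float = 0.0
    h_l: float = 0.0
    t: float = 0.0


def short_term_increment(v: float, params: HabituationParams) -> float:
    """Velocity-dependent short-term charging rate I_s0 * exp(-k_v v).

    Faster locomotion slows habituation onset.
    """
    if v < 0:
        raise ValueError("velocity must be non-negative")
    return params.i_s0 * float(np.exp(-params.k_v * v))


def step(
    state: HabituationState,
    s: float,
    v: float,
    params: HabituationParams,
    rng: np.random.Generator | None = None,
) -> HabituationState:
    """One Euler-Maruyama step; components clamped to [0, 1] afterwards.

    ``s`` is the normalized stimulus drive in [0, 1], ``v`` the normalized
    linear velocity. ``rng`` is required whenever a noise scale is nonzero.
    """
    dt = params.dt
    if params.sigma_s > 0 or params.sigma_l > 0:
        if rng is None:
            raise ValueError("rng required for stochastic integration")
        z_s, z_l = rng.standard_normal(2)
    else:
        z_s = z_l = 0.0
    i_s = short_term_increment(v, params)
    h_s = state.h_s + (-params.d_s * state.h_s + i_s * s) * dt \
        + params.sigma_s * np.sqrt(dt) * z_s
    h_l = state.h_l + (-params.d_l * state.h_l + params.i_l * state.h_s) * dt \
        + params.sigma_l * np.sqrt(dt) * z_l
    return HabituationState(
        h_s=float(np.clip(h_s, 0.0, 1.0)),
        h_l=float(np.clip(h_l, 0.0, 1.0)),
        t=state.t + dt,
    )


def combined_level(state: HabituationState, mode: str = "sum_clamp",
                   weights: tuple[float, float] = (1.0, 1.0)) -> float:
    """Scalar habituation level H in [0, 1].

    Default rule: ``min(1, H_s + H_l)``; ``mode="weighted"`` uses a clamped
    weighted sum instead.
    """
    if mode == "sum_clamp":
        return min(1.0, state.h_s + state.h_l)
    if mode == "weighted":
        return float(np.clip(weights[0] * state.h_s + weights[1] * state.h_l, 0.0, 1.0))
    raise ValueError(f"unknown combination mode {mode!r}")


def simulate(
    params: HabituationParams,
    stimulus,
    velocity,
    n_steps: int,
    rng: np.random.Generator | None = None,
    initial: HabituationState | None = None,
) -> pd.DataFrame:
    """Integrate a trajectory; ``stimulus``/``velocity`` are callables of t
    or constants. Returns a frame with columns t, h_s, h_l, h, s, v.
    """
    s_fn = stimulus if callable(stimulus) else (lambda t: stimulus)
    v_fn = velocity if callable(velocity) else (lambda t: velocity)
    state = initial if initial is not None else HabituationState()
    rows = []
    for _ in range(n_steps):
        s = float(s_fn(state.t))
        v = float(v_fn(state.t))
        state = step(state, s, v, params, rng)
        rows.append((state.t, state.h_s, state.h_l, combined_level(state), s, v))
    return pd.DataFrame(rows, columns=["t", "h_s", "h_l", "h", "s", "v"])
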