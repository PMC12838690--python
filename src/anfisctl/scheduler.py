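"""Habituation-compensating stimulus shaping.

Two mechanisms: a linear-chirp amplitude modulation whose instantaneous
frequency grows with the habituation level, and an adaptive inter-burst
interval that lengthens rest periods as habituation accumulates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid


@dataclass(frozen=True)
class ChirpParams:
    """f(t) = f_start + k_f * H(t) * t; modulation depth A(H) = a1 * H."""

    f_start: float = 25.0
    k_f: float = 5.0
    a1: float = 0.5

    def __post_init__(self) -> None:
        if self.f_start <= 0:
            raise ValueError("f_start must be positive")
        if self.k_f < 0:
            raise ValueError("k_f must be non-negative")
        if not (0.0 <= self.a1 <= 1.0):
            raise ValueError("a1 must lie in [0, 1] to keep P(t) non-negative")

    def depth(self, h):
        return self.a1 * np.asarray(h, dtype=float)


@dataclass(frozen=True)
class IBIParams:
    """IBI(H) = IBI_max - (IBI_max - IBI_min) * exp(-k * H)."""

    ibi_min: float = 2.0
    ibi_max: float = 30.0
    k: float = 3.0

    def __post_init__(self) -> None:
        if not (0 < self.ibi_min <= self.ibi_max):
            raise ValueError("require 0 < ibi_min <= ibi_max")
        if self.k <= 0:
            raise ValueError("k must be positive")


@dataclass
class StimulationCommand:
    """One stimulation burst as emitted by a controller.

    ``mod_depth`` is the chirp amplitude-modulation depth A(H) applied
    within the burst; it rides along so the plant model can account for the
    stimulus-pattern variation it implies.
    """

    amplitude: float  # V
    frequency: float  # Hz
    duration_ms: float
    ibi: float  # s until the next burst may be issued
    side: str  # "left" | "right" | "none"
    mod_depth: float = 0.0

    def __post_init__(self) -> None:
        if self.side not in ("left", "right", "none"):
            raise ValueError(f"invalid side {self.side!r}")
        if self.side != "none" and self.duration_ms <= 0:
            raise ValueError("active commands need a positive duration")


@dataclass(frozen=True)
class SafeRanges:
    """Hardware-safe output bounds; commands are clipped into these."""

    amplitude: tuple[float, float] = (0.5, 3.5)
    frequency: tuple[float, float] = (10.0, 200.0)
    duration_ms: tuple[float, float] = (50.0, 500.0)


def clip_command(cmd: StimulationCommand, ranges: SafeRanges) -> tuple[StimulationCommand, bool]:
    """Clip a command into the safe ranges; flags whether clipping occurred."""
    amp = float(np.clip(cmd.amplitude, *ranges.amplitude))
    frq = float(np.clip(cmd.frequency, *ranges.frequency))
    dur = float(np.clip(cmd.duration_ms, *ranges.duration_ms))
    clipped = (amp, frq, dur) != (cmd.amplitude, cmd.frequency, cmd.duration_ms)
    return StimulationCommand(amp, frq, dur, cmd.ibi, cmd.side, cmd.mod_depth), clipped


def chirp_phase(times: np.ndarray, h: np.ndarray, params: ChirpParams) -> np.ndarray:
    """Accumulated phase phi(t) = 2*pi * integral of f_start + k_f*H(tau)*tau.

    Cumulative trapezoid on the supplied grid; phi(0) = 0 and phi is
    non-decreasing for in-range H.
    """
    times = np.asarray(times, dtype=float)
    h = np.asarray(h, dtype=float)
    if times.shape != h.shape:
        raise ValueError("times and H series must be aligned")
    f_inst = params.f_start + params.k_f * h * times
    return 2.0 * np.pi * cumulative_trapezoid(f_inst, times, initial=0.0)


def modulate_pulse(
    p_base: np.ndarray, h: np.ndarray, times: np.ndarray, params: ChirpParams
) -> np.ndarray:
    """P(t) = P_base(t) * (1 + A(H(t)) * sin(phi(t)))."""
    p_base = np.asarray(p_base, dtype=float)
    phi = chirp_phase(times, np.asarray(h, dtype=float), params)
    return p_base * (1.0 + params.depth(h) * np.sin(phi))


def inter_burst_interval(h: float, params: IBIParams) -> float:
    """Rest period in seconds; IBI_min at H=0, saturating to IBI_max."""
    if not (0.0 <= h <= 1.0):
        raise ValueError("habituation level must lie in [0, 1]")
    return params.ibi_max - (params.ibi_max - params.ibi_min) * float(np.exp(-params.k * h))


def waveform_frame(times, p_base, h, params: ChirpParams) -> pd.DataFrame:
    """Tabulate a modulated waveform (t, p_base, h, phi, p) for CSV dumps."""
    phi = chirp_phase(np.asarray(times, float), np.asarray(h, float), params)
    p = np.asarray(p_base, float) * (1.0 + params.depth(h) * np.sin(phi))
    return pd.DataFrame({"t": times, "p_base": p_base, "h": h, "phi": phi, "p": p})
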