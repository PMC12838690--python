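"""Closed-loop trial runner, metric calculators, and paired comparisons.

All metric calculators are pure functions of telemetry frames, so a report
recomputed from a stored CSV matches the in-memory result exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import habituation as hab
from . import plant as plant_mod
from .plant import Arena, PlantState, SpecimenProfile, plant_step, sense

NOT_REACHED = -1.0  # sentinel for half-life "never reached" / undefined metrics

TELEMETRY_COLUMNS = [
    "t", "x", "y", "heading", "v_lin", "v_ang", "h_s", "h_l", "h_latent",
    "h_observer", "err_bear", "dist_targ", "cmd_issued", "cmd_amp", "cmd_freq",
    "cmd_dur", "cmd_side", "stim_active", "turn_cmd", "target_idx",
]


@dataclass
class TrialTelemetry:
    """Per-step trial log plus outcome summary and run metadata."""

    frame: pd.DataFrame
    completed: bool = False
    completion_time: float = math.nan
    targets_reached: int = 0
    targets_attempted: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def completion_rate(self) -> float:
        if self.targets_attempted == 0:
            return 0.0
        return self.targets_reached / self.targets_attempted

    def to_csv(self, path) -> None:
        # default float formatting is shortest-round-trip, so a reloaded
        # frame reproduces the metrics exactly
        self.frame.to_csv(path, index=False)


def _sample_target(rng: np.random.Generator, arena: Arena,
                   state: PlantState | None = None) -> tuple[float, float]:
    """Next waypoint: inside the arena margins, off obstacles and — when the
    plant state is known — in the frontal hemisphere at checkpoint distance,
    so successive legs resemble a corridor course rather than repeated
    about-faces."""
    fallback = None
    for attempt in range(200):
        x = rng.uniform(0.15 * arena.width, 0.85 * arena.width)
        y = rng.uniform(0.15 * arena.height, 0.85 * arena.height)
        if arena.point_in_obstacle(x, y):
            continue
        if fallback is None:
            fallback = (float(x), float(y))
        if state is None:
            return (float(x), float(y))
        dist = math.hypot(x - state.x, y - state.y)
        bearing = math.degrees(math.atan2(y - state.y, x - state.x))
        rel = abs(plant_mod.wrap_angle(bearing - state.heading))
        if 40.0 <= dist <= 110.0 and rel <= 100.0:
            return (float(x), float(y))
    return fallback if fallback is not None else arena.target


def run_trial(
    controller,
    profile: SpecimenProfile,
    arena: Arena,
    duration: float,
    seed: int,
    dt: float = 0.1,
    noise: bool = True,
    waypoints: bool = False,
    target_timeout: float = 60.0,
    initial_state: PlantState | None = None,
) -> TrialTelemetry:
    """Run one seeded closed-loop trial: sense -> control -> actuate.

    With ``waypoints=True`` the trial cycles through successive random
    targets (reach or per-target timeout), which yields a graded completion
    rate; otherwise it ends at the first completion or at ``duration``.
    """
    rng = np.random.default_rng(seed)
    state = initial_state if initial_state is not None else PlantState(
        x=0.15 * arena.width, y=0.15 * arena.height,
        habituation=hab.HabituationState(),
    )
    rows = []
    t = 0.0
    n_steps = int(round(duration / dt))
    completed = False
    completion_time = math.nan
    reached = 0
    attempted = 1 if n_steps > 0 else 0
    target_deadline = target_timeout
    current_arena = arena
    target_idx = 0

    for _ in range(n_steps):
        h_obs = controller.observer_level() if hasattr(controller, "observer_level") else 0.0
        try:
            sensors = sense(state, current_arena, hab_lvl=h_obs, dt=dt)
        except ValueError:
            tel = TrialTelemetry(pd.DataFrame(rows, columns=TELEMETRY_COLUMNS))
            tel.meta["aborted"] = "non-finite or out-of-bounds state"
            return tel
        cmd = controller.step(sensors, t)
        # deliver whatever burst is active during this step
        delivered = controller.active_command(t) if hasattr(controller, "active_command") else cmd
        state_next = plant_step(state, delivered, profile, dt, rng=rng,
                                noise=noise, arena=current_arena)
        turn_cmd = 0.0
        if delivered is not None and delivered.side != "none":
            sign = 1.0 if delivered.side == "left" else -1.0
            nl = math.tanh(state_next.drive / profile.sat_scale)
            turn_cmd = profile.gain * nl * sign
        rows.append((
            t, state.x, state.y, state.heading, state.v_lin, state.v_ang,
            state.habituation.h_s, state.habituation.h_l,
            hab.combined_level(state.habituation), h_obs,
            sensors["err_bear"], sensors["dist_targ"],
            1 if cmd is not None else 0,
            cmd.amplitude if cmd is not None else 0.0,
            cmd.frequency if cmd is not None else 0.0,
            cmd.duration_ms if cmd is not None else 0.0,
            cmd.side if cmd is not None else "none",
            1 if delivered is not None else 0,
            turn_cmd, target_idx,
        ))
        state = state_next
        t += dt
        dist = math.hypot(current_arena.target[0] - state.x,
                          current_arena.target[1] - state.y)
        if dist <= current_arena.completion_radius:
            reached += 1
            if not completed:
                completed = True
                completion_time = t
            if not waypoints:
                break
            target_idx += 1
            attempted += 1
            current_arena = replace(current_arena, target=_sample_target(rng, arena, state))
            target_deadline = t + target_timeout
        elif waypoints and t >= target_deadline:
            target_idx += 1
            attempted += 1
            current_arena = replace(current_arena, target=_sample_target(rng, arena, state))
            target_deadline = t + target_timeout

    frame = pd.DataFrame(rows, columns=TELEMETRY_COLUMNS)
    return TrialTelemetry(
        frame, completed=completed, completion_time=completion_time,
        targets_reached=reached, targets_attempted=attempted if waypoints else 1,
        meta={
            "seed": seed, "dt": dt, "duration": duration,
            "controller": getattr(controller, "name", type(controller).__name__),
            "profile_gain": profile.gain, "profile_threshold": profile.threshold,
            "profile_sat": profile.sat_scale, "omega_max": profile.omega_max,
        },
    )


# -- navigation metrics ------------------------------------------------------


def navigation_metrics(tel: TrialTelemetry, response_fraction: float = 0.25,
                       locomotion_threshold: float = 0.05) -> dict:
    """Directional-control metrics from one telemetry frame.

    direction MAE = mean |bearing error| over locomoting steps; response
    time = median latency from command emission until the turn-rate change
    exceeds ``response_fraction`` of the commanded (habituation-free)
    response; consistency index = % of commands achieving that response;
    path efficiency = straight-line displacement / path length.
    """
    f = tel.frame
    if len(f) == 0:
        raise ValueError("empty telemetry")
    moving = f["v_lin"] > locomotion_threshold
    mae = float(f.loc[moving, "err_bear"].abs().mean()) if moving.any() \
        else float(f["err_bear"].abs().mean())
    dx = np.diff(f["x"].to_numpy())
    dy = np.diff(f["y"].to_numpy())
    path_len = float(np.hypot(dx, dy).sum())
    straight = float(math.hypot(f["x"].iloc[-1] - f["x"].iloc[0],
                                f["y"].iloc[-1] - f["y"].iloc[0]))
    efficiency = 100.0 * min(straight / path_len, 1.0) if path_len > 0 else 0.0

    cmd_idx = np.nonzero(f["cmd_issued"].to_numpy())[0]
    latencies = []
    hits = 0
    omega_max = tel.meta.get("omega_max", 120.0)
    t_arr = f["t"].to_numpy()
    vang = f["v_ang"].to_numpy()
    dur = f["cmd_dur"].to_numpy()
    gain = tel.meta.get("profile_gain", 60.0)
    thr = tel.meta.get("profile_threshold", 1.2)
    sat = tel.meta.get("profile_sat", 1.0)
    amp = f["cmd_amp"].to_numpy()
    for i in cmd_idx:
        # habituation-free expected normalized response to this command
        u = max(0.0, amp[i] - thr)
        expected = gain * math.tanh(u / sat) / omega_max
        if expected <= 0:
            continue
        window_end = t_arr[i] + dur[i] / 1000.0 + 2.0
        j = i
        detected = None
        while j < len(f) and t_arr[j] <= window_end:
            if abs(vang[j] - vang[i]) >= response_fraction * expected:
                detected = t_arr[j] - t_arr[i]
                break
            j += 1
        if detected is not None:
            latencies.append(detected)
            hits += 1
    n_cmd = len([i for i in cmd_idx])
    return {
        "direction_mae_deg": mae,
        "response_time_s": float(np.median(latencies)) if latencies else NOT_REACHED,
        "consistency_index_pct": 100.0 * hits / n_cmd if n_cmd else NOT_REACHED,
        "path_efficiency_pct": efficiency,
        "n_commands": n_cmd,
        "completed": tel.completed,
        "completion_time_s": tel.completion_time,
        "completion_rate_pct": 100.0 * tel.completion_rate,
    }


# -- habituation-resistance metrics -----------------------------------------


def run_pulse_protocol(
    profile: SpecimenProfile,
    n_pulses: int = 50,
    period: float = 10.0,
    amplitude: float = 3.0,
    duration_ms: float = 300.0,
    dt: float = 0.05,
    seed: int = 0,
    noise: bool = False,
    initial: PlantState | None = None,
) -> tuple[pd.DataFrame, PlantState]:
    """Deliver identical supra-threshold pulses at a fixed cadence.

    Returns per-pulse peak turn-rate responses (deg/s) and the final plant
    state (for chaining a rest phase).
    """
    from .scheduler import StimulationCommand

    rng = np.random.default_rng(seed)
    state = initial if initial is not None else PlantState(v_lin=0.3)
    steps_per_period = int(round(period / dt))
    steps_on = int(round(duration_ms / 1000.0 / dt))
    rows = []
    t = 0.0
    cmd = StimulationCommand(amplitude, 50.0, duration_ms, period, "left")
    for pulse in range(n_pulses):
        peak = 0.0
        for k in range(steps_per_period):
            delivered = cmd if k < steps_on else None
            state = plant_step(state, delivered, profile, dt, rng=rng, noise=noise)
            if k < steps_on + int(1.0 / dt):
                sign_resp = state.v_ang * profile.omega_max
                peak = max(peak, abs(sign_resp))
            t += dt
        rows.append((pulse, t, peak, hab.combined_level(state.habituation)))
    return pd.DataFrame(rows, columns=["pulse", "t", "response", "h"]), state


def rest_and_probe(
    profile: SpecimenProfile,
    state: PlantState,
    rest_minutes: float,
    probe_every: float = 60.0,
    amplitude: float = 3.0,
    duration_ms: float = 300.0,
    dt: float = 0.05,
    seed: int = 1,
    noise: bool = False,
) -> pd.DataFrame:
    """Rest the plant, probing the response once per ``probe_every`` seconds."""
    from .scheduler import StimulationCommand

    rng = np.random.default_rng(seed)
    cmd = StimulationCommand(amplitude, 50.0, duration_ms, probe_every, "left")
    steps_on = int(round(duration_ms / 1000.0 / dt))
    rows = []
    t = 0.0
    n_probes = int(round(rest_minutes * 60.0 / probe_every))
    steps_per = int(round(probe_every / dt))
    for probe in range(n_probes):
        peak = 0.0
        for k in range(steps_per):
            delivered = cmd if k < steps_on else None
            state = plant_step(state, delivered, profile, dt, rng=rng, noise=noise)
            if k < steps_on + int(1.0 / dt):
                peak = max(peak, abs(state.v_ang * profile.omega_max))
            t += dt
        rows.append((probe, t / 60.0, peak, hab.combined_level(state.habituation)))
    return pd.DataFrame(rows, columns=["probe", "minutes", "response", "h"])


def habituation_metrics(stimulus_frame: pd.DataFrame,
                        rest_frame: pd.DataFrame | None = None) -> dict:
    """Habituation-resistance metrics from a repeated-stimulus protocol.

    half-life = index (1-based) of the first stimulus whose response drops
    to <= 50% of the first response (sentinel -1 if never); MRL = final
    response as % of initial; recovery rate = mean % of initial regained per
    minute of rest.
    """
    if len(stimulus_frame) < 2:
        raise ValueError("need at least 2 stimuli for habituation metrics")
    resp = stimulus_frame["response"].to_numpy(dtype=float)
    initial = resp[0]
    if initial <= 0:
        raise ValueError("initial response is zero; metrics undefined")
    below = np.nonzero(resp <= 0.5 * initial)[0]
    half_life = float(below[0] + 1) if below.size else NOT_REACHED
    mrl = 100.0 * resp[-1] / initial
    out = {"response_half_life": half_life, "mrl_pct": mrl}
    if rest_frame is not None and len(rest_frame) >= 2:
        pct = 100.0 * rest_frame["response"].to_numpy(dtype=float) / initial
        minutes = rest_frame["minutes"].to_numpy(dtype=float)
        out["recovery_rate_pct_per_min"] = float(
            (pct[-1] - pct[0]) / (minutes[-1] - minutes[0])
        )
    return out


# -- performance score and effective control duration ------------------------


def performance_score(tel: TrialTelemetry, window_s: float = 300.0) -> pd.DataFrame:
    """Rolling composite score: 0.5*(1 - mean|err|/180) + 0.5*response ratio.

    The response ratio is the habituation attenuation factor (1 - latent H),
    i.e. the response amplitude relative to the habituation-free response to
    the same command, averaged over the steps in the window during which a
    stimulus was actually delivered. A window with no stimulation exerts no
    control, so its response term is 0.
    """
    f = tel.frame
    if len(f) == 0:
        raise ValueError("empty telemetry")
    dt = tel.meta.get("dt", 0.1)
    win = max(1, int(round(window_s / dt)))
    err_term = 1.0 - f["err_bear"].abs().rolling(win, min_periods=1).mean() / 180.0
    active = f["stim_active"].to_numpy(dtype=bool)
    resp = pd.Series(np.where(active, 1.0 - f["h_latent"], np.nan), index=f.index)
    resp_term = resp.rolling(win, min_periods=1).mean().fillna(0.0)
    return pd.DataFrame({"t": f["t"], "score": 0.5 * err_term + 0.5 * resp_term})


def ecd_minutes(tel: TrialTelemetry, window_s: float = 300.0,
                threshold: float = 0.5) -> float:
    """Minutes until the rolling performance score first falls below the
    threshold; returns the trial duration if it never does."""
    ps = performance_score(tel, window_s)
    dt = tel.meta.get("dt", 0.1)
    settle = int(round(window_s / dt))  # ignore the warm-up partial window
    below = ps.iloc[settle:].loc[ps["score"] < threshold]
    if len(below):
        return float(below["t"].iloc[0]) / 60.0
    return float(ps["t"].iloc[-1] + dt) / 60.0


# -- paired comparison -------------------------------------------------------


def paired_win_fraction(a: np.ndarray, b: np.ndarray) -> float:
    """Fraction of pairs where a > b, ties counted as half a win."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.mean(np.where(a > b, 1.0, np.where(a == b, 0.5, 0.0))))


def compare_controllers(
    factories: dict,
    n_seeds: int,
    arena: Arena,
    nominal: SpecimenProfile,
    duration: float = 480.0,
    dt: float = 0.1,
    variability: float = 0.45,
    waypoints: bool = True,
    target_timeout: float = 60.0,
    window_s: float = 60.0,
    base_seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Paired multi-seed study: every controller sees the same specimens and
    the same plant noise seeds. Returns the per-trial table and per-metric
    paired win fractions of the first controller over each other one.
    """
    if n_seeds < 2:
        raise ValueError("need at least 2 seeds for a paired comparison")
    names = list(factories)
    rows = []
    for s in range(n_seeds):
        seed = base_seed + s
        spec_rng = np.random.default_rng(10_000 + seed)
        profile = plant_mod.sample_specimen(spec_rng, nominal, variability)
        for name in names:
            ctrl = factories[name]()
            tel = run_trial(ctrl, profile, arena, duration, seed=seed, dt=dt,
                            waypoints=waypoints, target_timeout=target_timeout)
            nav = navigation_metrics(tel)
            rows.append({
                "controller": name, "seed": seed,
                "ecd_min": ecd_minutes(tel, window_s=window_s),
                **nav,
            })
    table = pd.DataFrame(rows)
    wins = {}
    ref = names[0]
    for other in names[1:]:
        a = table[table.controller == ref].sort_values("seed")
        b = table[table.controller == other].sort_values("seed")
        wins[f"{ref}_vs_{other}"] = {
            "ecd": paired_win_fraction(a["ecd_min"].to_numpy(), b["ecd_min"].to_numpy()),
            "completion": paired_win_fraction(
                a["completion_rate_pct"].to_numpy(), b["completion_rate_pct"].to_numpy()
            ),
        }
    return table, wins
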