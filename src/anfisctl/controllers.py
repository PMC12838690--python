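"""Assembled stimulation controllers.

`AdaptiveController` wires the 8-input / 3-output Sugeno rule base to a
noise-free habituation observer, chirp + inter-burst-interval scheduling,
per-rule local RLS adaptation, and online rule grow/prune. The fixed
baselines (`PIDFuzzyController`, `NaturalController`) implement the
comparison arms: a frozen PID + static fuzzy lookup, and no stimulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import habituation as hab
from ._defaults import INPUT_TABLE
from .anfis import ANFISModel, InputSpec, NoActiveRuleError, Rule, gaussian_mf
from .plant import SENSOR_NAMES
from .scheduler import (ChirpParams, IBIParams, SafeRanges, StimulationCommand,
                        clip_command, inter_burst_interval)


class ConfigError(ValueError):
    """Raised with a list of offending configuration fields."""


def default_input_specs() -> list[InputSpec]:
    """The 8 controller inputs with their published initial partitions."""
    specs = []
    for name, lo, hi, wrap, mfs in INPUT_TABLE:
        specs.append(InputSpec(
            name=name, lo=lo, hi=hi, wrap=wrap,
            mfs=[gaussian_mf(c, w) for _, c, w in mfs],
        ))
    return specs


@dataclass
class ControllerConfig:
    """Everything needed to assemble the adaptive controller."""

    min_rules: int = 80
    max_rules: int = 150
    n_rules_init: int = 105
    eps_fire: float = 0.1
    utility_discount: float = 0.99
    deviation_threshold: float = 10.0  # deg; no stimulation below this
    dt: float = 0.1  # control period, s
    lam: float = 0.995
    p0: float = 1e3
    online_learning: bool = True
    consequent_init: str = "linearize"  # or "zero"
    seed_batch: int = 1500
    # grow a rule when the best-matching rule's geometric-mean membership
    # (raw firing ^ 1/n_inputs) falls below this coverage level
    coverage_threshold: float = 0.5
    safe: SafeRanges = field(default_factory=SafeRanges)
    chirp: ChirpParams = field(default_factory=ChirpParams)
    ibi: IBIParams = field(default_factory=IBIParams)
    observer_hab: hab.HabituationParams = field(
        default_factory=lambda: hab.HabituationParams().noise_free()
    )
    # controller-side prior of the plant response (for adaptation targets)
    nominal_threshold: float = 1.2
    nominal_gain: float = 60.0
    nominal_sat: float = 1.0
    nominal_omega_max: float = 120.0
    amp_ref: float = 3.5
    novelty_relief: float = 0.7

    def validate(self) -> None:
        bad = []
        if self.min_rules < 1:
            bad.append("min_rules")
        if self.max_rules < self.min_rules:
            bad.append("max_rules")
        if not (self.min_rules <= self.n_rules_init <= self.max_rules):
            bad.append("n_rules_init")
        if not (0.0 < self.eps_fire < 1.0):
            bad.append("eps_fire")
        if not (0.0 < self.utility_discount < 1.0):
            bad.append("utility_discount")
        if self.deviation_threshold < 0:
            bad.append("deviation_threshold")
        if not (0.0 < self.lam <= 1.0):
            bad.append("lam")
        if self.dt <= 0:
            bad.append("dt")
        if self.safe.amplitude[0] < 0 or self.safe.frequency[0] < 10.0 - 1e-9 \
                or self.safe.frequency[1] > 200.0 + 1e-9:
            bad.append("safe")
        if self.consequent_init not in ("linearize", "zero"):
            bad.append("consequent_init")
        if bad:
            raise ConfigError(f"invalid controller config fields: {', '.join(bad)}")


def teacher_policy(cfg: ControllerConfig, sensors: dict, h: float,
                   gain_correction: float = 1.0) -> np.ndarray:
    """Habituation-compensating expert targets (amplitude, frequency, duration).

    The amplitude inverts the nominal response model: it requests the turn
    rate a proportional law demands, accounting for the habituation
    attenuation (1 - H), the specimen-gain correction (estimated online from
    realized responses), and the saturating nonlinearity. Frequency sweeps
    upward within the responsive band as habituation grows; duration grows
    with error magnitude. This seeds the rule consequents and serves as the
    online adaptation target.
    """
    err = abs(sensors["err_bear"])
    omega_des = min(1.2 * err, 0.8 * cfg.nominal_omega_max)  # deg/s
    gain_est = cfg.nominal_gain * gain_correction
    # cap the compensation: beyond ~80% attenuation amplitude cannot help
    attenuation = max(1.0 - h, 0.2)
    ratio = min(omega_des / (gain_est * attenuation), 0.95)
    amp = cfg.nominal_threshold + cfg.nominal_sat * math.atanh(ratio)
    freq = 30.0 + 30.0 * h
    dur = 300.0 + 150.0 * math.tanh(err / 60.0)
    return np.array([
        float(np.clip(amp, *cfg.safe.amplitude)),
        float(np.clip(freq, *cfg.safe.frequency)),
        float(np.clip(dur, *cfg.safe.duration_ms)),
    ])


def sensors_to_vector(sensors: dict) -> np.ndarray:
    return np.array([sensors[k] for k in SENSOR_NAMES], dtype=float)


def _sample_seed_states(rng: np.random.Generator, n: int) -> np.ndarray:
    """Plausible navigation states, matched to what closed-loop trials visit:
    arena-scale proximities, walking-gait speeds, small angular rates."""
    cols = {
        "prox_f": rng.uniform(0.4, 1.0, n),
        "prox_b": rng.uniform(0.4, 1.0, n),
        "vel_lin": np.clip(rng.normal(0.5, 0.15, n), 0.0, 1.0),
        "vel_ang": np.clip(rng.normal(0.0, 0.25, n), -1.0, 1.0),
        "dist_targ": rng.uniform(0.0, 0.6, n),
        "err_bear": rng.uniform(-180.0, 180.0, n),
        "accel_ang": np.clip(rng.normal(0.0, 0.2, n), -1.0, 1.0),
        "hab_lvl": rng.uniform(0.0, 0.9, n),
    }
    return np.column_stack([cols[k] for k in SENSOR_NAMES])


def grow_prune_rules(model: ANFISModel, x: np.ndarray, utilities: np.ndarray,
                     cfg: ControllerConfig) -> np.ndarray:
    """Add a rule matched to ``x``; prune the least useful rule at the cap.

    The new antecedent selects, per input, the MF with the highest degree at
    ``x``; its consequent linearizes the current aggregate output (or is a
    safe-midpoint constant when no rule is active). Returns the updated
    utility vector. At least one rule always remains.
    """
    memb = model.memberships(x)
    antecedent = tuple(int(np.argmax(d)) for d in memb)
    if any(tuple(r.antecedent) == antecedent for r in model.rules):
        return utilities  # matched rule already exists; nothing to create
    xp = model.prepare_inputs(x)
    consequent = np.zeros((model.n_outputs, model.n_inputs + 1))
    try:
        y0, _ = model.forward(x)
        if cfg.consequent_init == "linearize":
            grad = np.zeros((model.n_outputs, model.n_inputs))
            for j in range(model.n_inputs):
                hstep = 1e-4 * max(1.0, abs(xp[j]))
                xpj = xp.copy()
                xpj[j] += hstep
                try:
                    yj, _ = model.forward(xpj)
                    grad[:, j] = (yj - y0) / hstep
                except NoActiveRuleError:
                    pass
            consequent[:, 0] = y0 - grad @ xp
            consequent[:, 1:] = grad
        else:
            consequent[:, 0] = y0
    except NoActiveRuleError:
        mid = [sum(cfg.safe.amplitude) / 2, sum(cfg.safe.frequency) / 2,
               sum(cfg.safe.duration_ms) / 2]
        consequent[:, 0] = mid[: model.n_outputs]
    model.rules.append(Rule(antecedent, consequent))
    utilities = np.append(utilities, np.median(utilities) if utilities.size else 1.0)
    while model.n_rules > cfg.max_rules and model.n_rules > 1:
        worst = int(np.argmin(utilities))
        del model.rules[worst]
        utilities = np.delete(utilities, worst)
    model.mark_dirty()
    return utilities


def build_model(cfg: ControllerConfig, rng: np.random.Generator,
                n_outputs: int = 3) -> ANFISModel:
    """Seed the rule base by clustering a batch of sampled states and fit the
    consequents to the expert policy by ridge regression."""
    specs = default_input_specs()
    states = _sample_seed_states(rng, cfg.seed_batch)
    # cluster step: each state votes for its best-matching antecedent combo
    probe = ANFISModel(specs, [Rule(tuple([0] * len(specs)),
                                    np.zeros((n_outputs, len(specs) + 1)))], n_outputs)
    seen: dict[tuple, None] = {}
    for row in states:
        memb = probe.memberships(row)
        ant = tuple(int(np.argmax(d)) for d in memb)
        if ant not in seen:
            seen[ant] = None
        if len(seen) >= cfg.n_rules_init:
            break
    rules = [Rule(ant, np.zeros((n_outputs, len(specs) + 1))) for ant in seen]
    model = ANFISModel(specs, rules, n_outputs)

    # consequent seeding: per-rule locally weighted least squares against the
    # expert policy, so each rule carries the local affine approximation of
    # the teacher where it dominates
    rows_x, rows_w, rows_y = [], [], []
    h_col = SENSOR_NAMES.index("hab_lvl")
    for row in states:
        w = model.firing_strengths(row)
        total = w.sum()
        if total == 0:
            continue
        sensors = dict(zip(SENSOR_NAMES, row))
        rows_x.append(np.concatenate(([1.0], model.prepare_inputs(row))))
        rows_w.append(w / total)
        rows_y.append(teacher_policy(cfg, sensors, h=row[h_col]))
    A = np.array(rows_x)  # (n, n_inputs + 1)
    W = np.array(rows_w)  # (n, n_rules)
    Yt = np.array(rows_y)  # (n, n_outputs)
    eye = 1e-6 * np.eye(A.shape[1])
    for i, rule in enumerate(model.rules):
        wi = W[:, i]
        Aw = A * wi[:, None]
        M = Aw.T @ A + eye
        for ch in range(n_outputs):
            rule.consequent[ch] = np.linalg.solve(M, Aw.T @ Yt[:, ch])
    model.mark_dirty()
    return model


class AdaptiveController:
    """The full dual-timescale adaptive stimulation controller."""

    name = "anfis"

    def __init__(self, cfg: ControllerConfig, model: ANFISModel):
        cfg.validate()
        self.cfg = cfg
        self.model = model
        self.utilities = np.ones(model.n_rules)
        n = model.n_inputs + 1
        self._p_local = [cfg.p0 * np.eye(n) for _ in range(model.n_rules)]
        self.observer = hab.HabituationState()
        self._obs_params = replace(cfg.observer_hab, dt=cfg.dt) \
            if cfg.observer_hab.dt != cfg.dt else cfg.observer_hab
        from types import SimpleNamespace
        self._novelty_model = SimpleNamespace(
            amp_ref=cfg.amp_ref, novelty_relief=cfg.novelty_relief,
        )
        self.last_command: Optional[StimulationCommand] = None
        self._stim_until = -math.inf
        self._burst_start = -math.inf
        self._burst_h = 0.0
        self._next_allowed = -math.inf
        self.gain_correction = 1.0
        self._ema_ratio = 1.0
        self._peak_resp = 0.0
        self.events: list[tuple[float, str]] = []

    # -- observer -----------------------------------------------------------

    def observer_level(self) -> float:
        return hab.combined_level(self.observer)

    def _advance_observer(self, t: float, v_lin: float) -> None:
        """Replay the issued stimulus through the same noise-free drift and
        stimulus-specificity rule the plant model uses."""
        from .plant import stimulus_drive

        s = 0.0
        cmd = self.active_command(t)
        if cmd is not None:
            s = stimulus_drive(cmd.amplitude, self._novelty_model,
                               mod_depth=cmd.mod_depth)
        self.observer = hab.step(self.observer, s, v_lin, self._obs_params)

    def active_amplitude(self, t: float) -> float:
        """Chirp-modulated amplitude delivered at time ``t`` of the current
        burst (constant-H closed form over the burst)."""
        if self.last_command is None or not (self._burst_start <= t < self._stim_until):
            return 0.0
        tau = t - self._burst_start
        ch = self.cfg.chirp
        phi = 2.0 * math.pi * (ch.f_start * tau + 0.5 * ch.k_f * self._burst_h * tau**2)
        return self.last_command.amplitude * (1.0 + ch.a1 * self._burst_h * math.sin(phi))

    def active_command(self, t: float) -> Optional[StimulationCommand]:
        """The burst being delivered at ``t`` (None outside a burst)."""
        if self.last_command is None or not (self._burst_start <= t < self._stim_until):
            return None
        return self.last_command

    # -- adaptation ---------------------------------------------------------

    def _update_gain_estimate(self, sensors: dict) -> None:
        """Track realized vs expected turn response to calibrate amplitude."""
        cfg = self.cfg
        if self.last_command is None:
            return
        if abs(sensors["vel_ang"]) > self._peak_resp:
            self._peak_resp = abs(sensors["vel_ang"])
        # at burst end, fold the peak into the gain-correction EMA
        if self._peak_resp > 0 and sensors["hab_lvl"] < 0.95:
            u = max(0.0, self.last_command.amplitude - cfg.nominal_threshold)
            expected = cfg.nominal_gain * math.tanh(u / cfg.nominal_sat) \
                * (1.0 - sensors["hab_lvl"]) / cfg.nominal_omega_max
            if expected > 1e-3:
                ratio = min(self._peak_resp / expected, 4.0)
                self._ema_ratio = 0.9 * self._ema_ratio + 0.1 * ratio
                # ratio of realized to nominal response scales the gain model
                self.gain_correction = float(np.clip(self._ema_ratio, 0.33, 3.0))

    def _local_rls(self, wbar: np.ndarray, x: np.ndarray, y_target: np.ndarray) -> None:
        """Weighted per-rule RLS on the affine consequents (fast timescale)."""
        lam = self.cfg.lam
        xa = np.concatenate(([1.0], x))
        idx = np.nonzero(wbar > 1e-3)[0]
        for i in idx:
            w = wbar[i]
            P = self._p_local[i]
            Pa = P @ xa
            denom = lam / w + xa @ Pa
            K = Pa / denom
            rule = self.model.rules[i]
            rule.consequent += np.outer(y_target - rule.consequent @ xa, K)
            lam_eff = 1.0 - w * (1.0 - lam)
            P = (P - np.outer(K, Pa)) / lam_eff
            self._p_local[i] = 0.5 * (P + P.T)
        self.model.mark_dirty()

    def _grow(self, x: np.ndarray, t: float, reason: str) -> None:
        self.utilities = grow_prune_rules(self.model, x, self.utilities, self.cfg)
        # realign local covariances with the mutated rule list
        n = self.model.n_inputs + 1
        while len(self._p_local) < self.model.n_rules:
            self._p_local.append(self.cfg.p0 * np.eye(n))
        self._p_local = self._p_local[: self.model.n_rules]
        self.events.append((t, reason))

    # -- main entry ---------------------------------------------------------

    def step(self, sensors: dict, t: float) -> Optional[StimulationCommand]:
        """One control step; returns a command or None (no stimulation)."""
        cfg = self.cfg
        self._advance_observer(t, sensors["vel_lin"])
        h = self.observer_level()
        sensors = dict(sensors, hab_lvl=h)
        x = sensors_to_vector(sensors)

        try:
            y, trace = self.model.forward(x)
            coverage = trace.firing.max() ** (1.0 / self.model.n_inputs)
            if trace.normalized.max() < cfg.eps_fire or coverage < cfg.coverage_threshold:
                self._grow(x, t, "low_firing")
                y, trace = self.model.forward(x)
        except NoActiveRuleError:
            self._grow(x, t, "no_active_rule")
            try:
                y, trace = self.model.forward(x)
            except NoActiveRuleError:
                return None

        self.utilities = cfg.utility_discount * self.utilities
        self.utilities[: trace.normalized.size] += trace.normalized

        self._update_gain_estimate(sensors)
        if cfg.online_learning:
            target = teacher_policy(cfg, sensors, h, self.gain_correction)
            self._local_rls(trace.normalized, self.model.prepare_inputs(x), target)
            y, trace = self.model.forward(x)

        if abs(sensors["err_bear"]) < cfg.deviation_threshold:
            return None
        if t < self._next_allowed:
            return None

        # rest as long as habituation warrants, but shorten the rest when the
        # bearing error is large: recovery must not cost the navigation task
        ibi = inter_burst_interval(h, cfg.ibi) \
            * (0.6 + 0.4 * math.exp(-abs(sensors["err_bear"]) / 60.0))
        cmd = StimulationCommand(
            amplitude=float(y[0]), frequency=float(y[1]),
            duration_ms=float(y[2]) if y.size > 2 else 200.0,
            ibi=max(ibi, cfg.ibi.ibi_min),
            side="left" if sensors["err_bear"] > 0 else "right",
            mod_depth=float(cfg.chirp.depth(h)),
        )
        cmd, clipped = clip_command(cmd, cfg.safe)
        if clipped:
            self.events.append((t, "clipped"))
        self.last_command = cmd
        self._burst_start = t
        self._burst_h = h
        self._stim_until = t + cmd.duration_ms / 1000.0
        self._next_allowed = self._stim_until + cmd.ibi
        self._peak_resp = 0.0
        return cmd


def build_controller(cfg: ControllerConfig | None = None,
                     rng: np.random.Generator | None = None) -> AdaptiveController:
    """Assemble the adaptive controller from a config (defaults if None)."""
    cfg = cfg or ControllerConfig()
    cfg.validate()
    rng = rng or np.random.default_rng(0)
    return AdaptiveController(cfg, build_model(cfg, rng))


def control_step(controller: AdaptiveController, sensors: dict, t: float):
    """Functional alias for :meth:`AdaptiveController.step`."""
    return controller.step(sensors, t)


# -- baselines ---------------------------------------------------------------


@dataclass
class PIDGains:
    kp: float = 0.8
    ki: float = 0.05
    kd: float = 0.2
    integral_clamp: float = 1.0


class PIDFuzzyController:
    """Frozen PID on bearing error + static fuzzy lookup for the stimulus.

    No learning, no habituation compensation, fixed inter-burst interval:
    the conventional fixed-parameter comparison arm.
    """

    name = "pid_fuzzy"

    # (|demand| bin x frontal-proximity bin) -> (amplitude, frequency, duration)
    LOOKUP = {
        (0, 0): (2.8, 50.0, 200.0), (0, 1): (2.8, 50.0, 160.0),
        (1, 0): (3.2, 50.0, 300.0), (1, 1): (3.2, 50.0, 240.0),
        (2, 0): (3.5, 50.0, 400.0), (2, 1): (3.5, 50.0, 320.0),
    }

    def __init__(self, gains: PIDGains | None = None, dt: float = 0.1,
                 deviation_threshold: float = 10.0, fixed_ibi: float = 2.0,
                 safe: SafeRanges | None = None):
        self.gains = gains or PIDGains()
        self.dt = dt
        self.deviation_threshold = deviation_threshold
        self.fixed_ibi = fixed_ibi
        self.safe = safe or SafeRanges()
        self.integral = 0.0
        self.prev_err = 0.0
        self.last_command: Optional[StimulationCommand] = None
        self._stim_until = -math.inf
        self._next_allowed = -math.inf

    def active_command(self, t: float) -> Optional[StimulationCommand]:
        if self.last_command is None or t >= self._stim_until:
            return None
        return self.last_command

    def step(self, sensors: dict, t: float) -> Optional[StimulationCommand]:
        g = self.gains
        e = sensors["err_bear"] / 180.0
        self.integral = float(np.clip(self.integral + e * self.dt,
                                      -g.integral_clamp, g.integral_clamp))
        deriv = (e - self.prev_err) / self.dt
        self.prev_err = e
        demand = g.kp * e + g.ki * self.integral + g.kd * deriv
        if abs(sensors["err_bear"]) < self.deviation_threshold:
            return None
        if t < self._next_allowed:
            return None
        mag = abs(demand)
        mag_bin = 0 if mag < 1.0 / 3.0 else (1 if mag < 2.0 / 3.0 else 2)
        prox_bin = 1 if sensors["prox_f"] >= 0.5 else 0
        amp, frq, dur = self.LOOKUP[(mag_bin, prox_bin)]
        cmd = StimulationCommand(amp, frq, dur, self.fixed_ibi,
                                 side="left" if demand > 0 else "right")
        cmd, _ = clip_command(cmd, self.safe)
        self.last_command = cmd
        self._stim_until = t + cmd.duration_ms / 1000.0
        self._next_allowed = self._stim_until + self.fixed_ibi
        return cmd


def pid_fuzzy_step(controller: PIDFuzzyController, sensors: dict, t: float):
    """Functional alias for :meth:`PIDFuzzyController.step`."""
    return controller.step(sensors, t)


class NaturalController:
    """No stimulation ever: the natural-behavior arm."""

    name = "natural"

    def step(self, sensors: dict, t: float) -> None:
        return None

    def active_command(self, t: float) -> None:
        return None
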