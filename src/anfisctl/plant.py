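"""Virtual-insect plant.

A sampled specimen turns in response to supra-threshold stimulation through
a Wiener cascade (first-order low-pass drive filter followed by a static
tanh saturation), attenuated by its latent habituation state. Natural
locomotion is an Ornstein-Uhlenbeck walk. Geometry is planar: positions in
cm, headings in degrees, counter-clockwise positive, wrapped to (-180, 180].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import habituation as hab
from .scheduler import StimulationCommand


def wrap_angle(deg: float) -> float:
    """Wrap an angle in degrees to (-180, 180]."""
    a = (deg + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


@dataclass(frozen=True)
class WalkParams:
    """Ornstein-Uhlenbeck natural-walk parameters (calibration knobs)."""

    speed_mean: float = 0.5  # normalized [0, 1]
    speed_sd: float = 0.1
    speed_tau: float = 2.0  # s
    turn_sd: float = 8.0  # deg/s
    turn_tau: float = 1.0  # s


@dataclass(frozen=True)
class SpecimenProfile:
    """One virtual insect.

    ``threshold`` (V) gates the stimulus; ``gain`` (deg/s) scales the
    saturated response; ``tau_c`` (s) is the cascade filter time constant;
    ``sat_scale`` (V) sets where the tanh saturates.
    """

    threshold: float = 1.2
    gain: float = 60.0
    tau_c: float = 0.3
    sat_scale: float = 1.0
    amp_ref: float = 3.5  # amplitude normalizer for the habituation drive
    # habituation is stimulus-specific: a temporally varied (amplitude-
    # modulated) burst habituates less than a flat repetitive one
    novelty_relief: float = 0.7  # drive reduction at full modulation depth
    v_max: float = 10.0  # cm/s at v_lin == 1
    omega_max: float = 120.0  # deg/s at v_ang == 1
    turn_slowdown: float = 0.7  # forward-speed reduction during hard turns
    hab: hab.HabituationParams = field(default_factory=hab.HabituationParams)
    walk: WalkParams = field(default_factory=WalkParams)
    seed: int = 0


def sample_specimen(
    rng: np.random.Generator,
    nominal: SpecimenProfile,
    variability: float = 0.45,
) -> SpecimenProfile:
    """Draw a specimen around the nominal profile.

    Threshold and gain are log-normal with coefficient of variation equal to
    ``variability`` and mean equal to the nominal value; ``variability=0``
    returns the nominal profile unchanged. Deterministic given the rng state.
    """
    if variability < 0:
        raise ValueError("variability must be non-negative")
    if variability == 0:
        return nominal
    sigma = math.sqrt(math.log(1.0 + variability**2))
    draws = rng.standard_normal(2)

    def lognorm(nom: float, z: float) -> float:
        return nom * math.exp(sigma * z - 0.5 * sigma**2)

    return replace(
        nominal,
        threshold=lognorm(nominal.threshold, draws[0]),
        gain=lognorm(nominal.gain, draws[1]),
    )


@dataclass(frozen=True)
class Arena:
    """Rectangular arena with optional axis-aligned box / circle obstacles.

    Obstacles: ("rect", x0, y0, x1, y1) or ("circle", cx, cy, r). The target
    must lie inside the bounds and outside every obstacle.
    """

    width: float = 170.0
    height: float = 170.0
    obstacles: tuple = ()
    target: tuple[float, float] = (150.0, 150.0)
    completion_radius: float = 15.0

    def __post_init__(self) -> None:
        tx, ty = self.target
        if not (0 <= tx <= self.width and 0 <= ty <= self.height):
            raise ValueError("target outside arena bounds")
        if self.point_in_obstacle(tx, ty):
            raise ValueError("target inside an obstacle")

    @property
    def diagonal(self) -> float:
        return math.hypot(self.width, self.height)

    def point_in_obstacle(self, x: float, y: float) -> bool:
        for ob in self.obstacles:
            if ob[0] == "rect":
                _, x0, y0, x1, y1 = ob
                if x0 <= x <= x1 and y0 <= y <= y1:
                    return True
            elif ob[0] == "circle":
                _, cx, cy, r = ob
                if math.hypot(x - cx, y - cy) <= r:
                    return True
        return False

    def contains(self, x: float, y: float) -> bool:
        return 0 <= x <= self.width and 0 <= y <= self.height


def _ray_rect(x, y, dx, dy, x0, y0, x1, y1) -> float | None:
    """Slab intersection of a ray with an axis-aligned box; nearest t >= 0."""
    tmin, tmax = -math.inf, math.inf
    for p, d, lo, hi in ((x, dx, x0, x1), (y, dy, y0, y1)):
        if abs(d) < 1e-12:
            if not (lo <= p <= hi):
                return None
        else:
            t1, t2 = (lo - p) / d, (hi - p) / d
            if t1 > t2:
                t1, t2 = t2, t1
            tmin, tmax = max(tmin, t1), min(tmax, t2)
    if tmax < max(tmin, 0.0):
        return None
    return tmin if tmin > 0 else tmax


def raycast(arena: Arena, x: float, y: float, heading_deg: float, max_range: float = 400.0) -> float:
    """Distance (cm) to the nearest wall/obstacle along a heading, capped."""
    th = math.radians(heading_deg)
    dx, dy = math.cos(th), math.sin(th)
    best = math.inf
    # outer walls: ray leaves through whichever boundary comes first
    for wall_t in (
        (arena.width - x) / dx if dx > 0 else (0 - x) / dx if dx < 0 else math.inf,
        (arena.height - y) / dy if dy > 0 else (0 - y) / dy if dy < 0 else math.inf,
    ):
        if 0 <= wall_t < best:
            best = wall_t
    for ob in arena.obstacles:
        if ob[0] == "rect":
            t = _ray_rect(x, y, dx, dy, *ob[1:])
            if t is not None and 0 <= t < best:
                best = t
        elif ob[0] == "circle":
            _, cx, cy, r = ob
            fx, fy = x - cx, y - cy
            b = fx * dx + fy * dy
            disc = b * b - (fx * fx + fy * fy - r * r)
            if disc >= 0:
                t = -b - math.sqrt(disc)
                if t >= 0 and t < best:
                    best = t
    return min(best, max_range)


@dataclass
class PlantState:
    x: float = 20.0
    y: float = 20.0
    heading: float = 0.0  # deg, (-180, 180]
    v_lin: float = 0.5  # normalized [0, 1]
    v_ang: float = 0.0  # normalized [-1, 1]
    prev_v_ang: float = 0.0
    drive: float = 0.0  # cascade low-pass internal state (V above threshold)
    walk_speed: float = 0.5
    walk_turn: float = 0.0  # deg/s
    habituation: hab.HabituationState = field(default_factory=hab.HabituationState)


def stimulus_drive(amplitude: float, profile: SpecimenProfile,
                   mod_depth: float = 0.0) -> float:
    """Habituation drive of one delivered stimulus step.

    ``S = (amp / amp_ref) * (1 - relief * mod_depth)``: habituation is
    stimulus-specific, so a flat repetitive train habituates at the full
    rate while a temporally varied burst (``mod_depth`` = chirp modulation
    depth A(H)) reads as a changing stimulus and habituates less.
    """
    return min(1.0, amplitude / profile.amp_ref) \
        * (1.0 - profile.novelty_relief * min(max(mod_depth, 0.0), 1.0))


def plant_step(
    state: PlantState,
    command: StimulationCommand | None,
    profile: SpecimenProfile,
    dt: float,
    rng: np.random.Generator | None = None,
    noise: bool = True,
    arena: Arena | None = None,
) -> PlantState:
    """Advance the plant by one step of ``dt`` seconds.

    ``command`` is the stimulation burst currently being delivered (or
    None). The commanded turn rate is
    ``gain * tanh(lowpass(max(0, amp - threshold)) / sat) * (1 - H)`` with
    the sign set by the stimulated side (left = CCW = positive).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    active = command is not None and command.side != "none"
    u = max(0.0, command.amplitude - profile.threshold) if active else 0.0
    drive = state.drive + (dt / profile.tau_c) * (u - state.drive)
    nl = math.tanh(drive / profile.sat_scale)
    h_level = hab.combined_level(state.habituation)
    side_sign = 0.0
    if active:
        side_sign = 1.0 if command.side == "left" else -1.0
    turn_cmd = profile.gain * nl * (1.0 - h_level) * side_sign  # deg/s

    # latent habituation advances with the delivered stimulus and current gait
    s_drive = stimulus_drive(command.amplitude, profile,
                             mod_depth=command.mod_depth) if active else 0.0
    hparams = replace(profile.hab, dt=dt) if profile.hab.dt != dt else profile.hab
    hab_state = hab.step(state.habituation, s_drive, state.v_lin, hparams, rng)

    # natural walk (OU processes on speed and heading jitter)
    walk_speed, walk_turn = state.walk_speed, state.walk_turn
    if noise:
        if rng is None:
            raise ValueError("rng required when natural-walk noise is enabled")
        wp = profile.walk
        walk_speed += (dt / wp.speed_tau) * (wp.speed_mean - walk_speed) + \
            wp.speed_sd * math.sqrt(2.0 * dt / wp.speed_tau) * rng.standard_normal()
        walk_turn += -(dt / wp.turn_tau) * walk_turn + \
            wp.turn_sd * math.sqrt(2.0 * dt / wp.turn_tau) * rng.standard_normal()
    v_lin = float(np.clip(walk_speed, 0.0, 1.0)) if noise else state.v_lin
    omega = turn_cmd + (walk_turn if noise else 0.0)  # deg/s

    heading = wrap_angle(state.heading + omega * dt)
    # commanded turning slows forward progress (pivot-like maneuvers)
    slow = 1.0 - profile.turn_slowdown * min(1.0, abs(turn_cmd) / 90.0)
    speed = v_lin * profile.v_max * slow
    nx = state.x + speed * math.cos(math.radians(heading)) * dt
    ny = state.y + speed * math.sin(math.radians(heading)) * dt
    if arena is not None:
        nx = float(np.clip(nx, 0.0, arena.width))
        ny = float(np.clip(ny, 0.0, arena.height))
        if arena.point_in_obstacle(nx, ny):
            nx, ny = state.x, state.y  # blocked; stay put
    return PlantState(
        x=nx, y=ny, heading=heading,
        v_lin=v_lin,
        v_ang=float(np.clip(omega / profile.omega_max, -1.0, 1.0)),
        prev_v_ang=state.v_ang,
        drive=drive,
        walk_speed=walk_speed, walk_turn=walk_turn,
        habituation=hab_state,
    )


SENSOR_NAMES = (
    "prox_f", "prox_b", "vel_lin", "vel_ang",
    "dist_targ", "err_bear", "accel_ang", "hab_lvl",
)

_PROX_RANGE = 400.0  # cm, ToF-like maximum range
_ACCEL_REF = 10.0  # 1/s, normalizer for the angular-acceleration channel


def sense(
    state: PlantState,
    arena: Arena,
    hab_lvl: float = 0.0,
    dt: float = 0.1,
    rng: np.random.Generator | None = None,
    prox_noise: float = 0.0,
) -> dict[str, float]:
    """Produce the 8-channel sensor state.

    Proximities are 1 - distance/range (1 = touching, 0 = clear at max
    range). Bearing error is positive when the target lies to the left.
    ``hab_lvl`` is supplied by the caller (the controller's observer), not
    read from the plant's latent state.
    """
    if not arena.contains(state.x, state.y):
        raise ValueError("plant state outside arena bounds")
    d_f = raycast(arena, state.x, state.y, state.heading, _PROX_RANGE)
    d_b = raycast(arena, state.x, state.y, wrap_angle(state.heading + 180.0), _PROX_RANGE)
    if prox_noise > 0:
        if rng is None:
            raise ValueError("rng required for sensor noise")
        d_f *= 1.0 + prox_noise * rng.standard_normal()
        d_b *= 1.0 + prox_noise * rng.standard_normal()
    tx, ty = arena.target
    dist = math.hypot(tx - state.x, ty - state.y)
    bearing = math.degrees(math.atan2(ty - state.y, tx - state.x))
    err_bear = wrap_angle(bearing - state.heading)
    accel = (state.v_ang - state.prev_v_ang) / (dt * _ACCEL_REF)
    return {
        "prox_f": float(np.clip(1.0 - d_f / _PROX_RANGE, 0.0, 1.0)),
        "prox_b": float(np.clip(1.0 - d_b / _PROX_RANGE, 0.0, 1.0)),
        "vel_lin": state.v_lin,
        "vel_ang": state.v_ang,
        "dist_targ": float(np.clip(dist / arena.diagonal, 0.0, 1.0)),
        "err_bear": err_bear,
        "accel_ang": float(np.clip(accel, -1.0, 1.0)),
        "hab_lvl": float(np.clip(hab_lvl, 0.0, 1.0)),
    }
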