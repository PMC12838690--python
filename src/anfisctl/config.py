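"""YAML configuration: defaults, deep-merge loading, and object builders.

Sections: plant, habituation, controller, scheduler, arena, experiment.
Every value here is overridable from the user file; unknown keys are
rejected so typos fail loudly.
"""

from __future__ import annotations

import copy
from typing import Any

import yaml

from . import habituation as hab
from .controllers import ControllerConfig, PIDFuzzyController, PIDGains
from .plant import Arena, SpecimenProfile, WalkParams
from .scheduler import ChirpParams, IBIParams, SafeRanges


def default_config() -> dict:
    return {
        "plant": {
            "threshold": 1.2, "gain": 60.0, "tau_c": 0.3, "sat_scale": 1.0,
            "amp_ref": 3.5, "v_max": 10.0, "omega_max": 120.0,
            "novelty_relief": 0.7, "turn_slowdown": 0.7, "variability": 0.45,
            "walk": {"speed_mean": 0.5, "speed_sd": 0.1, "speed_tau": 2.0,
                     "turn_sd": 8.0, "turn_tau": 1.0},
        },
        "habituation": {
            "d_s": 0.02, "d_l": 0.0005, "i_l": 0.002, "i_s0": 0.08,
            "k_v": 1.5, "sigma_s": 0.005, "sigma_l": 0.001, "dt": 0.05,
        },
        "controller": {
            "min_rules": 80, "max_rules": 150, "n_rules_init": 105,
            "eps_fire": 0.1, "utility_discount": 0.99,
            "deviation_threshold": 10.0, "dt": 0.1, "lam": 0.995,
            "online_learning": True, "consequent_init": "linearize",
            "safe": {"amplitude": [0.5, 3.5], "frequency": [10.0, 200.0],
                     "duration_ms": [50.0, 500.0]},
            "pid": {"kp": 0.8, "ki": 0.05, "kd": 0.2, "integral_clamp": 1.0,
                    "fixed_ibi": 2.0},
        },
        "scheduler": {
            "chirp": {"f_start": 25.0, "k_f": 5.0, "a1": 0.5},
            "ibi": {"ibi_min": 2.0, "ibi_max": 30.0, "k": 3.0},
        },
        "arena": {
            "width": 170.0, "height": 170.0, "obstacles": [],
            "target": [150.0, 150.0], "completion_radius": 15.0,
        },
        "experiment": {
            "duration": 480.0, "dt": 0.1, "n_seeds": 20,
            "waypoints": True, "target_timeout": 60.0,
            "score_window_s": 60.0,
        },
    }


def _merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise KeyError(f"unknown configuration key: {here}")
        if isinstance(base[key], dict) and isinstance(value, dict):
            out[key] = _merge(base[key], value, here)
        else:
            out[key] = value
    return out


def load_config(path: str | None = None) -> dict:
    """Defaults deep-merged with an optional user YAML file."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, user)
    return cfg


# -- builders ----------------------------------------------------------------


def make_habituation_params(cfg: dict) -> hab.HabituationParams:
    return hab.HabituationParams(**cfg["habituation"])


def make_profile(cfg: dict, seed: int = 0) -> SpecimenProfile:
    p = cfg["plant"]
    return SpecimenProfile(
        threshold=p["threshold"], gain=p["gain"], tau_c=p["tau_c"],
        sat_scale=p["sat_scale"], amp_ref=p["amp_ref"], v_max=p["v_max"],
        omega_max=p["omega_max"],
        novelty_relief=p["novelty_relief"], turn_slowdown=p["turn_slowdown"],
        hab=make_habituation_params(cfg),
        walk=WalkParams(**p["walk"]),
        seed=seed,
    )


def make_arena(cfg: dict) -> Arena:
    a = cfg["arena"]
    return Arena(
        width=a["width"], height=a["height"],
        obstacles=tuple(tuple(ob) for ob in a["obstacles"]),
        target=tuple(a["target"]), completion_radius=a["completion_radius"],
    )


def make_controller_config(cfg: dict) -> ControllerConfig:
    c = cfg["controller"]
    s = cfg["scheduler"]
    safe = SafeRanges(
        amplitude=tuple(c["safe"]["amplitude"]),
        frequency=tuple(c["safe"]["frequency"]),
        duration_ms=tuple(c["safe"]["duration_ms"]),
    )
    return ControllerConfig(
        min_rules=c["min_rules"], max_rules=c["max_rules"],
        n_rules_init=c["n_rules_init"], eps_fire=c["eps_fire"],
        utility_discount=c["utility_discount"],
        deviation_threshold=c["deviation_threshold"], dt=c["dt"],
        lam=c["lam"], online_learning=c["online_learning"],
        consequent_init=c["consequent_init"],
        safe=safe,
        chirp=ChirpParams(**s["chirp"]), ibi=IBIParams(**s["ibi"]),
        observer_hab=make_habituation_params(cfg).noise_free(),
        nominal_threshold=cfg["plant"]["threshold"],
        nominal_gain=cfg["plant"]["gain"],
        nominal_sat=cfg["plant"]["sat_scale"],
        nominal_omega_max=cfg["plant"]["omega_max"],
        amp_ref=cfg["plant"]["amp_ref"],
        novelty_relief=cfg["plant"]["novelty_relief"],
    )


def make_pid_controller(cfg: dict) -> PIDFuzzyController:
    c = cfg["controller"]
    pid = c["pid"]
    return PIDFuzzyController(
        gains=PIDGains(kp=pid["kp"], ki=pid["ki"], kd=pid["kd"],
                       integral_clamp=pid["integral_clamp"]),
        dt=c["dt"], deviation_threshold=c["deviation_threshold"],
        fixed_ibi=pid["fixed_ibi"],
        safe=SafeRanges(
            amplitude=tuple(c["safe"]["amplitude"]),
            frequency=tuple(c["safe"]["frequency"]),
            duration_ms=tuple(c["safe"]["duration_ms"]),
        ),
    )


def desk_scale_overrides() -> dict[str, Any]:
    """Accelerated habituation dynamics for desk-scale benchmark runs.

    Timescales are compressed so that habituation-driven degradation and the
    compensation advantage both manifest within minutes of simulated time.
    """
    return {
        "habituation": {"d_s": 0.02, "d_l": 0.004, "i_l": 0.0012, "i_s0": 0.18,
                        "k_v": 1.0, "sigma_s": 0.01, "sigma_l": 0.002,
                        "dt": 0.1},
        "scheduler": {"ibi": {"ibi_min": 3.0, "ibi_max": 12.0, "k": 2.0},
                      "chirp": {"a1": 1.0}},
        "plant": {"gain": 160.0, "sat_scale": 2.5, "novelty_relief": 0.9,
                  "walk": {"turn_sd": 3.0}},
        "experiment": {"duration": 600.0, "score_window_s": 60.0},
    }
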