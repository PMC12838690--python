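"""Desk-scale benchmark protocols.

These wrap the paired-trial machinery with the accelerated (desk-scale)
habituation dynamics so that habituation-driven degradation, the
compensation advantage, and the rule-cap trade-off all manifest within
minutes of simulated time. All runs are fully determined by their seeds.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import config as cfg_mod
from . import experiments as exp
from .controllers import NaturalController, build_controller
from .plant import sample_specimen


def desk_config(habituation: bool = True) -> dict:
    """Desk-scale configuration; ``habituation=False`` zeroes the plant's
    habituation drive (and, through the shared config, the observer's)."""
    cfg = cfg_mod._merge(cfg_mod.default_config(), cfg_mod.desk_scale_overrides())
    if not habituation:
        cfg = cfg_mod._merge(cfg, {"habituation": {"i_s0": 0.0, "i_l": 0.0,
                                                   "sigma_s": 0.0, "sigma_l": 0.0}})
    return cfg


def paired_study(
    n_seeds: int = 20,
    duration: float = 600.0,
    habituation: bool = True,
    base_seed: int = 0,
    include_natural: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Adaptive controller vs frozen PID-fuzzy baseline on paired seeds."""
    cfg = desk_config(habituation)
    ccfg = cfg_mod.make_controller_config(cfg)
    factories = {
        "anfis": lambda: build_controller(ccfg, np.random.default_rng(base_seed)),
        "pid_fuzzy": lambda: cfg_mod.make_pid_controller(cfg),
    }
    if include_natural:
        factories["natural"] = lambda: NaturalController()
    return exp.compare_controllers(
        factories, n_seeds=n_seeds,
        arena=cfg_mod.make_arena(cfg), nominal=cfg_mod.make_profile(cfg),
        duration=duration, dt=cfg["experiment"]["dt"],
        variability=cfg["plant"]["variability"],
        target_timeout=cfg["experiment"]["target_timeout"],
        window_s=cfg["experiment"]["score_window_s"], base_seed=base_seed,
    )


def rule_cap_ablation(
    caps: tuple[int, ...] = (45, 105, 135),
    n_seeds: int = 20,
    duration: float = 360.0,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Completion rate vs maximum active rule count on paired seeds."""
    cfg = desk_config(True)
    base = cfg_mod.make_controller_config(cfg)
    arena = cfg_mod.make_arena(cfg)
    nominal = cfg_mod.make_profile(cfg)
    rows = []
    for cap in caps:
        ccfg = dataclasses.replace(
            base, max_rules=cap, n_rules_init=min(cap, base.n_rules_init),
            min_rules=min(base.min_rules, cap),
        )
        for s in range(n_seeds):
            seed = base_seed + s
            profile = sample_specimen(np.random.default_rng(10_000 + seed),
                                      nominal, cfg["plant"]["variability"])
            ctrl = build_controller(ccfg, np.random.default_rng(base_seed))
            tel = exp.run_trial(ctrl, profile, arena, duration, seed=seed,
                                dt=cfg["experiment"]["dt"], waypoints=True,
                                target_timeout=cfg["experiment"]["target_timeout"])
            rows.append({
                "cap": cap, "seed": seed,
                "completion_rate_pct": 100.0 * tel.completion_rate,
                "direction_mae_deg": exp.navigation_metrics(tel)["direction_mae_deg"],
            })
    return pd.DataFrame(rows)
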