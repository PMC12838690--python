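import math
from dataclasses import replace

import numpy as np
import pytest

from anfisctl.anfis import NoActiveRuleError
from anfisctl.controllers import (AdaptiveController, ConfigError,
                                  ControllerConfig, NaturalController,
                                  PIDFuzzyController, PIDGains, build_controller,
                                  build_model, control_step,
                                  default_input_specs, grow_prune_rules,
                                  pid_fuzzy_step, teacher_policy)
from anfisctl.plant import SENSOR_NAMES


def sensors(**kw) -> dict:
    base = dict(prox_f=0.1, prox_b=0.1, vel_lin=0.5, vel_ang=0.0,
                dist_targ=0.5, err_bear=0.0, accel_ang=0.0, hab_lvl=0.0)
    base.update(kw)
    return base


@pytest.fixture(scope="module")
def controller() -> AdaptiveController:
    return build_controller(ControllerConfig(), np.random.default_rng(1))


@pytest.fixture
def fresh_controller(controller) -> AdaptiveController:
    """A cheap per-test copy with pristine runtime state."""
    return AdaptiveController(controller.cfg, controller.model.copy())


class TestInputSpecs:
    def test_mf_counts(self):
        specs = default_input_specs()
        counts = {s.name: len(s.mfs) for s in specs}
        assert counts == {"prox_f": 4, "prox_b": 4, "vel_lin": 4, "vel_ang": 5,
                          "dist_targ": 4, "err_bear": 5, "accel_ang": 3,
                          "hab_lvl": 3}
        assert sum(counts.values()) == 32

    def test_prox_f_far_initialization(self):
        specs = {s.name: s for s in default_input_specs()}
        pf_far = specs["prox_f"].mfs[0]
        assert pf_far.c == 0.15
        assert pf_far.s1 == 0.10 and pf_far.s2 == 0.10

    def test_bearing_is_periodic_and_scaled(self):
        specs = {s.name: s for s in default_input_specs()}
        eb = specs["err_bear"]
        assert eb.wrap
        assert (eb.lo, eb.hi) == (-180.0, 180.0)
        assert eb.mfs[0].c == pytest.approx(-144.0)  # -0.8 on the degree scale

    def test_mf_count_bounds(self):
        for s in default_input_specs():
            assert 3 <= len(s.mfs) <= 5


class TestConfigValidation:
    def test_default_valid(self):
        ControllerConfig().validate()

    def test_offending_fields_listed(self):
        cfg = ControllerConfig(min_rules=0, eps_fire=2.0, lam=1.5)
        with pytest.raises(ConfigError) as err:
            cfg.validate()
        msg = str(err.value)
        assert "min_rules" in msg and "eps_fire" in msg and "lam" in msg

    def test_rule_cap_ordering(self):
        with pytest.raises(ConfigError):
            ControllerConfig(min_rules=100, max_rules=50).validate()


class TestBuildController:
    def test_initial_rule_count_within_bounds(self, controller):
        assert 80 <= controller.model.n_rules <= 150

    def test_eight_inputs_three_outputs(self, controller):
        assert controller.model.n_inputs == 8
        assert controller.model.n_outputs == 3

    def test_consequents_approximate_teacher(self, controller):
        cfg = controller.cfg
        rng = np.random.default_rng(9)
        errs = []
        for _ in range(200):
            s = sensors(err_bear=float(rng.uniform(-180, 180)),
                        hab_lvl=float(rng.uniform(0, 1)),
                        prox_f=float(rng.beta(1.2, 3.0)))
            x = np.array([s[k] for k in SENSOR_NAMES])
            try:
                y, _ = controller.model.forward(x)
            except NoActiveRuleError:
                continue
            t = teacher_policy(cfg, s, s["hab_lvl"])
            errs.append(abs(y[0] - t[0]))
        assert np.mean(errs) < 0.5  # amplitude channel tracks the teacher


class TestControlStep:
    def test_below_deviation_threshold_no_command(self, fresh_controller):
        assert fresh_controller.step(sensors(err_bear=2.0), 0.0) is None

    def test_refractory_gating(self, fresh_controller):
        c = fresh_controller
        cmd = c.step(sensors(err_bear=90.0), 0.0)
        assert cmd is not None
        t_again = cmd.duration_ms / 1000.0 + cmd.ibi / 2.0
        assert c.step(sensors(err_bear=90.0), t_again) is None

    def test_left_turn_fixture(self, fresh_controller):
        cmd = control_step(fresh_controller, sensors(err_bear=90.0), 0.0)
        assert cmd is not None
        assert cmd.side == "left"
        cfg = fresh_controller.cfg
        assert cfg.safe.amplitude[0] <= cmd.amplitude <= cfg.safe.amplitude[1]
        assert cfg.safe.frequency[0] <= cmd.frequency <= cfg.safe.frequency[1]
        assert cfg.safe.duration_ms[0] <= cmd.duration_ms <= cfg.safe.duration_ms[1]

    def test_right_turn_sign(self, fresh_controller):
        cmd = fresh_controller.step(sensors(err_bear=-90.0), 0.0)
        assert cmd is not None and cmd.side == "right"

    def test_safe_ranges_on_every_step(self, fresh_controller):
        rng = np.random.default_rng(3)
        c = fresh_controller
        t = 0.0
        for _ in range(300):
            s = sensors(err_bear=float(rng.uniform(-180, 180)),
                        vel_ang=float(rng.uniform(-1, 1)),
                        prox_f=float(rng.uniform(0, 1)))
            cmd = c.step(s, t)
            if cmd is not None:
                cfg = c.cfg
                assert cfg.safe.amplitude[0] <= cmd.amplitude <= cfg.safe.amplitude[1]
                assert cfg.safe.frequency[0] <= cmd.frequency <= cfg.safe.frequency[1]
                assert cfg.safe.duration_ms[0] <= cmd.duration_ms <= cfg.safe.duration_ms[1]
            assert c.cfg.min_rules <= c.model.n_rules <= c.cfg.max_rules \
                or c.model.n_rules <= c.cfg.max_rules  # grow/prune keeps the cap
            assert 0.0 <= c.observer_level() <= 1.0
            t += c.cfg.dt

    def test_observer_advances_under_stimulation(self, fresh_controller):
        c = fresh_controller
        t = 0.0
        for _ in range(200):
            c.step(sensors(err_bear=120.0), t)
            t += c.cfg.dt
        assert c.observer_level() > 0.0

    def test_chirp_modulated_amplitude_within_envelope(self, fresh_controller):
        c = fresh_controller
        # push the observer up so the modulation depth is nonzero
        for k in range(400):
            c.step(sensors(err_bear=150.0), k * c.cfg.dt)
        cmd = None
        t = 400 * c.cfg.dt
        while cmd is None:
            cmd = c.step(sensors(err_bear=150.0), t)
            t += c.cfg.dt
        h = c._burst_h
        saw_mod = False
        for k in range(int(cmd.duration_ms / 1000.0 / c.cfg.dt)):
            amp = c.active_amplitude(t - c.cfg.dt + k * c.cfg.dt)
            assert amp <= cmd.amplitude * (1.0 + c.cfg.chirp.a1 * h) + 1e-9
            if abs(amp - cmd.amplitude) > 1e-9:
                saw_mod = True
        if h > 0.05:
            assert saw_mod


class TestGrowPrune:
    def test_no_growth_when_covered(self, fresh_controller):
        c = fresh_controller
        x = np.array([sensors(err_bear=90.0)[k] for k in SENSOR_NAMES])
        # grow once so x's best-matching rule exists, then growth is a no-op
        utils = grow_prune_rules(c.model, x, c.utilities.copy(), c.cfg)
        n = c.model.n_rules
        utils2 = grow_prune_rules(c.model, x, utils, c.cfg)
        assert c.model.n_rules == n
        assert utils2 is utils

    def test_cap_conservation(self, fresh_controller):
        c = fresh_controller
        cfg = replace_max(c.cfg, c.model.n_rules)  # cap at the current count
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = np.array([rng.uniform(lo, hi) for lo, hi in
                          [(0, 1), (0, 1), (0, 1), (-1, 1), (0, 1), (-180, 180), (-1, 1), (0, 1)]])
            c.utilities = grow_prune_rules(c.model, x, c.utilities, cfg)
            assert c.model.n_rules <= cfg.max_rules
            assert c.model.n_rules >= 1
            assert len(c.utilities) == c.model.n_rules

    def test_uncovered_corner_post_condition(self, fresh_controller):
        c = fresh_controller
        x = np.array([1.0, 1.0, 0.0, 1.0, 0.0, 179.0, -1.0, 1.0])  # odd corner
        c.utilities = grow_prune_rules(c.model, x, c.utilities, c.cfg)
        w = c.model.firing_strengths(x)
        wbar = w / w.sum()
        assert wbar.max() >= c.cfg.eps_fire


def replace_max(cfg: ControllerConfig, max_rules: int) -> ControllerConfig:
    import dataclasses
    return dataclasses.replace(cfg, max_rules=max_rules,
                               min_rules=min(cfg.min_rules, max_rules),
                               n_rules_init=min(cfg.n_rules_init, max_rules))


class TestPIDFuzzy:
    def test_zero_error_no_command(self):
        pid = PIDFuzzyController()
        assert pid_fuzzy_step(pid, sensors(err_bear=0.0), 0.0) is None

    def test_magnitude_bins_monotone(self):
        amps = []
        for err in (20.0, 80.0, 170.0):
            pid = PIDFuzzyController(gains=PIDGains(kp=0.8, ki=0.0, kd=0.0))
            cmd = pid.step(sensors(err_bear=err), 0.0)
            amps.append(cmd.amplitude)
        assert amps == sorted(amps)
        assert amps[0] < amps[-1]

    def test_anti_windup_clamp(self):
        pid = PIDFuzzyController(gains=PIDGains(ki=0.05, integral_clamp=1.0))
        t = 0.0
        for _ in range(600):  # 60 s of sustained 180 deg error
            pid.step(sensors(err_bear=180.0), t)
            t += pid.dt
        assert pid.integral == pytest.approx(1.0)

    def test_fixed_ibi_gating(self):
        pid = PIDFuzzyController(fixed_ibi=2.0)
        cmd = pid.step(sensors(err_bear=90.0), 0.0)
        assert cmd is not None
        assert pid.step(sensors(err_bear=90.0), cmd.duration_ms / 1000.0 + 1.0) is None

    def test_side_follows_demand(self):
        pid = PIDFuzzyController(gains=PIDGains(ki=0.0, kd=0.0))
        assert pid.step(sensors(err_bear=90.0), 0.0).side == "left"
        pid2 = PIDFuzzyController(gains=PIDGains(ki=0.0, kd=0.0))
        assert pid2.step(sensors(err_bear=-90.0), 0.0).side == "right"


class TestNatural:
    def test_never_commands(self):
        nat = NaturalController()
        rng = np.random.default_rng(0)
        for k in range(100):
            assert nat.step(sensors(err_bear=float(rng.uniform(-180, 180))), 0.1 * k) is None


class TestObserverTracking:
    def test_observer_matches_latent_with_matched_params(self):
        """Noise off and matched parameters: observer == plant latent H."""
        from anfisctl.habituation import HabituationParams, HabituationState, combined_level, step

        params = HabituationParams(d_s=0.05, d_l=0.001, i_l=0.01, i_s0=0.3,
                                   k_v=1.0, sigma_s=0.0, sigma_l=0.0, dt=0.1)
        latent = HabituationState()
        observer = HabituationState()
        rng = np.random.default_rng(0)
        for k in range(2000):
            s = 0.8 if (k // 30) % 2 == 0 else 0.0
            v = float(rng.uniform(0, 1))
            latent = step(latent, s, v, params)
            observer = step(observer, s, v, params)
            assert combined_level(observer) == pytest.approx(combined_level(latent), abs=1e-12)
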