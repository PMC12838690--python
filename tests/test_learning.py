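import numpy as np
import pytest

from anfisctl.anfis import ANFISModel, InputSpec, NoActiveRuleError, Rule, gaussian_mf
from anfisctl.learning import (ConsequentEstimator, DualTimescaleHistory,
                               PremiseOptState, RLSState, batch_rmse,
                               build_regressor, dual_timescale_update,
                               init_premise_opt, init_rls, kfold_validate,
                               lma_step, premise_step, rls_update,
                               set_model_theta, theta_from_model, train)
from conftest import random_model


class TestBuildRegressor:
    def test_single_rule_layout(self):
        a = build_regressor(np.array([1.0]), [2.0, 3.0])
        assert a.tolist() == [1.0, 2.0, 3.0]

    def test_two_rule_layout(self):
        a = build_regressor(np.array([0.5, 0.5]), [2.0])
        assert a.tolist() == [0.5, 1.0, 0.5, 1.0]

    def test_matches_forward_output(self, rng):
        for _ in range(100):
            model, _ = random_model(rng, n_inputs=2, n_mfs=2)
            x = rng.uniform(-2, 2, 2)
            y, trace = model.forward(x)
            a = build_regressor(trace.normalized, model.prepare_inputs(x))
            theta = theta_from_model(model, 0)
            assert a @ theta == pytest.approx(y[0], abs=1e-12)


class TestRLSUpdate:
    def test_scalar_hand_example(self):
        st = RLSState(np.zeros(1), np.array([[1000.0]]), lam=1.0)
        st = rls_update(st, np.array([1.0]), 2.0)
        assert st.theta[0] == pytest.approx(1000.0 / 1001.0 * 2.0, rel=1e-12)
        assert st.theta[0] == pytest.approx(1.998002, abs=1e-6)
        assert st.P[0, 0] == pytest.approx(1000.0 / 1001.0, rel=1e-12)
        assert st.P[0, 0] == pytest.approx(0.999001, abs=1e-6)

    def test_zero_regressor_no_information(self):
        st = RLSState(np.array([1.5]), np.array([[10.0]]), lam=0.9)
        st2 = rls_update(st, np.array([0.0]), 7.0)
        assert st2.theta[0] == 1.5
        assert st2.P[0, 0] == pytest.approx(10.0 / 0.9)

    def test_matches_batch_ols(self, rng):
        n = 3
        A = rng.uniform(-1, 1, (50, n))
        theta_true = rng.uniform(-2, 2, n)
        y = A @ theta_true
        st = init_rls(n, lam=1.0, p0=1e6)
        for a, yi in zip(A, y):
            st = rls_update(st, a, yi)
        ols, *_ = np.linalg.lstsq(A, y, rcond=None)
        assert np.linalg.norm(st.theta - ols) / np.linalg.norm(ols) < 1e-6

    def test_non_finite_rejected(self):
        st = init_rls(2)
        with pytest.raises(FloatingPointError):
            rls_update(st, np.array([1.0, np.nan]), 1.0)

    def test_invalid_forgetting(self):
        with pytest.raises(ValueError):
            RLSState(np.zeros(1), np.eye(1), lam=0.0)

    def test_covariance_stays_symmetric(self, rng):
        st = init_rls(4, lam=0.99)
        for _ in range(200):
            st = rls_update(st, rng.uniform(-1, 1, 4), rng.normal())
        assert np.allclose(st.P, st.P.T)

    def test_forgetting_bounded_covariance(self, rng):
        # persistent excitation: random full-support regressors
        st = init_rls(3, lam=0.995, p0=1e3)
        traces = []
        for _ in range(10_000):
            st = rls_update(st, rng.uniform(-1, 1, 3) + 0.1, rng.normal())
            traces.append(np.trace(st.P))
        assert max(traces[1000:]) < 1e4  # no blow-up after burn-in


class TestLMAStep:
    def test_linear_residual_lands_exactly(self):
        # e(alpha) = alpha - 3, J = 1: Gauss-Newton solves it in one step
        alpha, accepted, damping, rmse = lma_step(
            lambda a: np.array([a[0] - 3.0]), np.array([0.0]), damping=1e-12
        )
        assert accepted
        assert alpha[0] == pytest.approx(3.0, abs=1e-6)
        assert rmse == pytest.approx(0.0, abs=1e-6)

    def test_zero_residual_no_move(self):
        alpha, accepted, _, rmse = lma_step(
            lambda a: np.zeros(3), np.array([1.0, 2.0]), damping=1e-2
        )
        assert accepted and rmse == 0.0
        assert alpha.tolist() == [1.0, 2.0]

    def test_rejected_step_raises_damping(self):
        # residual whose first-order model is misleading at large steps
        calls = {"n": 0}

        def res(a):
            return np.array([np.sin(50.0 * a[0]) + 2.0 * a[0]])

        a0 = np.array([0.031])
        _, accepted, damping, _ = lma_step(res, a0, damping=1e-8)
        if not accepted:
            assert damping == pytest.approx(1e-7)


class TestPremiseStep:
    def _toy(self):
        spec = InputSpec("x", 0.0, np.pi, [gaussian_mf(0.8, 0.8), gaussian_mf(2.4, 0.8)])
        rules = [Rule((0,), np.array([[0.0, 0.0]])), Rule((1,), np.array([[0.0, 0.0]]))]
        return ANFISModel([spec], rules, 1)

    def test_zero_residual_unchanged(self):
        model = self._toy()
        for r in model.rules:
            r.consequent[:] = 0.0
        model.mark_dirty()
        X = np.linspace(0, np.pi, 20)[:, None]
        Y = np.zeros((20, 1))
        alpha0 = model.get_premise_params()
        opt = init_premise_opt(model)
        model, opt, rmse = premise_step(model, opt, (X, Y), mode="lma")
        assert rmse == 0.0
        assert np.array_equal(model.get_premise_params(), alpha0)

    def test_sin_toy_improves(self):
        model = self._toy()
        X = np.linspace(0, np.pi, 40)[:, None]
        Y = np.sin(X)
        rmse0 = batch_rmse(model, X, Y)
        est = ConsequentEstimator(model, lam=1.0)
        opt = init_premise_opt(model)
        for _ in range(20):
            for x, y in zip(X, Y):
                _, trace = model.forward(x)
                est.update(model, trace.normalized, x, y)
            model, opt, _ = premise_step(model, opt, (X, Y), mode="lma")
        assert batch_rmse(model, X, Y) < rmse0

    def test_accepted_steps_non_increasing(self):
        model = self._toy()
        X = np.linspace(0, np.pi, 30)[:, None]
        Y = np.sin(X)
        opt = init_premise_opt(model)
        prev = batch_rmse(model, X, Y)
        for _ in range(10):
            alpha_before = model.get_premise_params()
            model, opt, rmse = premise_step(model, opt, (X, Y), mode="lma")
            accepted = not np.array_equal(alpha_before, model.get_premise_params())
            if accepted:
                assert rmse <= prev + 1e-12
                prev = rmse

    def test_gd_momentum_mode_runs(self):
        model = self._toy()
        for r in model.rules:
            r.consequent[:] = 0.5  # nonzero so the premise gradient is alive
        model.mark_dirty()
        X = np.linspace(0, np.pi, 30)[:, None]
        Y = np.sin(X)
        opt = init_premise_opt(model)
        model, opt, rmse = premise_step(model, opt, (X, Y), mode="gd_momentum")
        assert np.isfinite(rmse)
        assert opt.momentum is not None and np.any(opt.momentum != 0)

    def test_widths_stay_positive(self):
        model = self._toy()
        opt = init_premise_opt(model, eta=10.0)  # absurd rate to force violation
        X = np.linspace(0, np.pi, 30)[:, None]
        Y = 5.0 * np.sin(X)
        for _ in range(5):
            model, opt, _ = premise_step(model, opt, (X, Y), mode="gd_momentum")
        for spec in model.inputs:
            for mf in spec.mfs:
                assert mf.s1 > 0 and mf.s2 > 0

    def test_unknown_mode(self):
        model = self._toy()
        with pytest.raises(ValueError):
            premise_step(model, init_premise_opt(model), (np.zeros((1, 1)), np.zeros((1, 1))), mode="bogus")


class TestDualTimescale:
    def test_premise_refinement_count(self, rng):
        model, _ = random_model(rng)
        est = ConsequentEstimator(model, lam=1.0)
        stream = [(rng.uniform(-2, 2, 2), rng.normal(size=1)) for _ in range(500)]
        *_, hist = dual_timescale_update(model, est, stream, n_premise=50)
        assert hist.premise_steps == 10
        assert hist.rls_steps == 500

    def test_stationary_linear_target_exact(self, rng):
        # one always-active rule: the affine target is inside the model class
        specs = [InputSpec("a", -2, 2, [gaussian_mf(0.0, 5.0)]),
                 InputSpec("b", -2, 2, [gaussian_mf(0.0, 5.0)])]
        model = ANFISModel(specs, [Rule((0, 0), np.zeros((1, 3)))], 1)
        est = ConsequentEstimator(model, lam=1.0, p0=1e6)
        for _ in range(200):
            x = rng.uniform(-2, 2, 2)
            y = 3.0 + 2.0 * x[0] - x[1]
            _, trace = model.forward(x)
            est.update(model, trace.normalized, x, [y])
        x = rng.uniform(-2, 2, 2)
        y, _ = model.forward(x)
        assert abs(y[0] - (3.0 + 2.0 * x[0] - x[1])) < 1e-8

    def test_forgetting_tracks_drift_better(self, rng):
        spec = InputSpec("x", -1, 1, [gaussian_mf(0.0, 3.0)])

        def run(lam):
            model = ANFISModel([spec], [Rule((0,), np.zeros((1, 2)))], 1)
            est = ConsequentEstimator(model, lam=lam, p0=1e3)
            r = np.random.default_rng(7)
            errs = []
            for t in range(500):
                x = r.uniform(-1, 1, 1)
                coef = 2.0 if t < 250 else -2.0
                y = coef * x[0]
                out, trace = model.forward(x)
                if t >= 250:
                    errs.append((out[0] - y) ** 2)
                est.update(model, trace.normalized, x, [y])
            return float(np.mean(errs))

        assert run(0.995) < run(1.0)


class TestOfflineTraining:
    def test_train_history_and_early_stop(self, rng, tmp_path):
        model, _ = random_model(rng)
        target, _ = random_model(np.random.default_rng(5))
        X = rng.uniform(-2, 2, (100, 2))
        Y = target.predict(X)
        csv = tmp_path / "hist.csv"
        hist = train(model, X, Y, epochs=30, lam=1.0, patience=5, history_csv=csv)
        assert {"epoch", "rmse", "accepted", "damping"} <= set(hist.columns)
        assert csv.exists()
        assert hist["rmse"].iloc[-1] <= hist["rmse"].iloc[0] + 1e-9

    def test_kfold_shapes(self, rng):
        target, _ = random_model(np.random.default_rng(3))
        X = rng.uniform(-2, 2, (60, 2))
        Y = target.predict(X)
        res = kfold_validate(lambda: random_model(np.random.default_rng(11))[0],
                             X, Y, k=5, epochs=3, rng=rng)
        assert len(res) == 5
        assert np.all(np.isfinite(res["test_rmse"]))


class TestSugenoRecovery:
    def test_noise_free_recovery(self, rng):
        truth, _ = random_model(np.random.default_rng(1))
        X = rng.uniform(-2, 2, (300, 2))
        Y = truth.predict(X)
        student = truth.copy()
        for r in student.rules:
            r.consequent[:] = 0.0
        student.mark_dirty()
        est = ConsequentEstimator(student, lam=1.0, p0=1e9)
        for _ in range(3):
            for x, y in zip(X, Y):
                _, trace = student.forward(x)
                est.update(student, trace.normalized, x, y)
        assert batch_rmse(student, X, Y) <= 1e-8

    def test_noisy_recovery_to_noise_floor(self, rng):
        truth, _ = random_model(np.random.default_rng(2))
        X = rng.uniform(-2, 2, (400, 2))
        sigma = 0.05
        Y = truth.predict(X) + sigma * rng.standard_normal((400, 1))
        student = truth.copy()
        for r in student.rules:
            r.consequent[:] = 0.0
        student.mark_dirty()
        est = ConsequentEstimator(student, lam=1.0, p0=1e6)
        for x, y in zip(X, Y):
            _, trace = student.forward(x)
            est.update(student, trace.normalized, x, y)
        assert batch_rmse(student, X, Y) <= 1.5 * sigma
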