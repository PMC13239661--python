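"""Movement-process layer: closed forms, exact simulation, population draws."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from trackdesign import (
    ModelKind,
    MovementModel,
    PopulationModel,
    SamplingSchedule,
    dense_covariance,
    position_acf,
    sample_population,
    simulate_track,
    true_area,
    true_mean_speed,
    velocity_variance,
)

HOUR = 3600.0
DAY = 86400.0


class TestPositionAcf:
    def test_zero_lag_returns_sigma(self):
        for model in (
            MovementModel(ModelKind.IID, sigma=2.5),
            MovementModel(ModelKind.OU, tau_p=DAY, sigma=2.5),
            MovementModel(ModelKind.OUF, tau_p=10.0, tau_v=1.0, sigma=2.5),
        ):
            assert position_acf(model, 0.0) == pytest.approx(2.5)

    def test_long_lag_decays_to_zero(self):
        model = MovementModel(ModelKind.OUF, tau_p=10.0, tau_v=1.0, sigma=2.0)
        assert position_acf(model, 1e4) == pytest.approx(0.0, abs=1e-12)

    def test_negative_lag_rejected(self):
        model = MovementModel(ModelKind.OU, tau_p=1.0, sigma=1.0)
        with pytest.raises(ValueError):
            position_acf(model, -1.0)

    def test_ou_is_tau_v_to_zero_limit_of_ouf(self):
        ou = MovementModel(ModelKind.OU, tau_p=DAY, sigma=1.0)
        ouf = MovementModel(ModelKind.OUF, tau_p=DAY, tau_v=1e-3 * DAY, sigma=1.0)
        lags = np.array([0.0, 0.1, 0.5, 1.0, 3.0]) * DAY
        a, b = position_acf(ou, lags), position_acf(ouf, lags)
        assert np.all(np.abs(a - b) <= 0.01 * np.maximum(a, 1e-12))

    def test_repeated_root_limit_continuous(self):
        near = MovementModel(ModelKind.OUF, tau_p=10.0, tau_v=10.0 * (1 - 1e-7), sigma=1.0)
        apart = MovementModel(ModelKind.OUF, tau_p=10.0, tau_v=10.0 * (1 - 1e-4), sigma=1.0)
        lags = np.array([0.5, 5.0, 20.0])
        assert position_acf(near, lags) == pytest.approx(
            position_acf(apart, lags), rel=1e-3
        )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        tau_p=st.floats(1.0, 1e6),
        ratio=st.floats(1e-3, 0.99),
        sigma=st.floats(1e-6, 1e9),
    )
    def test_nonincreasing_property(self, tau_p, ratio, sigma):
        model = MovementModel(
            ModelKind.OUF, tau_p=tau_p, tau_v=ratio * tau_p, sigma=sigma
        )
        lags = np.linspace(0, 5 * tau_p, 50)
        vals = position_acf(model, lags)
        assert vals[0] == pytest.approx(sigma, rel=1e-12)
        assert np.all(np.diff(vals) <= 1e-9 * sigma)

    def test_matches_empirical_lag_covariance(self):
        """Empirical autocovariance of exact simulations matches the closed form."""
        model = MovementModel(ModelKind.OUF, tau_p=10.0, tau_v=1.0, sigma=2.0)
        sched = SamplingSchedule(duration=5.0, interval=1.0)
        reps = 4000
        xs = np.empty((reps, sched.n))
        for i in range(reps):
            xs[i] = simulate_track(model, sched, seed=10_000 + i).x
        for lag_idx in (0, 1, 5):
            emp = np.mean(xs[:, 0] * xs[:, lag_idx])
            # var of product of bivariate normals: c^2 + s0*s_lag
            c = position_acf(model, lag_idx * 1.0)
            se = np.sqrt((c**2 + model.sigma**2) / reps)
            assert abs(emp - c) < 3 * se


class TestVelocityAndTruth:
    def test_velocity_variance_closed_form(self):
        model = MovementModel(ModelKind.OUF, tau_p=2.0, tau_v=1.0, sigma=2.0)
        assert velocity_variance(model) == pytest.approx(1.0)

    def test_velocity_variance_matches_acf_curvature(self):
        model = MovementModel(ModelKind.OUF, tau_p=10 * DAY, tau_v=HOUR, sigma=1.0)
        h = 1e-4 * model.tau_v
        d2 = (
            position_acf(model, 2 * h) - 2 * position_acf(model, h) + position_acf(model, 0.0)
        ) / h**2
        assert -d2 == pytest.approx(velocity_variance(model), rel=1e-4)

    def test_velocity_undefined_for_ou(self):
        with pytest.raises(ValueError, match="velocity not defined"):
            velocity_variance(MovementModel(ModelKind.OU, tau_p=1.0, sigma=1.0))

    def test_true_area_linear_in_sigma_and_monotone_in_level(self):
        m1 = MovementModel(ModelKind.OU, tau_p=1.0, sigma=1.0)
        m2 = MovementModel(ModelKind.OU, tau_p=1.0, sigma=2.0)
        assert true_area(m2) == pytest.approx(2 * true_area(m1))
        levels = [0.5, 0.8, 0.95, 0.999]
        areas = [true_area(m1, lv) for lv in levels]
        assert np.all(np.diff(areas) > 0)

    def test_true_area_monte_carlo_containment(self):
        model = MovementModel(ModelKind.OU, tau_p=1.0, sigma=1.0)
        area = true_area(model, 0.95)
        r2 = area / np.pi  # radius^2 of the quantile circle
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(1_000_000, 2))
        frac = np.mean(np.sum(pts**2, axis=1) <= r2)
        se = np.sqrt(0.95 * 0.05 / 1_000_000)
        assert abs(frac - 0.95) < 3 * se

    def test_true_mean_speed_rayleigh(self):
        model = MovementModel(ModelKind.OUF, tau_p=2.0, tau_v=0.5, sigma=1.0)
        assert velocity_variance(model) == pytest.approx(1.0)
        assert true_mean_speed(model) == pytest.approx(np.sqrt(np.pi / 2.0))
        rng = np.random.default_rng(4)
        v = rng.normal(size=(1_000_000, 2))
        emp = np.mean(np.hypot(v[:, 0], v[:, 1]))
        se = np.std(np.hypot(v[:, 0], v[:, 1])) / 1000.0
        assert abs(emp - true_mean_speed(model)) < 3 * se

    def test_speed_sqrt_scaling_in_sigma(self):
        m1 = MovementModel(ModelKind.OUF, tau_p=2.0, tau_v=1.0, sigma=1.0)
        m4 = MovementModel(ModelKind.OUF, tau_p=2.0, tau_v=1.0, sigma=4.0)
        assert true_mean_speed(m4) == pytest.approx(2 * true_mean_speed(m1))

    def test_speed_undefined_for_ou(self):
        with pytest.raises(ValueError):
            true_mean_speed(MovementModel(ModelKind.OU, tau_p=1.0, sigma=1.0))


class TestSimulation:
    def test_determinism(self, ouf_model):
        sched = SamplingSchedule(duration=10 * HOUR, interval=HOUR)
        a = simulate_track(ouf_model, sched, seed=5)
        b = simulate_track(ouf_model, sched, seed=5)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)
        c = simulate_track(ouf_model, sched, seed=6)
        assert not np.array_equal(a.x, c.x)

    def test_fix_cap_refused(self, ou_model):
        sched = SamplingSchedule(duration=2e6, interval=1.0)
        with pytest.raises(ValueError, match="coarsen"):
            simulate_track(ou_model, sched, seed=0)

    def test_iid_limit_of_coarse_ou(self):
        """Sampling an OU far apart gives effectively independent fixes."""
        model = MovementModel(ModelKind.OU, tau_p=1.0, sigma=3.0)
        n = 10_000
        sched = SamplingSchedule(duration=(n - 1) * 100.0, interval=100.0)
        tr = simulate_track(model, sched, seed=11)
        svar = 0.5 * (np.var(tr.x) + np.var(tr.y))
        se = model.sigma * np.sqrt(2.0 / (2 * n))  # pooled chi^2 sampling error
        assert abs(svar - model.sigma) < 3 * se

    def test_state_space_matches_dense_covariance_law(self, ouf_model):
        """The O(n) Markov recursion and the dense Gaussian law agree."""
        sched = SamplingSchedule(duration=20 * HOUR, interval=HOUR)
        n = sched.n
        cov = dense_covariance(ouf_model, sched.times)
        chol_inv = np.linalg.inv(np.linalg.cholesky(cov))
        reps = 300
        whitened = np.empty((reps, 2 * n))
        for i in range(reps):
            tr = simulate_track(ouf_model, sched, seed=20_000 + i)
            whitened[i, :n] = chol_inv @ tr.x
            whitened[i, n:] = chol_inv @ tr.y
        flat = whitened.ravel()
        # whitening by the dense Cholesky must produce iid standard normals
        assert abs(np.mean(flat)) < 3 / np.sqrt(flat.size)
        assert np.var(flat) == pytest.approx(1.0, abs=0.02)
        ks = stats.kstest(flat[::7], "norm")
        assert ks.pvalue > 0.01


class TestPopulationSampling:
    def test_prototype_mode_returns_copies(self, ouf_model):
        pop = PopulationModel.from_prototype(ouf_model)
        models = sample_population(pop, 5, seed=0)
        assert len(models) == 5
        assert all(m == models[0] for m in models)
        assert models[0].tau_p == pytest.approx(ouf_model.tau_p, rel=1e-12)

    def test_lognormal_sampling_moments(self, ouf_model):
        pop = PopulationModel.from_prototype(ouf_model, np.diag([0.25, 0.25, 0.25]))
        models = sample_population(pop, 4000, seed=1)
        logs = np.log([m.tau_p for m in models])
        se = 0.5 / np.sqrt(len(models))
        assert abs(np.mean(logs) - np.log(ouf_model.tau_p)) < 3.5 * se

    def test_single_draw_reproducible(self, ouf_model):
        pop = PopulationModel.from_prototype(ouf_model, np.diag([0.1, 0.1, 0.1]))
        a = sample_population(pop, 1, seed=9)[0]
        b = sample_population(pop, 1, seed=9)[0]
        assert a == b

    def test_invalid_draws_rejected(self, ouf_model):
        # huge timescale variance forces tau_v > tau_p draws; all results valid
        pop = PopulationModel.from_prototype(ouf_model, np.diag([1.0, 1.0, 0.0]))
        models = sample_population(pop, 200, seed=2)
        assert all(m.tau_p > m.tau_v > 0 for m in models)
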