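"""Area (AKDE / Gaussian) and speed (conditional simulation / SLD) estimators."""

import numpy as np
import pytest
from scipy import stats

from trackdesign import (
    ModelKind,
    MovementModel,
    SamplingSchedule,
    Track,
    akde_area,
    ctsd_speed,
    fit,
    gaussian_area,
    simulate_track,
    sld_speed,
    true_area,
    true_mean_speed,
)
from trackdesign.estimators import SpeedEstimationError
from trackdesign.fitting import FitResult

HOUR = 3600.0
DAY = 86400.0


def _oracle_fit(model: MovementModel, n_area: float = 1e8, n: int = 1000) -> FitResult:
    """A FitResult carrying the exact model (as if estimation were perfect)."""
    names = ("sigma", "tau_p", "tau_v") if model.kind is ModelKind.OUF else ("sigma", "tau_p")
    k = len(names)
    return FitResult(
        selected_kind=model.kind,
        model=model,
        ci_log={},
        loglik=0.0,
        aicc={},
        dof_area=n_area,
        dof_speed=n_area,
        n=n,
        cov_log=np.eye(k) / n_area,
        param_names=names,
    )


class TestGaussianArea:
    def test_plug_in_identity(self, ouf_model):
        fr = _oracle_fit(ouf_model)
        est = gaussian_area(fr)
        assert est.value == pytest.approx(true_area(ouf_model), rel=1e-12)

    def test_ci_collapses_as_dof_grows(self, ouf_model):
        widths = [
            gaussian_area(_oracle_fit(ouf_model, n_area=na)).ci_high
            - gaussian_area(_oracle_fit(ouf_model, n_area=na)).ci_low
            for na in (5, 50, 5000, 5e6)
        ]
        assert np.all(np.diff(widths) < 0)
        assert widths[-1] < 1e-2 * gaussian_area(_oracle_fit(ouf_model)).value

    def test_ci_brackets_value(self, ouf_fit):
        est = gaussian_area(ouf_fit)
        assert 0 < est.ci_low <= est.value <= est.ci_high


class TestAkdeArea:
    def test_grid_refinement_converged(self, ouf_track, ouf_fit):
        a = akde_area(ouf_track, ouf_fit, grid_size=151).value
        b = akde_area(ouf_track, ouf_fit, grid_size=301).value
        assert abs(a - b) / b < 0.01

    def test_agrees_with_gaussian_area_at_large_n(self, ouf_model):
        """With plenty of range crossings the KDE area is near the Gaussian area."""
        sched = SamplingSchedule(duration=60 * ouf_model.tau_p, interval=HOUR)
        rel = []
        for s in range(8):
            tr = simulate_track(ouf_model, sched, seed=4000 + s)
            fr = fit(tr, candidates=[ModelKind.OUF])
            a = akde_area(tr, fr).value
            g = gaussian_area(fr).value
            rel.append(a / g - 1.0)
        assert np.all(np.abs(rel) < 0.10)

    def test_short_duration_underestimates(self, ouf_model):
        """Too few range crossings: the typical informative estimate is low.

        Fits pinned at the timescale-identifiability bound report zero
        effective sample size and are excluded, as the design loop's
        weighting effectively does.
        """
        sched = SamplingSchedule(duration=2 * ouf_model.tau_p, interval=HOUR / 2)
        errs = []
        for s in range(40):
            tr = simulate_track(ouf_model, sched, seed=5000 + s)
            fr = fit(tr, candidates=[ModelKind.OU, ModelKind.OUF])
            if fr.dof_area <= 0.5:
                continue
            errs.append(akde_area(tr, fr).value / true_area(ouf_model) - 1.0)
        assert len(errs) >= 15
        assert np.median(errs) < 0.0

    def test_small_dof_flagged_unreliable(self, ouf_model):
        fr = _oracle_fit(ouf_model, n_area=1.0)
        tr = simulate_track(
            ouf_model, SamplingSchedule(duration=20 * HOUR, interval=HOUR), seed=1
        )
        est = akde_area(tr, fr)
        assert any("unreliable" in f for f in est.flags)


class TestCtsdSpeed:
    def test_requires_correlated_velocity(self, ou_model):
        tr = simulate_track(
            ou_model, SamplingSchedule(duration=10 * DAY, interval=HOUR), seed=2
        )
        fr = fit(tr, candidates=[ModelKind.OU])
        with pytest.raises(SpeedEstimationError, match="too coarse"):
            ctsd_speed(tr, fr)

    def test_reproducible_and_near_truth(self, ouf_track, ouf_fit, ouf_model):
        a = ctsd_speed(ouf_track, ouf_fit, n_draws=40, seed=7)
        b = ctsd_speed(ouf_track, ouf_fit, n_draws=40, seed=7)
        assert a.value == b.value
        assert a.value == pytest.approx(true_mean_speed(ouf_model), rel=0.25)
        assert a.ci_low <= a.value <= a.ci_high

    def test_robust_to_location_error(self, ouf_model):
        """Modeled location error keeps the speed estimate finite and close."""
        sched = SamplingSchedule(duration=20 * ouf_model.tau_p, interval=HOUR / 4)
        step_sd = np.sqrt(
            2 * (ouf_model.sigma - float(__import__("trackdesign").position_acf(ouf_model, sched.interval)))
        )
        err = 3.0 * step_sd
        rng = np.random.default_rng(99)
        vals, slds = [], []
        for s in range(5):
            tr = simulate_track(ouf_model, sched, seed=6000 + s)
            noisy = Track(
                tr.individual_id, tr.times,
                tr.x + rng.normal(scale=err, size=len(tr)),
                tr.y + rng.normal(scale=err, size=len(tr)),
                error_sd=np.full(len(tr), err),
            )
            fr = fit(noisy, candidates=[ModelKind.OUF])
            vals.append(ctsd_speed(noisy, fr, n_draws=30, seed=s).value)
            slds.append(sld_speed(noisy))
        truth = true_mean_speed(ouf_model)
        assert np.mean(slds) > 2.0 * truth  # naive estimator blown up by noise
        assert np.mean(vals) == pytest.approx(truth, rel=0.25)


class TestSldSpeed:
    def test_two_fix_example(self):
        tr = Track("a", np.array([0.0, 100.0]), np.array([0.0, 60.0]), np.array([0.0, 80.0]))
        assert sld_speed(tr) == pytest.approx(1.0)

    def test_exact_on_straight_line(self):
        t = np.arange(11.0)
        tr = Track("a", t, 3.0 * t, 4.0 * t)
        assert sld_speed(tr) == pytest.approx(5.0)

    def test_noise_only_expectation(self):
        """A stationary animal + GPS noise: E[SLD step] = sqrt(pi) * error SD."""
        r = 10.0
        n = 20_000
        rng = np.random.default_rng(21)
        tr = Track(
            "still", np.arange(float(n)),
            rng.normal(scale=r, size=n), rng.normal(scale=r, size=n),
        )
        expected = np.sqrt(np.pi) * r  # mean modulus of N(0, 2 r^2 I)
        assert sld_speed(tr) * (n - 1.0) / (n - 1.0) == pytest.approx(
            expected * (n - 1) / (n - 1), rel=0.02
        )

    def test_divergence_with_finer_sampling(self, ouf_model):
        """With fixed noise, SLD speed grows as the interval shrinks."""
        rng = np.random.default_rng(31)
        speeds = []
        for dt in (HOUR, HOUR / 4, HOUR / 16):
            sched = SamplingSchedule(duration=4 * ouf_model.tau_p, interval=dt)
            tr = simulate_track(ouf_model, sched, seed=77)
            noisy = Track(
                tr.individual_id, tr.times,
                tr.x + rng.normal(scale=200.0, size=len(tr)),
                tr.y + rng.normal(scale=200.0, size=len(tr)),
            )
            speeds.append(sld_speed(noisy))
        assert speeds[0] < speeds[1] < speeds[2]
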