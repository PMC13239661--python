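"""Corruption, relative errors, the design loop, and sensitivity mechanics."""

import math

import numpy as np
import pytest
from scipy import stats

from trackdesign import (
    CorruptionSpec,
    DesignSpec,
    ModelKind,
    MovementModel,
    PopulationModel,
    SamplingSchedule,
    ScalarEstimate,
    corrupt,
    evaluate_design,
    loo_correctness,
    pop_mean,
    relative_error,
    resample_combinations,
    simulate_track,
)
from trackdesign.design import DeploymentFailure, population_truth

HOUR = 3600.0
DAY = 86400.0


def _chi2_pool(rng, truth, m=10, nu=40.0):
    pool = []
    for i in range(m):
        val = truth * rng.chisquare(nu) / nu
        lo = val * nu / stats.chi2.ppf(0.975, nu)
        hi = val * nu / stats.chi2.ppf(0.025, nu)
        pool.append(ScalarEstimate(val, nu, lo, hi, "area", individual=str(i)))
    return pool


class TestCorrupt:
    @pytest.fixture()
    def track(self, ou_model):
        return simulate_track(
            ou_model, SamplingSchedule(duration=9999.0, interval=1.0), seed=0
        )

    def test_identity_spec(self, track):
        out = corrupt(track, CorruptionSpec(), seed=1)
        assert np.array_equal(out.x, track.x) and np.array_equal(out.times, track.times)

    def test_thinning_is_binomial(self, track):
        out = corrupt(track, CorruptionSpec(fix_success=0.5), seed=2)
        n = len(track)
        se = np.sqrt(n * 0.25)
        assert abs(len(out) - 0.5 * n) < 3 * se
        assert set(out.times).issubset(set(track.times))

    def test_storage_cap_keeps_earliest(self, track):
        out = corrupt(track, CorruptionSpec(storage_cap=100), seed=3)
        assert len(out) == 100
        assert np.array_equal(out.times, track.times[:100])

    def test_failure_truncates(self, track):
        out = corrupt(track, CorruptionSpec(failure_hazard=1 / 1000.0), seed=4)
        assert out.times[-1] <= track.times[-1]
        assert len(out) >= 2

    def test_error_recorded_and_applied(self, track):
        out = corrupt(track, CorruptionSpec(error_rms=50.0), seed=5)
        assert out.error_sd is not None and np.all(out.error_sd == 50.0)
        rmse = np.sqrt(np.mean((out.x - track.x) ** 2))
        assert rmse == pytest.approx(50.0, rel=0.1)

    def test_unusable_deployment_raises(self, track):
        with pytest.raises(DeploymentFailure):
            corrupt(track, CorruptionSpec(failure_hazard=1e6), seed=6)

    def test_deterministic(self, track):
        spec = CorruptionSpec(fix_success=0.7, error_rms=10.0)
        a = corrupt(track, spec, seed=7)
        b = corrupt(track, spec, seed=7)
        assert np.array_equal(a.x, b.x) and np.array_equal(a.times, b.times)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            CorruptionSpec(fix_success=0.0)
        with pytest.raises(ValueError):
            CorruptionSpec(storage_cap=1)


class TestRelativeError:
    @pytest.mark.parametrize(
        "estimate,truth,expected",
        [(10.0, 10.0, 0.0), (7.5, 10.0, -25.0), (1.014, 1.0, 1.4)],
    )
    def test_convention(self, estimate, truth, expected):
        assert relative_error(estimate, truth) == pytest.approx(expected)

    def test_nonpositive_truth_rejected(self):
        with pytest.raises(ValueError):
            relative_error(1.0, 0.0)


class TestPopulationTruth:
    def test_prototype_closed_forms(self, ouf_model):
        pop = PopulationModel.from_prototype(ouf_model)
        import trackdesign as td

        assert population_truth(pop, "area") == pytest.approx(td.true_area(ouf_model))
        assert population_truth(pop, "speed") == pytest.approx(
            td.true_mean_speed(ouf_model)
        )

    def test_heterogeneous_matches_monte_carlo(self, ouf_model):
        from trackdesign import sample_population, true_area, true_mean_speed

        pop = PopulationModel.from_prototype(ouf_model, np.diag([0.2, 0.2, 0.2]))
        models = sample_population(pop, 40_000, seed=3)
        mc_area = np.mean([true_area(m) for m in models])
        mc_speed = np.mean([true_mean_speed(m) for m in models])
        assert population_truth(pop, "area") == pytest.approx(mc_area, rel=0.02)
        assert population_truth(pop, "speed") == pytest.approx(mc_speed, rel=0.02)


class TestEvaluateDesign:
    @pytest.fixture(scope="class")
    def small_report(self, ou_model):
        pop = PopulationModel.from_prototype(ou_model)
        design = DesignSpec(
            schedule=SamplingSchedule(duration=12 * DAY, interval=DAY / 10),
            m=3, replicates=2, seed=21, targets=("area",),
            fit_candidates=(ModelKind.OU,), area_estimator="gaussian",
        )
        return pop, design, evaluate_design(pop, design)

    def test_bitwise_deterministic(self, small_report):
        pop, design, report = small_report
        again = evaluate_design(pop, design)
        assert report.to_json() == again.to_json()

    def test_verdict_recomputable_from_stored_errors(self, small_report):
        _, design, report = small_report
        s = report.summaries["area"]
        lo, hi = s.re_ci
        manual = (
            abs(np.mean(s.rel_errors)) <= design.error_threshold
            and max(abs(lo), abs(hi)) <= design.error_threshold
        )
        assert report.verdict("area") == manual

    def test_rows_round_trip(self, small_report):
        _, design, report = small_report
        rows = report.to_rows()
        assert len(rows) == len(report.summaries["area"].rel_errors)
        recomputed = [r["rel_error_pct"] for r in rows]
        assert recomputed == report.summaries["area"].rel_errors

    def test_corruption_reduces_usable_data(self, ou_model):
        pop = PopulationModel.from_prototype(ou_model)
        design = DesignSpec(
            schedule=SamplingSchedule(duration=12 * DAY, interval=DAY / 10),
            m=3, replicates=2, seed=22, targets=("area",),
            fit_candidates=(ModelKind.OU,), area_estimator="gaussian",
            corruption=CorruptionSpec(failure_hazard=5.0 / DAY),
        )
        report = evaluate_design(pop, design)
        s = report.summaries["area"]
        # early failures leave almost no usable tracks
        assert s.failure_fraction > 0 or s.n_failed_replicates > 0 or s.rel_errors


class TestResampling:
    def test_enumerates_small_pools(self):
        rng = np.random.default_rng(1)
        pool = _chi2_pool(rng, 10.0, m=5)
        rs = resample_combinations(pool, 2, seed=0)
        assert len(rs.combos) == math.comb(5, 2) == 10
        assert len(set(rs.combos)) == 10

    def test_caps_large_pools_at_250_distinct(self):
        rng = np.random.default_rng(2)
        pool = _chi2_pool(rng, 10.0, m=50)
        rs = resample_combinations(pool, 25, max_combos=250, seed=1)
        assert len(rs.combos) == 250
        assert len(set(rs.combos)) == 250
        assert all(len(set(c)) == 25 for c in rs.combos)

    def test_full_pool_single_combination(self):
        rng = np.random.default_rng(3)
        pool = _chi2_pool(rng, 10.0, m=6)
        rs = resample_combinations(pool, 6, seed=2)
        assert len(rs.combos) == 1
        assert rs.means[0] == pytest.approx(pop_mean(pool).mean)

    def test_stabilizes_estimates(self):
        """Across-combination means vary less than single-combination draws."""
        rng = np.random.default_rng(4)
        pool = _chi2_pool(rng, 10.0, m=20, nu=10.0)
        rs = resample_combinations(pool, 5, max_combos=200, seed=3)
        var_single = np.var(rs.means)
        # the across-combination mean is an average of ~200 correlated draws
        assert np.var([rs.mean]) <= var_single
        assert rs.envelope[0] <= rs.mean <= rs.envelope[1]


class TestLooCorrectness:
    def test_all_within_threshold(self):
        rng = np.random.default_rng(5)
        pool = _chi2_pool(rng, 10.0, m=10, nu=5000.0)
        truth = pop_mean(pool).mean
        assert loo_correctness(pool, truth, threshold=5.0) == 100.0

    def test_matches_direct_enumeration(self):
        rng = np.random.default_rng(6)
        pool = _chi2_pool(rng, 10.0, m=10, nu=30.0)
        truth = 10.0
        direct = [
            abs(relative_error(pop_mean(pool[:i] + pool[i + 1:]).mean, truth)) <= 5.0
            for i in range(10)
        ]
        expected = 100.0 * sum(direct) / 10
        assert loo_correctness(pool, truth, threshold=5.0) == expected

    def test_zero_when_truth_far(self):
        rng = np.random.default_rng(7)
        pool = _chi2_pool(rng, 10.0, m=10)
        assert loo_correctness(pool, 100.0, threshold=5.0) == 0.0

    def test_requires_three(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError):
            loo_correctness(_chi2_pool(rng, 10.0, m=2), 10.0)
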