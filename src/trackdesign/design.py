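"""Evaluation of candidate sampling designs against closed-form truth.

A design is a sampling schedule (duration T, interval dt), a population
sample size m, a corruption model for deployment hazards, and a replicate
count.  Each replicate samples m individuals from the population law,
simulates and corrupts their tracks, fits movement models, estimates the
targets (home-range area and/or mean speed), aggregates them into a
population mean, and scores the population mean against the closed-form
expected value under the simulated population with a relative error.  The
paper-of-record convention for relative error is 100*(estimate - truth)/
truth, so negative values are underestimates, and a design "passes" when
the mean relative error and its confidence bounds all sit inside the
+/- threshold band (default 5%).

Sensitivity analyses: resampling of individual combinations per m (capped
number of distinct combinations) and leave-one-out correctness rates.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .estimators import (
    ScalarEstimate,
    SpeedEstimationError,
    akde_area,
    ctsd_speed,
    gaussian_area,
)
from .fitting import fit as fit_track
from .models import (
    ModelKind,
    PopulationModel,
    SamplingSchedule,
    Track,
    sample_population,
    simulate_track,
    true_area,
    true_mean_speed,
)
from .population import PopulationEstimate, pop_mean

__all__ = [
    "CorruptionSpec",
    "DesignSpec",
    "DesignReport",
    "DeploymentFailure",
    "corrupt",
    "relative_error",
    "population_truth",
    "evaluate_design",
    "resample_combinations",
    "loo_correctness",
]

logger = logging.getLogger(__name__)


class DeploymentFailure(RuntimeError):
    """A corrupted deployment yielded no usable data (counted, not fatal)."""


@dataclass(frozen=True)
class CorruptionSpec:
    """Deployment hazards applied to an ideal track.

    fix_success : probability each scheduled fix succeeds (data loss).
    failure_hazard : rate (1/s) of premature permanent device failure.
    storage_cap : maximum number of stored fixes, if any.
    error_rms : per-axis location-error standard deviation (m).
    """

    fix_success: float = 1.0
    failure_hazard: float = 0.0
    storage_cap: Optional[int] = None
    error_rms: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.fix_success <= 1.0):
            raise ValueError("fix_success must be in (0, 1]")
        if self.failure_hazard < 0 or self.error_rms < 0:
            raise ValueError("hazard and error_rms must be nonnegative")
        if self.storage_cap is not None and self.storage_cap < 2:
            raise ValueError("storage_cap must be >= 2")

    @property
    def is_identity(self) -> bool:
        return (
            self.fix_success == 1.0
            and self.failure_hazard == 0.0
            and self.storage_cap is None
            and self.error_rms == 0.0
        )


def corrupt(
    track: Track,
    spec: CorruptionSpec,
    seed: "int | np.random.Generator",
    error_multipliers: Optional[np.ndarray] = None,
) -> Track:
    """Apply deployment hazards to a track, in causal order.

    1. premature failure: truncate at an exponential failure time with the
       given hazard; 2. storage cap: keep the earliest ``cap`` fixes;
    3. data loss: Bernoulli(fix_success) thinning; 4. location error:
    additive iid Gaussian noise per axis (SD = error_rms, optionally scaled
    per fix), recorded in the track's ``error_sd``.

    Raises
    ------
    DeploymentFailure
        If fewer than 2 usable fixes remain; design evaluation counts these.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    times, x, y = track.times, track.x, track.y
    mult = (
        np.ones_like(times)
        if error_multipliers is None
        else np.broadcast_to(np.asarray(error_multipliers, float), times.shape)
    )

    if spec.failure_hazard > 0:
        t_fail = rng.exponential(1.0 / spec.failure_hazard)
        keep = times - times[0] <= t_fail
        times, x, y, mult = times[keep], x[keep], y[keep], mult[keep]
    if spec.storage_cap is not None:
        times, x, y, mult = (
            times[: spec.storage_cap],
            x[: spec.storage_cap],
            y[: spec.storage_cap],
            mult[: spec.storage_cap],
        )
    if spec.fix_success < 1.0:
        keep = rng.random(len(times)) < spec.fix_success
        times, x, y, mult = times[keep], x[keep], y[keep], mult[keep]
    if len(times) < 2:
        raise DeploymentFailure("deployment yielded no usable data")

    error_sd = None
    if spec.error_rms > 0:
        error_sd = spec.error_rms * mult
        x = x + rng.normal(size=len(times)) * error_sd
        y = y + rng.normal(size=len(times)) * error_sd
    return Track(track.individual_id, times, x, y, error_sd=error_sd)


def relative_error(estimate: float, truth: float) -> float:
    """Relative error in percent: 100 * (estimate - truth) / truth.

    Negative values are underestimates.
    """
    if truth <= 0:
        raise ValueError("truth must be positive")
    return 100.0 * (estimate - truth) / truth


def population_truth(pop: PopulationModel, target: str) -> float:
    """Closed-form population mean of a target under the population law.

    With log-parameters (log tau_p, log tau_v, log sigma) multivariate
    normal (mean mu, covariance S), both targets are log-normal functionals
    with exact means:

    * area: pi * q_0.95 * E[sigma] = pi * q * exp(mu_sigma + S_sigma/2)
    * speed: sqrt(pi/2) * E[exp((log sigma - log tau_p - log tau_v)/2)]
      = sqrt(pi/2) * exp(a'mu/2 + a'Sa/8), a = (-1, -1, 1).
    """
    mu = pop.mean_log
    cov = pop.cov_log
    if target == "area":
        q = stats.chi2.ppf(0.95, df=2)
        return float(np.pi * q * math.exp(mu[2] + cov[2, 2] / 2.0))
    if target == "speed":
        if pop.kind is not ModelKind.OUF:
            raise ValueError("speed truth requires an OUF population")
        a = np.array([-1.0, -1.0, 1.0])
        return float(
            math.sqrt(math.pi / 2.0)
            * math.exp(0.5 * float(a @ mu) + 0.125 * float(a @ cov @ a))
        )
    raise ValueError(f"unknown target {target!r}")


@dataclass(frozen=True)
class DesignSpec:
    """A candidate study design to evaluate."""

    schedule: SamplingSchedule
    m: int
    replicates: int = 10
    seed: int = 0
    corruption: CorruptionSpec = field(default_factory=CorruptionSpec)
    targets: tuple[str, ...] = ("area", "speed")
    error_threshold: float = 5.0
    fit_candidates: tuple[ModelKind, ...] = (ModelKind.IID, ModelKind.OU, ModelKind.OUF)
    area_estimator: str = "akde"  # "akde" | "gaussian"
    speed_draws: int = 64

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if self.replicates < 1 or self.error_threshold <= 0:
            raise ValueError("replicates >= 1 and threshold > 0 required")
        for t in self.targets:
            if t not in ("area", "speed"):
                raise ValueError(f"unknown target {t!r}")


@dataclass
class TargetSummary:
    """Aggregated outcome for one target across replicates."""

    target: str
    truth: float
    rel_errors: list[float]  # population-mean RE per replicate (successes)
    ci_widths_pct: list[float]  # population CI width as % of truth
    n_failed_individuals: int
    n_individuals: int
    n_failed_replicates: int
    mean_dof: float  # mean effective size (N_area or N_speed)

    @property
    def mean_re(self) -> float:
        return float(np.mean(self.rel_errors)) if self.rel_errors else float("nan")

    @property
    def re_ci(self) -> tuple[float, float]:
        k = len(self.rel_errors)
        if k < 2:
            return (float("nan"), float("nan"))
        se = float(np.std(self.rel_errors, ddof=1) / np.sqrt(k))
        t = stats.t.ppf(0.975, k - 1)
        return (self.mean_re - t * se, self.mean_re + t * se)

    @property
    def mean_ci_width_pct(self) -> float:
        return float(np.mean(self.ci_widths_pct)) if self.ci_widths_pct else float("nan")

    @property
    def failure_fraction(self) -> float:
        return self.n_failed_individuals / max(self.n_individuals, 1)

    def passes(self, threshold: float) -> bool:
        lo, hi = self.re_ci
        return (
            np.isfinite(self.mean_re)
            and abs(self.mean_re) <= threshold
            and np.isfinite(lo)
            and max(abs(lo), abs(hi)) <= threshold
        )


@dataclass
class DesignReport:
    """Per-design verdicts plus the raw replicate-level relative errors."""

    design: DesignSpec
    summaries: dict[str, TargetSummary]

    def verdict(self, target: str) -> bool:
        return self.summaries[target].passes(self.design.error_threshold)

    def to_dict(self) -> dict:
        out = {
            "duration_s": self.design.schedule.duration,
            "interval_s": self.design.schedule.interval,
            "m": self.design.m,
            "replicates": self.design.replicates,
            "seed": self.design.seed,
            "threshold_pct": self.design.error_threshold,
            "targets": {},
        }
        for name, s in self.summaries.items():
            lo, hi = s.re_ci
            out["targets"][name] = {
                "truth": s.truth,
                "mean_rel_error_pct": s.mean_re,
                "rel_error_ci_pct": [lo, hi],
                "mean_ci_width_pct": s.mean_ci_width_pct,
                "rel_errors_pct": s.rel_errors,
                "failure_fraction": s.failure_fraction,
                "failed_replicates": s.n_failed_replicates,
                "mean_effective_size": s.mean_dof,
                "pass": bool(s.passes(self.design.error_threshold)),
            }
        return out

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_rows(self) -> list[dict]:
        """Tidy rows (one per replicate x target) for CSV export/plotting."""
        rows = []
        for name, s in self.summaries.items():
            for i, re_val in enumerate(s.rel_errors):
                rows.append(
                    {
                        "target": name,
                        "replicate": i,
                        "m": self.design.m,
                        "duration_s": self.design.schedule.duration,
                        "interval_s": self.design.schedule.interval,
                        "rel_error_pct": re_val,
                        "ci_width_pct": s.ci_widths_pct[i]
                        if i < len(s.ci_widths_pct)
                        else float("nan"),
                    }
                )
        return rows


def _estimate_individual(track, design, rng, target):
    """Fit + estimate one target for one corrupted track; may raise."""
    fr = fit_track(track, candidates=design.fit_candidates)
    if target == "area":
        if design.area_estimator == "gaussian":
            est = gaussian_area(fr)
        else:
            est = akde_area(track, fr)
        est.individual = track.individual_id
        return est, fr
    est = ctsd_speed(track, fr, n_draws=design.speed_draws, seed=rng)
    return est, fr


def evaluate_design(pop: PopulationModel, design: DesignSpec) -> DesignReport:
    """Score one candidate design against the population's closed-form truth.

    Fully deterministic for a given (pop, design): all randomness derives
    from ``design.seed`` through per-replicate, per-individual substreams.
    """
    truths = {t: population_truth(pop, t) for t in design.targets}
    acc = {
        t: TargetSummary(
            target=t, truth=truths[t], rel_errors=[], ci_widths_pct=[],
            n_failed_individuals=0, n_individuals=0, n_failed_replicates=0,
            mean_dof=0.0,
        )
        for t in design.targets
    }
    dof_sums = {t: [] for t in design.targets}

    for rep in range(design.replicates):
        rep_rng = np.random.default_rng(
            np.random.SeedSequence([design.seed, rep])
        )
        models = sample_population(pop, design.m, rep_rng)
        per_target: dict[str, list[ScalarEstimate]] = {t: [] for t in design.targets}
        for i, model in enumerate(models):
            track = simulate_track(
                model, design.schedule, rep_rng, individual_id=f"r{rep}i{i}"
            )
            try:
                if not design.corruption.is_identity:
                    track = corrupt(track, design.corruption, rep_rng)
            except DeploymentFailure:
                for t in design.targets:
                    acc[t].n_failed_individuals += 1
                    acc[t].n_individuals += 1
                continue
            for t in design.targets:
                acc[t].n_individuals += 1
                try:
                    est, fr = _estimate_individual(track, design, rep_rng, t)
                    per_target[t].append(est)
                    dof_sums[t].append(
                        fr.dof_area if t == "area" else fr.dof_speed
                    )
                except (SpeedEstimationError, RuntimeError, ValueError) as exc:
                    acc[t].n_failed_individuals += 1
                    logger.debug("individual failed for %s: %s", t, exc)
        for t in design.targets:
            ests = per_target[t]
            if not ests:
                acc[t].n_failed_replicates += 1
                continue
            pe = pop_mean(ests)
            acc[t].rel_errors.append(relative_error(pe.mean, truths[t]))
            acc[t].ci_widths_pct.append(100.0 * (pe.ci_high - pe.ci_low) / truths[t])

    for t in design.targets:
        acc[t].mean_dof = float(np.mean(dof_sums[t])) if dof_sums[t] else 0.0
    return DesignReport(design=design, summaries=acc)


# ----------------------------------------------------------------------
# sensitivity analyses


def _sample_combinations(n: int, m: int, max_combos: int, rng) -> list[tuple[int, ...]]:
    total = math.comb(n, m)
    if total <= max_combos:
        return list(itertools.combinations(range(n), m))
    seen: set[tuple[int, ...]] = set()
    out: list[tuple[int, ...]] = []
    while len(out) < max_combos:
        combo = tuple(sorted(rng.choice(n, size=m, replace=False).tolist()))
        if combo not in seen:
            seen.add(combo)
            out.append(combo)
    return out


@dataclass
class ResampleResult:
    """Across-combination population means for one population sample size m."""

    m: int
    combos: list[tuple[int, ...]]
    means: np.ndarray
    ci_lows: np.ndarray
    ci_highs: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.means))

    @property
    def envelope(self) -> tuple[float, float]:
        return float(np.min(self.means)), float(np.max(self.means))


def resample_combinations(
    pool: Sequence[ScalarEstimate],
    m: int,
    max_combos: int = 250,
    seed: "int | np.random.Generator" = 0,
) -> ResampleResult:
    """Population means over random distinct combinations of m individuals.

    All C(|pool|, m) combinations are enumerated when there are at most
    ``max_combos`` of them; otherwise ``max_combos`` distinct combinations
    are sampled uniformly without replacement.
    """
    pool = list(pool)
    n = len(pool)
    if not (2 <= m <= n):
        raise ValueError("require 2 <= m <= |pool|")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    combos = _sample_combinations(n, m, max_combos, rng)
    means = np.empty(len(combos))
    lows = np.empty(len(combos))
    highs = np.empty(len(combos))
    for i, combo in enumerate(combos):
        pe = pop_mean([pool[j] for j in combo])
        means[i], lows[i], highs[i] = pe.mean, pe.ci_low, pe.ci_high
    return ResampleResult(m=m, combos=combos, means=means, ci_lows=lows, ci_highs=highs)


def loo_correctness(
    pool: Sequence[ScalarEstimate], truth: float, threshold: float = 5.0
) -> float:
    """Leave-one-out correctness rate (%).

    Excludes each individual in turn, recomputes the population mean, and
    reports the percentage of leave-one-out estimates whose relative error
    lies within +/- threshold.
    """
    pool = list(pool)
    if len(pool) < 3:
        raise ValueError("need at least 3 estimates for leave-one-out")
    hits = 0
    for i in range(len(pool)):
        pe = pop_mean(pool[:i] + pool[i + 1:])
        if abs(relative_error(pe.mean, truth)) <= threshold:
            hits += 1
    return 100.0 * hits / len(pool)
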