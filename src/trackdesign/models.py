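"""Stationary Gaussian movement processes (IID, OU, OUF).

The package's movement processes are isotropic, range-resident Gaussian
processes characterised by three scale parameters:

* ``tau_p`` — position autocorrelation timescale (home-range crossing time),
* ``tau_v`` — velocity autocorrelation timescale (directional persistence),
* ``sigma`` — per-axis stationary positional variance (m**2).

The OUF (Ornstein-Uhlenbeck with foraging) process has both timescales; the
OU process is its ``tau_v -> 0`` limit (uncorrelated velocities); IID ignores
both timescales.  Each axis is an independent copy of the same univariate
process, shifted by the home-range ``center``.

Per axis the OUF position autocovariance is

    C(t) = sigma * (tau_p * exp(-t/tau_p) - tau_v * exp(-t/tau_v)) / (tau_p - tau_v)

which is realised exactly by the 2-d Markov state (position, velocity) with
drift eigenvalues -1/tau_p and -1/tau_v.  Simulation draws the stationary
state and propagates it with the exact discrete transition, so tracks are
exact finite-dimensional draws of the continuous-time law at the schedule
times (no discretisation error).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ModelKind",
    "MovementModel",
    "SamplingSchedule",
    "Track",
    "PopulationModel",
    "position_acf",
    "velocity_variance",
    "true_area",
    "true_mean_speed",
    "simulate_track",
    "sample_population",
    "dense_covariance",
    "ou_transition",
    "ouf_transition",
]

#: relative tolerance under which tau_p and tau_v are treated as a repeated root
_DEGENERATE_RTOL = 1e-6

#: refuse simulations beyond this many fixes
MAX_FIXES = 1_000_000


class ModelKind(str, enum.Enum):
    IID = "IID"
    OU = "OU"
    OUF = "OUF"


@dataclass(frozen=True)
class MovementModel:
    """An isotropic stationary movement process.

    Parameters
    ----------
    kind : ModelKind
    tau_p : float
        Position autocorrelation timescale in seconds (ignored for IID).
    tau_v : float
        Velocity autocorrelation timescale in seconds (0 for OU/IID).
    sigma : float
        Per-axis stationary positional variance in m**2.
    center : (float, float)
        Home-range center in meters.
    """

    kind: ModelKind
    tau_p: float = 0.0
    tau_v: float = 0.0
    sigma: float = 1.0
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        kind = ModelKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if not np.isfinite(self.sigma) or self.sigma <= 0:
            raise ValueError("sigma must be positive and finite")
        if kind is ModelKind.OU:
            if self.tau_p <= 0:
                raise ValueError("OU requires tau_p > 0")
        elif kind is ModelKind.OUF:
            if not (self.tau_p > self.tau_v > 0):
                raise ValueError("OUF requires tau_p > tau_v > 0")

    def with_center(self, center: tuple[float, float]) -> "MovementModel":
        return replace(self, center=(float(center[0]), float(center[1])))


@dataclass(frozen=True)
class SamplingSchedule:
    """A regular sampling design: duration ``T`` and fix interval ``dt``.

    The fix times are ``i * dt`` for ``i = 0 .. floor(T/dt)``, so a schedule
    holds ``n = floor(T/dt) + 1`` locations before any corruption.
    """

    duration: float
    interval: float

    def __post_init__(self) -> None:
        if not (0 < self.interval <= self.duration):
            raise ValueError("require 0 < interval <= duration")

    @property
    def n(self) -> int:
        return int(np.floor(self.duration / self.interval + 1e-9)) + 1

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) * self.interval


@dataclass
class Track:
    """Time-stamped planar locations for one individual."""

    individual_id: str
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    error_sd: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.times) == len(self.x) == len(self.y)):
            raise ValueError("times, x, y must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("coordinates must be finite")
        if self.error_sd is not None:
            self.error_sd = np.broadcast_to(
                np.asarray(self.error_sd, dtype=float), self.times.shape
            ).copy()

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class PopulationModel:
    """Log-normal population law for the movement parameters.

    ``mean_log`` and ``cov_log`` describe the distribution of
    (log tau_p, log tau_v, log sigma) across individuals; a zero covariance
    is the "prototype" mode in which every individual shares the same
    parameters.  ``center_dispersion`` optionally scatters individual
    home-range centers (iid Gaussian per axis, meters).
    """

    kind: ModelKind
    mean_log: np.ndarray  # (log tau_p, log tau_v, log sigma)
    cov_log: np.ndarray
    center_dispersion: float = 0.0

    def __post_init__(self) -> None:
        self.kind = ModelKind(self.kind)
        self.mean_log = np.asarray(self.mean_log, dtype=float)
        self.cov_log = np.atleast_2d(np.asarray(self.cov_log, dtype=float))
        if self.mean_log.shape != (3,) or self.cov_log.shape != (3, 3):
            raise ValueError("mean_log must be length-3, cov_log 3x3")
        if not np.allclose(self.cov_log, self.cov_log.T):
            raise ValueError("cov_log must be symmetric")
        if np.min(np.linalg.eigvalsh(self.cov_log)) < -1e-10:
            raise ValueError("cov_log must be positive semi-definite")
        self.prototype()  # validates exp(mean_log)

    @classmethod
    def from_prototype(
        cls,
        model: MovementModel,
        cov_log: Optional[np.ndarray] = None,
        center_dispersion: float = 0.0,
    ) -> "PopulationModel":
        mean_log = np.log([max(model.tau_p, 1.0), max(model.tau_v, 1.0), model.sigma])
        cov = np.zeros((3, 3)) if cov_log is None else cov_log
        pop = cls(model.kind, mean_log, cov, center_dispersion)
        return pop

    def prototype(self) -> MovementModel:
        """The population-averaged (median on log scale) movement model."""
        tau_p, tau_v, sigma = np.exp(self.mean_log)
        if self.kind is ModelKind.IID:
            return MovementModel(ModelKind.IID, sigma=sigma)
        if self.kind is ModelKind.OU:
            return MovementModel(ModelKind.OU, tau_p=tau_p, sigma=sigma)
        return MovementModel(ModelKind.OUF, tau_p=tau_p, tau_v=tau_v, sigma=sigma)


# ----------------------------------------------------------------------
# closed-form summaries


def position_acf(model: MovementModel, lag: "float | np.ndarray") -> np.ndarray:
    """Per-axis positional autocovariance C(lag), in m**2.

    C(0) = sigma for every kind; OU decays as exp(-lag/tau_p); OUF is the
    two-exponential mixture with continuous velocities; IID is a point mass
    at lag 0.
    """
    lag_arr = np.asarray(lag, dtype=float)
    if np.any(lag_arr < 0):
        raise ValueError("lag must be nonnegative")
    if model.kind is ModelKind.IID:
        out = np.where(lag_arr == 0.0, model.sigma, 0.0)
    elif model.kind is ModelKind.OU:
        out = model.sigma * np.exp(-lag_arr / model.tau_p)
    else:
        tp, tv = model.tau_p, model.tau_v
        if abs(tp - tv) < _DEGENERATE_RTOL * tp:
            # repeated-root limit of (tp e^{-t/tp} - tv e^{-t/tv})/(tp - tv)
            out = model.sigma * np.exp(-lag_arr / tp) * (1.0 + lag_arr / tp)
        else:
            out = (
                model.sigma
                * (tp * np.exp(-lag_arr / tp) - tv * np.exp(-lag_arr / tv))
                / (tp - tv)
            )
    return out if out.ndim else float(out)


def velocity_variance(model: MovementModel) -> float:
    """Per-axis stationary velocity variance sigma/(tau_p*tau_v), (m/s)**2.

    Defined only for OUF: OU and IID have no mean-square-differentiable
    position process.
    """
    if model.kind is not ModelKind.OUF:
        raise ValueError(f"velocity not defined for {model.kind.value} model")
    return model.sigma / (model.tau_p * model.tau_v)


def true_area(model: MovementModel, level: float = 0.95) -> float:
    """Area (m**2) of the ``level`` quantile ellipse of the stationary law.

    For an isotropic bivariate Gaussian this is pi * q * sigma with q the
    chi-square(2) quantile at ``level``; it is the design loop's expected
    value for home-range area.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    q = stats.chi2.ppf(level, df=2)
    return float(np.pi * q * model.sigma)


def true_mean_speed(model: MovementModel) -> float:
    """Expected instantaneous speed E|v| = sqrt(pi/2 * sigma/(tau_p*tau_v)).

    The 2-d velocity is isotropic Gaussian, so speed is Rayleigh with mean
    sqrt(pi/2) times the per-axis velocity standard deviation.
    """
    return float(np.sqrt(np.pi / 2.0 * velocity_variance(model)))


# ----------------------------------------------------------------------
# exact transition matrices


def ou_transition(tau_p: float, sigma: float, dt: float) -> tuple[float, float]:
    """OU discrete transition: returns (phi, q) with x' = phi*x + N(0, q)."""
    phi = np.exp(-dt / tau_p)
    return phi, sigma * (1.0 - phi * phi)


def ouf_transition(
    tau_p: float, tau_v: float, sigma: float, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """OUF discrete transition for the (position, velocity) state.

    Returns (Phi, Q): ``z' = Phi @ z + N(0, Q)``.  Phi is the matrix
    exponential of the companion drift with eigenvalues -1/tau_p, -1/tau_v;
    Q follows from stationarity: Q = P_inf - Phi P_inf Phi'.
    """
    a, b = 1.0 / tau_p, 1.0 / tau_v
    if abs(tau_p - tau_v) < _DEGENERATE_RTOL * tau_p:
        e = np.exp(-a * dt)
        phi = e * np.array([[1.0 + a * dt, dt], [-a * a * dt, 1.0 - a * dt]])
    else:
        ea, eb = np.exp(-a * dt), np.exp(-b * dt)
        d = b - a
        phi = np.array(
            [
                [(b * ea - a * eb) / d, (ea - eb) / d],
                [a * b * (eb - ea) / d, (b * eb - a * ea) / d],
            ]
        )
    p_inf = np.diag([sigma, sigma * a * b])
    q = p_inf - phi @ p_inf @ phi.T
    # guard tiny negative eigenvalues from cancellation at very small dt
    q = 0.5 * (q + q.T)
    return phi, q


def stationary_state_cov(model: MovementModel) -> np.ndarray:
    if model.kind is ModelKind.OUF:
        return np.diag([model.sigma, velocity_variance(model)])
    return np.array([[model.sigma]])


# ----------------------------------------------------------------------
# simulation


def _chol_psd(mat: np.ndarray) -> np.ndarray:
    """Cholesky tolerant of semi-definite matrices (clips tiny negatives)."""
    try:
        return np.linalg.cholesky(mat)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(mat)
        w = np.clip(w, 0.0, None)
        return v * np.sqrt(w)


def simulate_track(
    model: MovementModel,
    schedule: "SamplingSchedule | Sequence[float]",
    seed: "int | np.random.Generator",
    individual_id: str = "sim",
) -> Track:
    """Draw a track exactly from the stationary law at the schedule times.

    The same (model, schedule, seed) triple always yields bitwise-identical
    coordinates.  ``schedule`` may be a :class:`SamplingSchedule` or an
    explicit strictly-increasing array of times (seconds).
    """
    times = (
        schedule.times
        if isinstance(schedule, SamplingSchedule)
        else np.asarray(schedule, dtype=float)
    )
    n = len(times)
    if n > MAX_FIXES:
        raise ValueError(
            f"schedule has {n} fixes > cap {MAX_FIXES}; coarsen the interval"
        )
    if n and np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    if model.kind is ModelKind.IID:
        sd = np.sqrt(model.sigma)
        xy = rng.normal(size=(n, 2)) * sd
    else:
        xy = np.empty((n, 2))
        dts = np.diff(times)
        p_inf = stationary_state_cov(model)
        l0 = _chol_psd(p_inf)
        d = p_inf.shape[0]
        # cache transitions by dt (schedules are mostly uniform)
        cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}

        def trans(dt: float) -> tuple[np.ndarray, np.ndarray]:
            key = float(dt)
            if key not in cache:
                if model.kind is ModelKind.OU:
                    phi, q = ou_transition(model.tau_p, model.sigma, dt)
                    cache[key] = (np.array([[phi]]), np.array([[np.sqrt(max(q, 0.0))]]))
                else:
                    phi, q = ouf_transition(model.tau_p, model.tau_v, model.sigma, dt)
                    cache[key] = (phi, _chol_psd(q))
            return cache[key]

        for axis in range(2):
            z = l0 @ rng.normal(size=d)
            xy[0, axis] = z[0]
            for i, dt in enumerate(dts):
                phi, lq = trans(dt)
                z = phi @ z + lq @ rng.normal(size=d)
                xy[i + 1, axis] = z[0]

    xy[:, 0] += model.center[0]
    xy[:, 1] += model.center[1]
    return Track(individual_id, times, xy[:, 0], xy[:, 1])


def dense_covariance(model: MovementModel, times: Sequence[float]) -> np.ndarray:
    """Full n x n per-axis covariance matrix from the closed-form ACF.

    O(n^2) memory — intended for oracles and small-n cross-checks, not for
    production simulation (which is O(n) through the Markov state).
    """
    t = np.asarray(times, dtype=float)
    lags = np.abs(t[:, None] - t[None, :])
    return np.asarray(position_acf(model, lags))


def sample_population(
    pop: PopulationModel, m: int, seed: "int | np.random.Generator"
) -> list[MovementModel]:
    """Draw ``m`` individual models from the population law.

    Log-parameters are multivariate normal; draws violating the model-kind
    invariants (e.g. tau_v >= tau_p for OUF) are rejection-resampled.  With
    zero ``cov_log`` this returns ``m`` copies of the prototype.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    proto = pop.prototype()
    models: list[MovementModel] = []
    zero_cov = not np.any(pop.cov_log)
    factor = None if zero_cov else _chol_psd(pop.cov_log)
    n_rejected = 0
    for _ in range(m):
        if zero_cov:
            model = proto
        else:
            for _attempt in range(1000):
                draw = pop.mean_log + factor @ rng.standard_normal(3)
                tau_p, tau_v, sigma = np.exp(draw)
                try:
                    if pop.kind is ModelKind.IID:
                        model = MovementModel(ModelKind.IID, sigma=sigma)
                    elif pop.kind is ModelKind.OU:
                        model = MovementModel(ModelKind.OU, tau_p=tau_p, sigma=sigma)
                    else:
                        model = MovementModel(
                            ModelKind.OUF, tau_p=tau_p, tau_v=tau_v, sigma=sigma
                        )
                    break
                except ValueError:
                    n_rejected += 1
            else:
                raise RuntimeError("could not draw a valid model in 1000 attempts")
        if pop.center_dispersion > 0:
            center = tuple(rng.normal(scale=pop.center_dispersion, size=2))
            model = model.with_center(center)
        models.append(model)
    if n_rejected:
        import logging

        logging.getLogger(__name__).info(
            "sample_population: rejection-resampled %d invalid draws", n_rejected
        )
    return models
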