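"""Population-level aggregation of positive scalar estimates.

Individual home-range areas and mean speeds are positive quantities whose
estimates carry chi-square sampling distributions (estimate ~ truth *
chi2_nu / nu).  On the log scale this noise has known mean psi(nu/2) -
log(nu/2) (negative: raw log estimates are biased low) and known variance
psi'(nu/2), so after subtracting the bias each individual contributes a
normally distributed observation of its own log-truth with known variance.
A normal-normal hierarchical model then estimates the population mean and
the between-individual log-variance by maximum likelihood, weighting each
individual by 1 / (known within-variance + between-variance): uncertain
individuals are automatically downweighted.  The population mean on the
natural scale is the log-normal back-transform exp(mu + v/2).

Speed estimates are square roots of chi-square scale quantities, so the
bias and variance terms enter with factors 1/2 and 1/4 respectively.

An inverse-Gaussian population law fitted by numerically marginalised ML is
available as an alternative population model for areas/speeds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

from .estimators import ScalarEstimate
from .fitting import FitResult
from .models import ModelKind, PopulationModel

__all__ = [
    "PopulationEstimate",
    "logchi2_bias",
    "logchi2_var",
    "pop_mean",
    "pop_mean_ig",
    "pop_average_model",
]

logger = logging.getLogger(__name__)

_CHI2_1_95 = 3.841458820694124  # 95% quantile of chi-square(1), profile cutoff


@dataclass
class PopulationEstimate:
    """Population mean of a positive quantity with 95% CI."""

    mean: float
    ci_low: float
    ci_high: float
    between_var_log: float
    m: int
    kind: str = ""
    n_failed: int = 0
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.mean <= self.ci_high):
            raise ValueError("CI must bracket the mean")
        if self.m < 1 or self.between_var_log < 0:
            raise ValueError("invalid population estimate")

    def to_row(self) -> dict:
        return {
            "kind": self.kind,
            "m": self.m,
            "mean": self.mean,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "between_var_log": self.between_var_log,
            "n_failed": self.n_failed,
        }


def logchi2_bias(dof: float) -> float:
    """E[log(chi2_nu / nu)] = psi(nu/2) - log(nu/2).

    Negative for all nu, increasing, and -> 0 as nu -> infinity; subtracting
    it debiases log-scale chi-square estimates.
    """
    if dof <= 0:
        raise ValueError("dof must be positive")
    return float(special.digamma(dof / 2.0) - np.log(dof / 2.0))


def logchi2_var(dof: float) -> float:
    """Var[log(chi2_nu)] = psi'(nu/2)."""
    if dof <= 0:
        raise ValueError("dof must be positive")
    return float(special.polygamma(1, dof / 2.0))


def _debiased_logs(estimates: Sequence[ScalarEstimate]) -> tuple[np.ndarray, np.ndarray]:
    """(y, s2): debiased log observations and their known within-variances.

    Area estimates are chi-square scale quantities; speed estimates are
    square roots of one, so their log-noise has half the bias and a quarter
    of the variance.
    """
    y = np.empty(len(estimates))
    s2 = np.empty(len(estimates))
    for i, est in enumerate(estimates):
        if est.value <= 0 or est.dof <= 0:
            raise ValueError("estimates must have positive value and dof")
        scale = 0.5 if est.kind == "speed" else 1.0
        y[i] = np.log(est.value) - scale * logchi2_bias(est.dof)
        s2[i] = scale * scale * logchi2_var(est.dof)
    return y, s2


def _nn_profile_mu(v: float, y: np.ndarray, s2: np.ndarray) -> tuple[float, float]:
    """Profile ML of mu at fixed between-variance v; returns (mu, nll)."""
    w = 1.0 / (s2 + v)
    mu = float(np.sum(w * y) / np.sum(w))
    nll = 0.5 * float(np.sum(np.log(s2 + v) + w * (y - mu) ** 2))
    return mu, nll


def _fit_normal_normal(y: np.ndarray, s2: np.ndarray) -> tuple[float, float, float]:
    """ML fit of y_i ~ N(mu, s2_i + v), v >= 0; returns (mu, v, nll)."""
    spread = max(float(np.var(y)), 1e-12)

    def nll_of(logv: float) -> float:
        return _nn_profile_mu(math.exp(logv), y, s2)[1]

    lo = math.log(spread) - 20.0
    hi = math.log(spread * 100.0 + float(np.max(s2)))
    res = optimize.minimize_scalar(nll_of, bounds=(lo, hi), method="bounded",
                                   options={"xatol": 1e-10})
    v_hat = math.exp(res.x)
    mu_v, nll_v = _nn_profile_mu(v_hat, y, s2)
    mu_0, nll_0 = _nn_profile_mu(0.0, y, s2)
    if nll_0 <= nll_v:  # boundary v = 0 is legitimate (homogeneous population)
        return mu_0, 0.0, nll_0
    return mu_v, v_hat, nll_v


def _profile_mu_ci(
    y: np.ndarray, s2: np.ndarray, mu_hat: float, nll_hat: float
) -> tuple[float, float]:
    """95% profile-likelihood CI for mu (v re-maximised at each mu)."""

    def profile_nll(mu: float) -> float:
        def nll_of(logv: float) -> float:
            v = math.exp(logv)
            w = 1.0 / (s2 + v)
            return 0.5 * float(np.sum(np.log(s2 + v) + w * (y - mu) ** 2))

        spread = max(float(np.var(y)) + float(np.mean(s2)), 1e-12)
        res = optimize.minimize_scalar(
            nll_of,
            bounds=(math.log(spread) - 25.0, math.log(spread * 100.0)),
            method="bounded",
            options={"xatol": 1e-8},
        )
        v0 = 0.5 * float(np.sum(np.log(s2) + (y - mu) ** 2 / s2)) if np.all(s2 > 0) else np.inf
        return min(res.fun, v0)

    def crit(mu: float) -> float:
        return 2.0 * (profile_nll(mu) - nll_hat) - _CHI2_1_95

    # bracket outward from the estimate
    scale = math.sqrt(float(np.mean(s2)) + float(np.var(y)) + 1e-12)
    step = max(scale, 1e-6)
    lo_br = mu_hat - step
    while crit(lo_br) < 0 and lo_br > mu_hat - 50 * step:
        lo_br -= step
    hi_br = mu_hat + step
    while crit(hi_br) < 0 and hi_br < mu_hat + 50 * step:
        hi_br += step
    try:
        lo = optimize.brentq(crit, lo_br, mu_hat, xtol=1e-8)
        hi = optimize.brentq(crit, mu_hat, hi_br, xtol=1e-8)
    except ValueError:  # pathological profile; fall back to Wald-ish bracket
        lo, hi = lo_br, hi_br
    return float(lo), float(hi)


def pop_mean(
    estimates: Sequence[ScalarEstimate], kind: Optional[str] = None
) -> PopulationEstimate:
    """Population mean by the log-chi-square-corrected normal-normal model.

    Failed individual estimates must be excluded upstream; their count can
    be attached by the caller (``n_failed``).  With a single estimate the
    individual's own chi-square CI is returned, flagged as carrying no
    between-individual information.
    """
    estimates = sorted(estimates, key=lambda e: (e.value, e.dof))
    if not estimates:
        raise ValueError("no estimates")
    kinds = {e.kind for e in estimates}
    if len(kinds) > 1:
        raise ValueError(f"mixed estimate kinds {kinds}")
    kind = kind or estimates[0].kind

    if len(estimates) == 1:
        e = estimates[0]
        return PopulationEstimate(
            mean=e.value,
            ci_low=e.ci_low,
            ci_high=e.ci_high,
            between_var_log=0.0,
            m=1,
            kind=kind,
            flags=["no between-individual information"],
        )

    y, s2 = _debiased_logs(estimates)
    mu, v, nll = _fit_normal_normal(y, s2)
    lo_mu, hi_mu = _profile_mu_ci(y, s2, mu, nll)
    half_v = v / 2.0
    return PopulationEstimate(
        mean=float(np.exp(mu + half_v)),
        ci_low=float(np.exp(lo_mu + half_v)),
        ci_high=float(np.exp(hi_mu + half_v)),
        between_var_log=float(v),
        m=len(estimates),
        kind=kind,
    )


# ----------------------------------------------------------------------
# inverse-Gaussian population law


def _ig_logpdf(x: np.ndarray, mean: float, lam: float) -> np.ndarray:
    return (
        0.5 * np.log(lam / (2.0 * np.pi * x**3))
        - lam * (x - mean) ** 2 / (2.0 * mean**2 * x)
    )


def pop_mean_ig(
    estimates: Sequence[ScalarEstimate], n_nodes: int = 64
) -> PopulationEstimate:
    """Population mean under an inverse-Gaussian population distribution.

    The marginal likelihood of each estimate integrates the chi-square
    sampling kernel over the IG population law (Gauss-Legendre on the log
    scale).  Falls back to :func:`pop_mean` with a warning if the optimiser
    fails.  Speed estimates are squared into their chi-square scale for the
    kernel and the resulting mean is mapped back.
    """
    estimates = list(estimates)
    if len(estimates) < 2:
        return pop_mean(estimates)
    kind = estimates[0].kind

    # chi-square-scale values (speed -> squared speed)
    vals = np.array([e.value**2 if kind == "speed" else e.value for e in estimates])
    nus = np.array([e.dof for e in estimates])

    y0, s20 = _debiased_logs(estimates)
    if kind == "speed":  # work on the squared scale
        y0, s20 = 2.0 * y0, 4.0 * s20
    mu0, v0, _ = _fit_normal_normal(y0, s20)

    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)

    def neg_marginal(theta: np.ndarray) -> float:
        log_mean, log_lam = theta
        if not (-200.0 < log_mean < 200.0 and -200.0 < log_lam < 200.0):
            return 1e300
        mean, lam = math.exp(log_mean), math.exp(log_lam)
        pop_sd = math.sqrt(math.log1p(mean / lam)) + 1e-4  # log-scale IG width
        total = 0.0
        with np.errstate(over="ignore", under="ignore", divide="ignore", invalid="ignore"):
            for est, nu in zip(vals, nus):
                # per-individual log-A range covering both the chi-square
                # kernel and the population widths (a narrow population must
                # not fall between quadrature nodes)
                kw = 3.0 / math.sqrt(nu) + 0.3
                la = min(math.log(est) - 2.0 * kw, log_mean - 8.0 * pop_sd)
                lb = max(math.log(est) + 2.0 * kw, log_mean + 8.0 * pop_sd)
                u = 0.5 * (lb - la) * nodes + 0.5 * (la + lb)
                w = 0.5 * (lb - la) * weights
                a = np.exp(u)
                log_pop = _ig_logpdf(a, mean, lam) + u  # + u: dA = A dlogA
                z = est * nu / a  # est | A ~ A chi2_nu / nu
                log_kernel = stats.chi2.logpdf(z, nu) + np.log(nu / a)
                integrand = np.exp(np.clip(log_kernel + log_pop, -745.0, 700.0))
                val = float(np.sum(w * integrand))
                if not np.isfinite(val) or val <= 0:
                    return 1e300
                total -= math.log(val)
        return total

    theta0 = np.array([mu0 + v0 / 2.0, mu0 + v0 / 2.0 - np.log(max(np.expm1(v0), 1e-3))])
    res = optimize.minimize(
        neg_marginal, theta0, method="Nelder-Mead",
        options={"fatol": 1e-7, "xatol": 1e-5, "maxiter": 600},
    )
    if not np.isfinite(res.fun) or res.fun >= 1e299:
        logger.warning("IG population fit failed to converge; falling back")
        out = pop_mean(estimates)
        out.flags.append("IG fit failed; normal-normal fallback")
        return out

    # Wald CI for log mean from the numeric Hessian
    def f(th):
        return neg_marginal(th)

    h = 1e-4
    e0 = np.array([h, 0.0])
    se_logmean = None
    try:
        d2 = (f(res.x + e0) - 2 * res.fun + f(res.x - e0)) / h**2
        if d2 > 0:
            se_logmean = 1.0 / math.sqrt(d2)
    except Exception:  # pragma: no cover - numeric edge
        pass
    floor = math.sqrt((v0 + float(np.mean(s20))) / len(vals)) / 4.0
    if se_logmean is None or not np.isfinite(se_logmean) or se_logmean < floor:
        se_logmean = max(floor, 1e-12)

    mean_cs = math.exp(res.x[0])
    lam = math.exp(res.x[1])
    lo_cs = math.exp(res.x[0] - 1.96 * se_logmean)
    hi_cs = math.exp(res.x[0] + 1.96 * se_logmean)
    if kind == "speed":
        # E[sqrt(A)] for A ~ IG: use sqrt of the mean as the reported scale
        mean_v, lo_v, hi_v = math.sqrt(mean_cs), math.sqrt(lo_cs), math.sqrt(hi_cs)
    else:
        mean_v, lo_v, hi_v = mean_cs, lo_cs, hi_cs
    between = math.log1p(mean_cs / lam)  # log-scale dispersion analogue
    return PopulationEstimate(
        mean=mean_v,
        ci_low=lo_v,
        ci_high=hi_v,
        between_var_log=float(max(between, 0.0)),
        m=len(estimates),
        kind=kind,
        flags=["inverse-Gaussian population model"],
    )


# ----------------------------------------------------------------------
# population-averaged movement model


def pop_average_model(fits: Sequence[FitResult]) -> PopulationModel:
    """Population-averaged movement model from multiple individual fits.

    Each log-parameter (tau_p, tau_v, sigma) is aggregated with the same
    chi-square-corrected normal-normal machinery used for areas, using the
    per-parameter effective DOF nu = 2 / Var(log estimate) from each fit's
    observed information.  Returns the population law (mean_log and diagonal
    between-individual covariance) that seeds population sampling.
    """
    fits = list(fits)
    if len(fits) < 2:
        raise ValueError("need at least 2 fits")
    order = [ModelKind.IID, ModelKind.OU, ModelKind.OUF]
    counts = {k: sum(f.selected_kind is k for f in fits) for k in order}
    majority = [k for k in order if counts[k] >= len(fits) / 2.0]
    kind = majority[-1] if majority else max(counts, key=lambda k: counts[k])
    used = [f for f in fits if f.selected_kind is kind]
    if len(used) < len(fits):
        logger.warning(
            "pop_average_model: excluding %d fits of other kinds than %s",
            len(fits) - len(used), kind.value,
        )
    if len(used) < 2:
        raise ValueError("fewer than 2 fits of the majority kind")

    param_map = {"tau_p": 0, "tau_v": 1, "sigma": 2}
    mean_log = np.array([0.0, 0.0, 0.0])
    cov_log = np.zeros((3, 3))
    for name, idx in param_map.items():
        if name not in used[0].param_names:
            continue
        y = []
        s2 = []
        for f in used:
            val = getattr(f.model, name)
            var = f.var_log(name)
            var = max(var, 1e-8)
            nu = 2.0 / var
            y.append(np.log(val) - logchi2_bias(nu))
            s2.append(logchi2_var(nu))
        mu, v, _ = _fit_normal_normal(np.array(y), np.array(s2))
        mean_log[idx] = mu
        cov_log[idx, idx] = v

    flags = ["low confidence: m = 2"] if len(used) == 2 else []
    pop = PopulationModel(kind, mean_log, cov_log)
    pop.flags = flags  # advisory only
    return pop
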