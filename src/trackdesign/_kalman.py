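"""Numba kernels for the linear-Gaussian state-space machinery.

One univariate axis of an OU or OUF process is a Gaussian Markov state of
dimension 1 (OU: position) or 2 (OUF: position, velocity).  These kernels
implement, per axis:

* the innovations (Kalman) filter with a constant mean regressor, returning
  the sufficient statistics for the exact profile likelihood over the
  home-range center,
* exact state-path simulation,
* the RTS smoother means (used by the conditional-simulation speed
  estimator via the standard "simulate / smooth / correct" trick).

State transitions use the closed-form matrix exponential of the companion
drift (eigenvalues -1/tau_p, -1/tau_v); near-equal timescales switch to the
repeated-root limit for stability.  All kernels are O(n).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_DEGENERATE_RTOL = 1e-6


@njit(cache=True)
def _ouf_phi(a: float, b: float, dt: float) -> np.ndarray:
    """2x2 transition matrix exp(F*dt), F = [[0,1],[-ab,-(a+b)]]."""
    phi = np.empty((2, 2))
    if abs(a - b) < _DEGENERATE_RTOL * min(a, b):
        e = np.exp(-a * dt)
        phi[0, 0] = e * (1.0 + a * dt)
        phi[0, 1] = e * dt
        phi[1, 0] = -e * a * a * dt
        phi[1, 1] = e * (1.0 - a * dt)
    else:
        ea = np.exp(-a * dt)
        eb = np.exp(-b * dt)
        d = b - a
        phi[0, 0] = (b * ea - a * eb) / d
        phi[0, 1] = (ea - eb) / d
        phi[1, 0] = a * b * (eb - ea) / d
        phi[1, 1] = (b * eb - a * ea) / d
    return phi


@njit(cache=True)
def _ouf_phi_q(
    a: float, b: float, sigma: float, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    phi = _ouf_phi(a, b, dt)
    # Q = P_inf - Phi P_inf Phi^T with P_inf = diag(sigma, sigma*a*b)
    p0 = sigma
    p1 = sigma * a * b
    q = np.empty((2, 2))
    q[0, 0] = p0 - (phi[0, 0] * phi[0, 0] * p0 + phi[0, 1] * phi[0, 1] * p1)
    q[0, 1] = -(phi[0, 0] * phi[1, 0] * p0 + phi[0, 1] * phi[1, 1] * p1)
    q[1, 0] = q[0, 1]
    q[1, 1] = p1 - (phi[1, 0] * phi[1, 0] * p0 + phi[1, 1] * phi[1, 1] * p1)
    return phi, q


@njit(cache=True)
def kalman_stats_ou(
    times: np.ndarray, y: np.ndarray, r: np.ndarray, tau_p: float, sigma: float
) -> tuple[float, float, float, float]:
    """Innovations statistics for one axis of an OU process.

    Filters the observations and the constant regressor u == 1 through the
    same (zero-mean) filter.  Returns (sum log S, sum nu^2/S, sum nu*w/S,
    sum w^2/S) with nu the data innovations and w the regressor innovations;
    the profile likelihood over the mean follows in closed form.
    """
    n = len(y)
    logdet = 0.0
    syy = 0.0
    syu = 0.0
    suu = 0.0
    my = 0.0
    mu = 0.0
    p = sigma
    for i in range(n):
        if i > 0:
            dt = times[i] - times[i - 1]
            phi = np.exp(-dt / tau_p)
            q = sigma * (1.0 - phi * phi)
            my = phi * my
            mu = phi * mu
            p = phi * phi * p + q
        s = p + r[i]
        nu = y[i] - my
        w = 1.0 - mu
        logdet += np.log(s)
        syy += nu * nu / s
        syu += nu * w / s
        suu += w * w / s
        k = p / s
        my += k * nu
        mu += k * w
        p -= k * p
    return logdet, syy, syu, suu


@njit(cache=True)
def kalman_stats_ouf(
    times: np.ndarray,
    y: np.ndarray,
    r: np.ndarray,
    tau_p: float,
    tau_v: float,
    sigma: float,
) -> tuple[float, float, float, float]:
    """Innovations statistics for one axis of an OUF process (cf. OU kernel).

    Fully scalar-unrolled 2-state filter: no allocations in the inner loop.
    """
    n = len(y)
    a = 1.0 / tau_p
    b = 1.0 / tau_v
    logdet = 0.0
    syy = 0.0
    syu = 0.0
    suu = 0.0
    my0 = 0.0
    my1 = 0.0
    mu0 = 0.0
    mu1 = 0.0
    p00 = sigma
    p01 = 0.0
    p11 = sigma * a * b
    prev_dt = -1.0
    f00 = 1.0
    f01 = 0.0
    f10 = 0.0
    f11 = 1.0
    q00 = 0.0
    q01 = 0.0
    q11 = 0.0
    for i in range(n):
        if i > 0:
            dt = times[i] - times[i - 1]
            if dt != prev_dt:
                phi, q = _ouf_phi_q(a, b, sigma, dt)
                f00 = phi[0, 0]
                f01 = phi[0, 1]
                f10 = phi[1, 0]
                f11 = phi[1, 1]
                q00 = q[0, 0]
                q01 = q[0, 1]
                q11 = q[1, 1]
                prev_dt = dt
            t0 = f00 * my0 + f01 * my1
            my1 = f10 * my0 + f11 * my1
            my0 = t0
            t0 = f00 * mu0 + f01 * mu1
            mu1 = f10 * mu0 + f11 * mu1
            mu0 = t0
            # P = Phi P Phi^T + Q
            a00 = f00 * p00 + f01 * p01
            a01 = f00 * p01 + f01 * p11
            a10 = f10 * p00 + f11 * p01
            a11 = f10 * p01 + f11 * p11
            p00 = a00 * f00 + a01 * f01 + q00
            p01 = a00 * f10 + a01 * f11 + q01
            p11 = a10 * f10 + a11 * f11 + q11
        s = p00 + r[i]
        nu = y[i] - my0
        w = 1.0 - mu0
        logdet += np.log(s)
        syy += nu * nu / s
        syu += nu * w / s
        suu += w * w / s
        k0 = p00 / s
        k1 = p01 / s
        my0 += k0 * nu
        my1 += k1 * nu
        mu0 += k0 * w
        mu1 += k1 * w
        c00 = p00
        c01 = p01
        p00 -= k0 * c00
        p01 -= k0 * c01
        p11 -= k1 * c01
    return logdet, syy, syu, suu


@njit(cache=True)
def simulate_ouf_axis(
    times: np.ndarray, tau_p: float, tau_v: float, sigma: float, noise: np.ndarray
) -> np.ndarray:
    """Exact stationary draw of the (position, velocity) path for one axis.

    ``noise`` is an (n, 2) array of standard normals (so callers control the
    RNG stream).  Returns an (n, 2) state path.
    """
    n = len(times)
    a = 1.0 / tau_p
    b = 1.0 / tau_v
    out = np.empty((n, 2))
    # stationary draw
    out[0, 0] = np.sqrt(sigma) * noise[0, 0]
    out[0, 1] = np.sqrt(sigma * a * b) * noise[0, 1]
    prev_dt = -1.0
    phi = np.eye(2)
    l00 = 0.0
    l10 = 0.0
    l11 = 0.0
    for i in range(1, n):
        dt = times[i] - times[i - 1]
        if dt != prev_dt:
            phi, q = _ouf_phi_q(a, b, sigma, dt)
            # 2x2 Cholesky with clipping
            q00 = max(q[0, 0], 0.0)
            l00 = np.sqrt(q00)
            l10 = q[1, 0] / l00 if l00 > 0 else 0.0
            l11 = np.sqrt(max(q[1, 1] - l10 * l10, 0.0))
            prev_dt = dt
        x0 = phi[0, 0] * out[i - 1, 0] + phi[0, 1] * out[i - 1, 1]
        x1 = phi[1, 0] * out[i - 1, 0] + phi[1, 1] * out[i - 1, 1]
        out[i, 0] = x0 + l00 * noise[i, 0]
        out[i, 1] = x1 + l10 * noise[i, 0] + l11 * noise[i, 1]
    return out


@njit(cache=True)
def smooth_ouf_axis(
    times: np.ndarray,
    y: np.ndarray,
    r: np.ndarray,
    tau_p: float,
    tau_v: float,
    sigma: float,
) -> np.ndarray:
    """RTS-smoothed state means E[(x, v) | all observations] for one axis.

    Observations are assumed zero-mean (subtract the fitted center first).
    """
    n = len(y)
    a = 1.0 / tau_p
    b = 1.0 / tau_v
    mf = np.empty((n, 2))  # filtered means
    pf = np.empty((n, 2, 2))  # filtered covs
    mp = np.empty((n, 2))  # predicted means
    pp = np.empty((n, 2, 2))  # predicted covs
    phis = np.empty((n, 2, 2))
    m = np.zeros(2)
    p = np.zeros((2, 2))
    p[0, 0] = sigma
    p[1, 1] = sigma * a * b
    prev_dt = -1.0
    phi = np.eye(2)
    q = np.zeros((2, 2))
    for i in range(n):
        if i > 0:
            dt = times[i] - times[i - 1]
            if dt != prev_dt:
                phi, q = _ouf_phi_q(a, b, sigma, dt)
                prev_dt = dt
            m = phi @ m
            p = phi @ p @ phi.T + q
        phis[i] = phi
        mp[i] = m
        pp[i] = p
        s = p[0, 0] + r[i]
        nu = y[i] - m[0]
        k0 = p[0, 0] / s
        k1 = p[1, 0] / s
        m = m.copy()
        m[0] += k0 * nu
        m[1] += k1 * nu
        pnew = p.copy()
        p00 = p[0, 0]
        p01 = p[0, 1]
        pnew[0, 0] = p00 - k0 * p00
        pnew[0, 1] = p01 - k0 * p01
        pnew[1, 0] = pnew[0, 1]
        pnew[1, 1] = p[1, 1] - k1 * p01
        p = pnew
        mf[i] = m
        pf[i] = p
    # backward (means only)
    ms = np.empty((n, 2))
    ms[n - 1] = mf[n - 1]
    for i in range(n - 2, -1, -1):
        # G = Pf_i Phi_{i+1}^T Pp_{i+1}^{-1}
        pp1 = pp[i + 1]
        det = pp1[0, 0] * pp1[1, 1] - pp1[0, 1] * pp1[1, 0]
        if det <= 0:
            ms[i] = mf[i]
            continue
        inv00 = pp1[1, 1] / det
        inv01 = -pp1[0, 1] / det
        inv11 = pp1[0, 0] / det
        cpt = pf[i] @ phis[i + 1].T
        g00 = cpt[0, 0] * inv00 + cpt[0, 1] * inv01
        g01 = cpt[0, 0] * inv01 + cpt[0, 1] * inv11
        g10 = cpt[1, 0] * inv00 + cpt[1, 1] * inv01
        g11 = cpt[1, 0] * inv01 + cpt[1, 1] * inv11
        d0 = ms[i + 1, 0] - mp[i + 1, 0]
        d1 = ms[i + 1, 1] - mp[i + 1, 1]
        ms[i, 0] = mf[i, 0] + g00 * d0 + g01 * d1
        ms[i, 1] = mf[i, 1] + g10 * d0 + g11 * d1
    return ms
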