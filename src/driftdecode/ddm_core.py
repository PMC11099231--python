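"""Drift-diffusion primitives.

The two-boundary Wiener diffusion model describes a decision variable that
starts at ``w = z * a`` between absorbing boundaries at 0 and ``a`` and drifts
with rate ``v`` (unit diffusion coefficient, the standard identifiability
convention).  First passage through the upper boundary maps to one response
category, the lower boundary to the other; the observed response time is the
passage time plus a non-decision offset ``t``.

This module provides the first-passage-time density (dual small-time /
large-time series expansion with adaptive truncation), an Euler–Maruyama
simulator used as data generator and Monte-Carlo oracle, and the summed
log-likelihood of a behavioral trial table.

Units: all model-level times are **seconds**; trial tables carry RT in
milliseconds and are converted at this boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DDMParams",
    "wfpt_density",
    "wfpt_logpdf",
    "simulate_ddm",
    "loglik",
    "prob_upper",
    "mean_decision_time",
]

try:  # optional compiled WFPT kernel; the numpy path is the reference
    import numba as _numba
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _numba = None


@dataclass(frozen=True)
class DDMParams:
    """Four-parameter diffusion model.

    v : drift rate (evidence units / s)
    a : boundary separation (> 0)
    z : relative starting point in (0, 1); absolute start is ``z * a``
    t : non-decision time in seconds (>= 0)
    """

    v: float
    a: float
    z: float = 0.5
    t: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.v):
            raise ValueError(f"drift rate must be finite, got {self.v}")
        if not (self.a > 0 and np.isfinite(self.a)):
            raise ValueError(f"boundary separation must be > 0, got {self.a}")
        if not (0.0 < self.z < 1.0):
            raise ValueError(f"relative start point must be in (0, 1), got {self.z}")
        if not (self.t >= 0 and np.isfinite(self.t)):
            raise ValueError(f"non-decision time must be >= 0, got {self.t}")


def _series_logdensity_numpy(u, v, a, w, err_tol):
    """Log first-passage density at the *lower* boundary for decision time u.

    ``u``, ``v``, ``a`` and ``w`` may be arrays (broadcast to a common
    shape).  Uses the normalized-time formulation: with ``tn = u / a**2``
    the density factorizes into ``exp(-v*a*w - v**2*u/2) / a**2`` times a
    drift-free density f(tn | w), for which a small-time and a large-time
    series are available.  The cheaper expansion is selected per element with
    truncation bounds chosen so the error in f is below ``err_tol``.
    """
    u = np.asarray(u, dtype=float)
    v = np.broadcast_to(np.asarray(v, dtype=float), u.shape).ravel()
    w = np.broadcast_to(np.asarray(w, dtype=float), u.shape).ravel()
    a = np.broadcast_to(np.asarray(a, dtype=float), u.shape).ravel()
    shape = u.shape
    u = u.ravel()

    out = np.full(u.size, -np.inf)
    ok = u > 0
    if not ok.any():
        return out.reshape(shape)

    uu, vv, ww, aa = u[ok], v[ok], w[ok], a[ok]
    tn = uu / aa**2  # normalized time

    # number of terms for the small-time expansion (Navarro-Fuss style bound)
    arg_s = 2.0 * err_tol * np.sqrt(2.0 * np.pi * tn)
    ks = np.where(
        arg_s < 1.0,
        2.0 + np.sqrt(np.maximum(-2.0 * tn * np.log(np.maximum(arg_s, 1e-300)), 0.0)),
        2.0,
    )
    ks = np.maximum(ks, np.sqrt(tn) + 1.0)

    # number of terms for the large-time expansion
    arg_l = np.pi * tn * err_tol
    kl = np.where(
        arg_l < 1.0,
        np.sqrt(np.maximum(-2.0 * np.log(np.maximum(arg_l, 1e-300)), 0.0) / (np.pi**2 * tn)),
        0.0,
    )
    kl = np.maximum(kl, 1.0 / (np.pi * np.sqrt(tn)))

    small = ks < kl
    f = np.zeros(tn.size)

    if small.any():
        t_s, w_s = tn[small], ww[small]
        kmax = int(np.ceil(ks[small].max()))
        acc = np.zeros(t_s.size)
        for k in range(-kmax, kmax + 1):
            wk = w_s + 2.0 * k
            acc += wk * np.exp(-(wk**2) / (2.0 * t_s))
        f[small] = acc / np.sqrt(2.0 * np.pi * t_s**3)

    large = ~small
    if large.any():
        t_l, w_l = tn[large], ww[large]
        kmax = int(np.ceil(kl[large].max()))
        acc = np.zeros(t_l.size)
        for k in range(1, kmax + 1):
            acc += k * np.exp(-(k**2) * np.pi**2 * t_l / 2.0) * np.sin(k * np.pi * w_l)
        f[large] = np.pi * acc

    # truncation can leave tiny negative values in the large-time branch
    f = np.maximum(f, 1e-300)
    logdens = np.log(f) - vv * aa * ww - vv**2 * uu / 2.0 - 2.0 * np.log(aa)
    out[ok] = logdens
    return out.reshape(shape)


if _numba is not None:

    @_numba.njit(cache=True)
    def _series_logdensity_kernel(u, v, a, w, err_tol, out):  # pragma: no cover
        for i in range(u.size):
            ui, vi, ai, wi = u[i], v[i], a[i], w[i]
            if ui <= 0.0:
                out[i] = -np.inf
                continue
            tn = ui / (ai * ai)
            arg_s = 2.0 * err_tol * np.sqrt(2.0 * np.pi * tn)
            if arg_s < 1.0:
                ks = 2.0 + np.sqrt(max(-2.0 * tn * np.log(arg_s), 0.0))
            else:
                ks = 2.0
            root = np.sqrt(tn)
            if ks < root + 1.0:
                ks = root + 1.0
            arg_l = np.pi * tn * err_tol
            if arg_l < 1.0:
                kl = np.sqrt(max(-2.0 * np.log(arg_l), 0.0) / (np.pi * np.pi * tn))
            else:
                kl = 0.0
            kl_min = 1.0 / (np.pi * root)
            if kl < kl_min:
                kl = kl_min
            if ks < kl:
                kmax = int(np.ceil(ks))
                acc = 0.0
                for k in range(-kmax, kmax + 1):
                    wk = wi + 2.0 * k
                    acc += wk * np.exp(-(wk * wk) / (2.0 * tn))
                f = acc / np.sqrt(2.0 * np.pi * tn * tn * tn)
            else:
                kmax = int(np.ceil(kl))
                acc = 0.0
                for k in range(1, kmax + 1):
                    acc += (
                        k
                        * np.exp(-(k * k) * np.pi * np.pi * tn / 2.0)
                        * np.sin(k * np.pi * wi)
                    )
                f = np.pi * acc
            if f < 1e-300:
                f = 1e-300
            out[i] = (
                np.log(f) - vi * ai * wi - vi * vi * ui / 2.0 - 2.0 * np.log(ai)
            )


def _series_logdensity(u, v, a, w, err_tol):
    u = np.asarray(u, dtype=float)
    shape = u.shape
    if _numba is None:
        return _series_logdensity_numpy(u, v, a, w, err_tol)
    uu = np.ascontiguousarray(u, dtype=float).ravel()
    vv = np.ascontiguousarray(np.broadcast_to(np.asarray(v, dtype=float), shape)).ravel()
    aa = np.ascontiguousarray(np.broadcast_to(np.asarray(a, dtype=float), shape)).ravel()
    ww = np.ascontiguousarray(np.broadcast_to(np.asarray(w, dtype=float), shape)).ravel()
    out = np.empty(uu.size)
    _series_logdensity_kernel(uu, vv, aa, ww, err_tol, out)
    return out.reshape(shape)


def wfpt_logpdf(rt, upper, v, a, z, t, err_tol=1e-7):
    """Vectorized log WFPT density for response times ``rt`` (seconds).

    ``upper`` is a boolean array marking upper-boundary responses; ``v`` may
    be scalar or per-trial (stimulus-signed drift).  Entries with
    ``rt <= t`` get ``-inf`` (a response cannot precede the non-decision
    time).
    """
    rt = np.asarray(rt, dtype=float)
    upper = np.broadcast_to(np.asarray(upper, dtype=bool), rt.shape)
    v = np.broadcast_to(np.asarray(v, dtype=float), rt.shape)
    z = np.broadcast_to(np.asarray(z, dtype=float), rt.shape)
    t = np.asarray(t, dtype=float)
    # upper-boundary density equals the lower-boundary density of the
    # reflected process (v -> -v, w -> 1 - w)
    v_eff = np.where(upper, -v, v)
    w_eff = np.where(upper, 1.0 - z, z)
    return _series_logdensity(rt - t, v_eff, a, w_eff, err_tol)


def wfpt_density(rt, boundary, p: DDMParams, err_tol: float = 1e-7):
    """WFPT density at ``rt`` seconds for one boundary ("upper" or "lower").

    Returns 0 for ``rt <= p.t``.  Accepts scalar or array ``rt``.
    """
    if boundary not in ("upper", "lower"):
        raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    rt_arr = np.atleast_1d(np.asarray(rt, dtype=float))
    if np.any(rt_arr < 0):
        raise ValueError("rt must be > 0")
    logd = wfpt_logpdf(rt_arr, boundary == "upper", p.v, p.a, p.z, p.t, err_tol)
    dens = np.exp(logd)
    return float(dens[0]) if np.isscalar(rt) or np.ndim(rt) == 0 else dens


def prob_upper(p: DDMParams) -> float:
    """Closed-form probability of absorption at the upper boundary.

    Gambler's-ruin formula ``(1 - exp(-2 v w)) / (1 - exp(-2 v a))`` with
    ``w = z * a``; the drift-free limit is ``z``.
    """
    w = p.z * p.a
    if abs(p.v) < 1e-9:
        return p.z
    return float(np.expm1(-2.0 * p.v * w) / np.expm1(-2.0 * p.v * p.a))


def mean_decision_time(p: DDMParams) -> float:
    """Closed-form unconditional mean first-passage time (excluding ``t``)."""
    w = p.z * p.a
    if abs(p.v) < 1e-9:
        return float(w * (p.a - w))
    return float(p.a / p.v * prob_upper(p) - w / p.v)


def simulate_ddm(p: DDMParams, n: int, seed: int, dt: float = 1e-4):
    """Euler–Maruyama first-passage simulation.

    Returns ``(rt, upper)``: response times in seconds (including the
    non-decision time ``p.t``) and a boolean upper-boundary indicator, both
    of length ``n``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    sqdt = np.sqrt(dt)
    x = np.full(n, p.z * p.a)
    rt = np.zeros(n)
    upper = np.zeros(n, dtype=bool)
    active = np.arange(n)
    step = 0
    max_steps = int(200.0 / dt)  # hard cap; never reached for sane parameters
    while active.size and step < max_steps:
        step += 1
        x[active] += p.v * dt + sqdt * rng.standard_normal(active.size)
        xa = x[active]
        hit_up = xa >= p.a
        hit_lo = xa <= 0.0
        done = hit_up | hit_lo
        if done.any():
            idx = active[done]
            rt[idx] = step * dt + p.t
            upper[idx] = hit_up[done]
            active = active[~done]
    if active.size:
        # absorb stragglers at the nearer boundary (never hit in practice)
        rt[active] = max_steps * dt + p.t
        upper[active] = x[active] > p.a / 2.0
    return rt, upper


def loglik(trials, p: DDMParams, err_tol: float = 1e-7, sign_by_target: bool = False) -> float:
    """Summed log-likelihood of a behavioral trial table under ``p``.

    Boundary coding: upper = "bird", lower = "dog" (fixed convention).  With
    ``sign_by_target`` the drift is stimulus-signed: ``+v`` on bird-target
    trials and ``-v`` on dog-target trials (requires a ``target`` column);
    ``z`` then measures response bias toward "bird".  Returns ``-inf`` when
    any trial has zero density (e.g. rt below the non-decision time).
    """
    rt_s = trials["rt_ms"].to_numpy(dtype=float) / 1000.0
    if np.any(rt_s <= 0):
        raise ValueError("all rt_ms must be > 0 (apply filter_premature first)")
    upper = (trials["choice"].to_numpy() == "bird")
    if sign_by_target:
        sign = np.where(trials["target"].to_numpy() == "bird", 1.0, -1.0)
        v = p.v * sign
    else:
        v = p.v
    logd = wfpt_logpdf(rt_s, upper, v, p.a, p.z, p.t, err_tol)
    return float(np.sum(logd))
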