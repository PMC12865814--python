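"""Wiener first-passage-time density, trial likelihood, and sampler.

The drift-diffusion process dX = v dt + dW starts at X(0) = z*a between
absorbing boundaries {0, a}.  The first-passage density at the *lower*
boundary is the classic series

    f(t | v, a, z) = (pi / a^2) exp(-v a z - v^2 t / 2)
                     * sum_{k>=1} k exp(-k^2 pi^2 t / (2 a^2)) sin(k pi z),

with z the relative starting point.  The large-time series above
converges slowly for small t, so the evaluation switches to the
equivalent small-time (image-charge) expansion whenever that needs fewer
terms; the number of terms is chosen adaptively for a truncation error
below ``err`` on the time-scaled density.  The density at the upper
boundary follows from the reflection (v, z) -> (-v, 1 - z).

A trial's likelihood is the density of its decision time rt - tau at the
observed boundary, with tau the non-decision time.  The starting point is
fixed at z = 0.5 throughout (no initial response bias).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

DEFAULT_Z = 0.5
SERIES_ERR = 1e-10
LIKELIHOOD_FLOOR = 1e-10


@dataclass(frozen=True)
class DDMParams:
    """Drift-diffusion parameters for one run.

    ``a`` is the boundary separation (evidence units), ``tau`` the
    non-decision time (s), ``z`` the relative starting point (fixed at
    0.5, never fitted).  The drift rate varies trial by trial and is
    supplied separately.
    """

    a: float
    tau: float
    z: float = DEFAULT_Z

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and self.a > 0):
            raise ValueError(f"boundary separation a must be > 0, got {self.a}")
        if not (np.isfinite(self.tau) and self.tau >= 0):
            raise ValueError(f"non-decision time tau must be >= 0, got {self.tau}")
        if not 0 < self.z < 1:
            raise ValueError(f"relative start point z must lie in (0, 1), got {self.z}")


@njit(cache=True)
def _fpt_density_scaled(tt: float, w: float, err: float) -> float:
    """Lower-boundary density of the unit process (a=1, v=0) at scaled time tt."""
    if tt <= 0.0:
        return 0.0
    # required terms, large-time expansion
    if math.pi * tt * err < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * tt * err) / (math.pi**2 * tt))
        kl = max(kl, 1.0 / (math.pi * math.sqrt(tt)))
    else:
        kl = 1.0 / (math.pi * math.sqrt(tt))
    # required terms, small-time expansion
    if 2.0 * math.sqrt(2.0 * math.pi * tt) * err < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * tt * math.log(2.0 * math.sqrt(2.0 * math.pi * tt) * err))
        ks = max(ks, math.sqrt(tt) + 1.0)
    else:
        ks = 2.0
    p = 0.0
    if ks < kl:  # small-time expansion needs fewer terms
        K = int(math.ceil(ks))
        for k in range(-((K - 1) // 2), ((K - 1) // 2) + (K - 1) % 2 + 1):
            x = w + 2.0 * k
            p += x * math.exp(-x * x / (2.0 * tt))
        p /= math.sqrt(2.0 * math.pi * tt**3)
    else:
        K = int(math.ceil(kl))
        for k in range(1, K + 1):
            p += k * math.exp(-(k**2) * math.pi**2 * tt / 2.0) * math.sin(k * math.pi * w)
        p *= math.pi
    return max(p, 0.0)


@njit(cache=True)
def _wfpt(t: float, v: float, a: float, w: float, err: float) -> float:
    """Lower-boundary first-passage density at decision time t."""
    tt = t / (a * a)
    g = _fpt_density_scaled(tt, w, err) / (a * a)
    return g * math.exp(-v * a * w - v * v * t / 2.0)


def wfpt_density(t, v: float, a: float, z: float = DEFAULT_Z, err: float = SERIES_ERR):
    """First-passage density at the lower boundary (1/s).

    ``t`` is the decision time (after non-decision time), scalar or array;
    all entries must be positive.  The upper-boundary density is
    ``wfpt_density(t, -v, a, 1 - z)``.
    """
    for name, val in (("v", v), ("a", a), ("z", z)):
        if not np.isfinite(val):
            raise ValueError(f"{name} must be finite, got {val}")
    if a <= 0 or not 0 < z < 1:
        raise ValueError(f"invalid parameters a={a}, z={z}")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise ValueError("decision time t must be > 0")
    if t_arr.ndim == 0:
        return _wfpt(float(t_arr), v, a, z, err)
    out = np.empty(t_arr.shape)
    flat = t_arr.ravel()
    oflat = out.ravel()
    for i in range(flat.size):
        oflat[i] = _wfpt(flat[i], v, a, z, err)
    return out


def response_likelihood(
    rt: float,
    choice,
    v: float,
    a: float,
    tau: float,
    z: float = DEFAULT_Z,
    floor: float = LIKELIHOOD_FLOOR,
) -> float:
    """Likelihood density of observing (rt, choice) under the DDM.

    ``choice`` is 1/"upper" for the upper boundary and 0/"lower" for the
    lower one.  Responses at or before the non-decision time (rt <= tau)
    and numerically underflowing densities return ``floor`` so the
    log-likelihood stays finite.
    """
    upper = choice in (1, "upper")
    if not upper and choice not in (0, "lower"):
        raise ValueError(f"choice must be 0/1 or 'lower'/'upper', got {choice!r}")
    t = rt - tau
    if t <= 0:
        return floor
    if upper:
        dens = _wfpt(t, -v, a, 1.0 - z, SERIES_ERR)
    else:
        dens = _wfpt(t, v, a, z, SERIES_ERR)
    return max(dens, floor)


@njit(cache=True)
def _em_first_passage(
    v: float, a: float, z: float, dt: float, t_max: float
) -> tuple[float, int]:
    """One Euler-Maruyama path; returns (passage time, boundary 1=upper/0=lower).

    Boundary -1 with t_max signals no absorption before t_max.
    Consumes numba's global RNG state (seed with np.random.seed first).
    """
    x = z * a
    sq = math.sqrt(dt)
    t = 0.0
    while t < t_max:
        x += v * dt + sq * np.random.normal()
        t += dt
        if x >= a:
            return t, 1
        if x <= 0.0:
            return t, 0
    return t_max, -1


@njit(cache=True)
def _em_batch(
    vs: np.ndarray, a: float, z: float, dt: float, t_max: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Independent first-passage draws, one per drift in ``vs``."""
    np.random.seed(seed)
    n = vs.size
    times = np.empty(n)
    bounds = np.empty(n, dtype=np.int64)
    for i in range(n):
        t, b = _em_first_passage(vs[i], a, z, dt, t_max)
        times[i] = t
        bounds[i] = b
    return times, bounds


def sample_first_passage(
    v: float,
    a: float,
    tau: float,
    z: float = DEFAULT_Z,
    seed: int = 0,
    dt: float = 1e-4,
    t_max: float = 30.0,
) -> tuple[float, int]:
    """Draw one (rt, boundary) pair by Euler-Maruyama simulation.

    Returns rt = first-passage time + tau and the boundary hit (1 upper,
    0 lower, -1 if the path was still unabsorbed at ``t_max``).
    """
    DDMParams(a=a, tau=tau, z=z)
    times, bounds = _em_batch(np.array([v], dtype=float), a, z, dt, t_max, seed)
    return float(times[0] + tau), int(bounds[0])


def sample_first_passage_batch(
    v: float,
    a: float,
    n: int,
    z: float = DEFAULT_Z,
    seed: int = 0,
    dt: float = 1e-4,
    t_max: float = 30.0,
) -> tuple[np.ndarray, np.ndarray]:
    """``n`` independent first-passage draws at a common drift (no tau offset)."""
    vs = np.full(n, float(v))
    return _em_batch(vs, a, z, dt, t_max, seed)
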