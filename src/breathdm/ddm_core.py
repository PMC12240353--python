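"""Wiener diffusion process: first-passage density, simulator and
respiratory-state parameter modulation.

The decision model is the four-parameter drift-diffusion model (DDM): evidence
accumulates from a starting point ``z * a`` (``z`` a fraction of the boundary
separation ``a``) with drift ``v`` and unit diffusion coefficient until it is
absorbed at 0 (lower boundary) or ``a`` (upper boundary); the response time is
the absorption time plus a non-decision time ``t``.  Under stimulus coding the
upper boundary is the "up" / "happy" response and each stimulus class carries
its own drift rate.

Respiratory state enters as additive group-level deltas on every parameter:
expiration is the reference state, inspiration applies
``theta + delta_theta``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = [
    "DDMParameters",
    "RespiratoryDeltas",
    "StimulusCoding",
    "RDM_CODING",
    "FAD_CODING",
    "wiener_fpt_density",
    "absorption_probability",
    "simulate_ddm",
    "apply_state_modulation",
    "trial_loglik",
]

# Parameter support used for validation (also the flat-prior bounds used by
# the hierarchical fit; see hier_fit).
A_MIN, A_MAX = 0.05, 5.0
Z_MIN, Z_MAX = 0.02, 0.98
T_MIN, T_MAX = 0.0, 1.0
V_ABS_MAX = 10.0


@dataclass(frozen=True)
class DDMParameters:
    """Base (expiration-state) decision parameters.

    ``v`` maps stimulus class -> signed drift rate (evidence units / s,
    positive toward the upper boundary); ``a`` is the boundary separation,
    ``z`` the relative starting point in (0, 1) and ``t`` the non-decision
    time in seconds.  Diffusion coefficient is fixed at 1, so all magnitudes
    are on that scale.
    """

    v: dict[str, float]
    a: float
    z: float
    t: float

    def __post_init__(self) -> None:
        if not self.v:
            raise ValueError("at least one stimulus class drift is required")
        for cls, vv in self.v.items():
            if not math.isfinite(vv):
                raise ValueError(f"drift for class {cls!r} is not finite")
        if not (self.a > 0 and math.isfinite(self.a)):
            raise ValueError("boundary separation a must be positive and finite")
        if not (0.0 < self.z < 1.0):
            raise ValueError("relative starting point z must lie in (0, 1)")
        if not (self.t >= 0 and math.isfinite(self.t)):
            raise ValueError("non-decision time t must be >= 0")


@dataclass(frozen=True)
class RespiratoryDeltas:
    """Inspiration-minus-expiration differences, additive on the natural
    scale of each parameter (``dz`` on the fraction scale of ``z``)."""

    dv: dict[str, float] = field(default_factory=dict)
    da: float = 0.0
    dz: float = 0.0
    dt: float = 0.0

    @classmethod
    def zeros(cls, classes: tuple[str, ...] | list[str]) -> "RespiratoryDeltas":
        return cls(dv={c: 0.0 for c in classes})


@dataclass(frozen=True)
class StimulusCoding:
    """Bijective map between absorbing boundaries and response categories."""

    upper: str
    lower: str

    def __post_init__(self) -> None:
        if self.upper == self.lower:
            raise ValueError("boundary coding must be bijective")

    def boundary_of(self, response: str) -> str:
        if response == self.upper:
            return "upper"
        if response == self.lower:
            return "lower"
        raise ValueError(f"response {response!r} not in coding")


RDM_CODING = StimulusCoding(upper="up", lower="down")
FAD_CODING = StimulusCoding(upper="happy", lower="angry")


# ---------------------------------------------------------------------------
# First-passage-time density (small-time / large-time series expansions)
# ---------------------------------------------------------------------------

def _fpt_lower_norm(u: np.ndarray, w: float, err: float) -> np.ndarray:
    """Density of first passage through the lower boundary for a zero-drift
    unit-diffusion process on (0, 1) started at ``w``, at normalised time
    ``u`` (time / a^2).  Series truncation chosen so the absolute error is
    below ``err``; the small- or large-time expansion is selected per element
    by comparing the number of terms each needs.
    """
    u = np.asarray(u, dtype=float)
    out = np.zeros_like(u)
    pos = u > 0
    if not np.any(pos):
        return out
    up = u[pos]

    # terms needed by each expansion (Navarro & Fuss style bounds)
    with np.errstate(divide="ignore", invalid="ignore"):
        ks = 2.0 + np.sqrt(np.maximum(-2.0 * up * np.log(2.0 * err * np.sqrt(2.0 * np.pi * up)), 0.0))
        ks = np.where(2.0 * err * np.sqrt(2.0 * np.pi * up) < 1.0, ks, 2.0)
        ks = np.maximum(ks, np.sqrt(up) + 1.0)
        kl = np.sqrt(np.maximum(-2.0 * np.log(np.pi * up * err) / (np.pi**2 * up), 0.0))
        kl = np.where(np.pi * up * err < 1.0, np.maximum(kl, 1.0 / (np.pi * np.sqrt(up))), 1.0 / (np.pi * np.sqrt(up)))

    small = ks < kl
    f = np.empty_like(up)

    if np.any(small):
        us = up[small]
        K = int(np.ceil(ks[small].max()))
        ks_half = (K - 1) // 2 + 1
        k = np.arange(-ks_half, ks_half + 1)
        terms = (w + 2.0 * k[None, :]) * np.exp(-((w + 2.0 * k[None, :]) ** 2) / (2.0 * us[:, None]))
        f[small] = terms.sum(axis=1) / np.sqrt(2.0 * np.pi * us**3)
    if np.any(~small):
        ul = up[~small]
        K = int(np.ceil(kl[~small].max()))
        k = np.arange(1, K + 1)
        terms = k[None, :] * np.exp(-(k[None, :] ** 2) * np.pi**2 * ul[:, None] / 2.0) * np.sin(k[None, :] * np.pi * w)
        f[~small] = np.pi * terms.sum(axis=1)

    out[pos] = np.maximum(f, 0.0)
    return out


def wiener_fpt_density(
    rt_s: float | np.ndarray,
    boundary: str,
    v: float,
    a: float,
    z: float,
    t: float,
    err: float = 1e-9,
) -> float | np.ndarray:
    """First-passage density (1/s) of absorbing at ``boundary`` at time
    ``rt_s``, for drift ``v``, separation ``a``, relative start ``z`` and
    non-decision time ``t``.  ``rt_s <= t`` gives density 0.

    The upper-boundary density is the lower-boundary form under the
    reflection ``v -> -v``, ``z -> 1 - z``.
    """
    if boundary not in ("upper", "lower"):
        raise ValueError("boundary must be 'upper' or 'lower'")
    _validate_scalar_params(v, a, z, t)
    rt = np.asarray(rt_s, dtype=float)
    scalar = rt.ndim == 0
    rt = np.atleast_1d(rt)

    if boundary == "upper":
        v_eff, w = -v, 1.0 - z
    else:
        v_eff, w = v, z

    tau = rt - t
    u = np.where(tau > 0, tau / a**2, 0.0)
    f = _fpt_lower_norm(u, w, err)
    with np.errstate(over="ignore"):
        dens = np.where(
            tau > 0,
            f / a**2 * np.exp(-v_eff * a * w - v_eff**2 * np.maximum(tau, 0.0) / 2.0),
            0.0,
        )
    return float(dens[0]) if scalar else dens


def _validate_scalar_params(v: float, a: float, z: float, t: float) -> None:
    if not (math.isfinite(v) and a > 0 and 0.0 < z < 1.0 and t >= 0):
        raise ValueError(f"invalid DDM parameters: v={v}, a={a}, z={z}, t={t}")


def absorption_probability(v: float, a: float, z: float) -> float:
    """Probability of absorbing at the upper boundary.

    For drift ``v != 0``, unit diffusion and boundaries {0, a} with start
    ``z * a``, this is ``(1 - exp(-2 v a z)) / (1 - exp(-2 v a))``; in the
    zero-drift limit it is ``z``.  Verified against brute-force path
    simulation in the test suite.
    """
    _validate_scalar_params(v, a, z, 0.0)
    x = 2.0 * v * a
    if abs(x) < 1e-10:
        return float(z)
    return float(math.expm1(-x * z) / math.expm1(-x))


@njit(fastmath=False)
def _logdens_lower_scalar(tau, w, v, a, err):  # pragma: no cover - numba
    """Log first-passage density at the lower boundary, scalar kernel.

    Same small/large-time switch as the vectorised density; used by the
    hierarchical sampler where per-call numpy overhead would dominate.
    """
    u = tau / (a * a)
    # series lengths
    tmp = 2.0 * err * math.sqrt(2.0 * math.pi * u)
    if tmp < 1.0:
        ks = 2.0 + math.sqrt(max(-2.0 * u * math.log(tmp), 0.0))
    else:
        ks = 2.0
    if ks < math.sqrt(u) + 1.0:
        ks = math.sqrt(u) + 1.0
    if math.pi * u * err < 1.0:
        kl = math.sqrt(max(-2.0 * math.log(math.pi * u * err) / (math.pi * math.pi * u), 0.0))
        if kl < 1.0 / (math.pi * math.sqrt(u)):
            kl = 1.0 / (math.pi * math.sqrt(u))
    else:
        kl = 1.0 / (math.pi * math.sqrt(u))

    f = 0.0
    if ks < kl:
        K = int(math.ceil(ks))
        half = (K - 1) // 2 + 1
        for k in range(-half, half + 1):
            wk = w + 2.0 * k
            f += wk * math.exp(-wk * wk / (2.0 * u))
        f /= math.sqrt(2.0 * math.pi * u * u * u)
    else:
        K = int(math.ceil(kl))
        for k in range(1, K + 1):
            f += k * math.exp(-k * k * math.pi * math.pi * u / 2.0) * math.sin(k * math.pi * w)
        f *= math.pi
    if f <= 0.0:
        return -np.inf
    return math.log(f) - 2.0 * math.log(a) - v * a * w - v * v * tau / 2.0


@njit(fastmath=False)
def wfpt_sum_loglik(rt, upper, v, a, z, t, err=1e-9):  # pragma: no cover - numba
    """Summed log-likelihood of trials sharing one parameter set.

    ``rt`` in seconds; ``upper`` a boolean array marking upper-boundary
    responses.  Any trial with ``rt <= t`` (or an invalid parameter set)
    makes the whole sum ``-inf``.
    """
    if not (a > 0.0 and 0.0 < z < 1.0 and t >= 0.0 and math.isfinite(v)):
        return -np.inf
    s = 0.0
    for i in range(rt.shape[0]):
        tau = rt[i] - t
        if tau <= 0.0:
            return -np.inf
        if upper[i]:
            ld = _logdens_lower_scalar(tau, 1.0 - z, -v, a, err)
        else:
            ld = _logdens_lower_scalar(tau, z, v, a, err)
        if not math.isfinite(ld):
            return -np.inf
        s += ld
    return s


# ---------------------------------------------------------------------------
# Simulator (Euler-Maruyama)
# ---------------------------------------------------------------------------

def _simulate_paths(v, a, z, n, dt, t_cap, seed):
    """Vectorised Euler-Maruyama over all still-active paths per step."""
    rng = np.random.default_rng(seed)
    sqdt = math.sqrt(dt)
    choices = np.full(n, -1, dtype=np.int8)
    rts = np.full(n, np.nan)
    max_steps = int(t_cap / dt)
    x = np.full(n, z * a)
    idx = np.arange(n)
    for step in range(1, max_steps + 1):
        x += v * dt + sqdt * rng.standard_normal(x.size)
        up = x >= a
        lo = x <= 0.0
        done = up | lo
        if np.any(done):
            hit = idx[done]
            choices[hit] = up[done].astype(np.int8)
            rts[hit] = step * dt
            keep = ~done
            x = x[keep]
            idx = idx[keep]
            if idx.size == 0:
                break
    return choices, rts


def simulate_ddm(
    v: float,
    a: float,
    z: float,
    t: float,
    n: int,
    dt: float = 1e-3,
    seed: int = 0,
    t_cap: float = 20.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate ``n`` diffusion trials by Euler-Maruyama at step ``dt``.

    Returns ``(choices, rts)`` where choice 1 means upper-boundary absorption,
    0 lower, and -1 a path censored at ``t_cap`` seconds (its RT is NaN).
    RTs include the non-decision time ``t``.
    """
    _validate_scalar_params(v, a, z, t)
    if n < 1:
        raise ValueError("n must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be positive")
    choices, dec_times = _simulate_paths(float(v), float(a), float(z), int(n), float(dt), float(t_cap), int(seed) & 0x7FFFFFFF)
    rts = dec_times + t
    return choices, rts


# ---------------------------------------------------------------------------
# Respiratory-state modulation and trial likelihood
# ---------------------------------------------------------------------------

def apply_state_modulation(
    base: DDMParameters, deltas: RespiratoryDeltas, state: str
) -> DDMParameters:
    """Effective parameters in a respiratory state.

    Expiration is the reference: the base parameters are returned unchanged.
    Inspiration adds each delta to its parameter; the result is validated and
    an out-of-range parameter raises with its name.
    """
    if state == "expiration":
        return base
    if state != "inspiration":
        raise ValueError(f"unknown respiratory state {state!r}")
    v = {c: base.v[c] + deltas.dv.get(c, 0.0) for c in base.v}
    a = base.a + deltas.da
    z = base.z + deltas.dz
    t = base.t + deltas.dt
    if a <= 0:
        raise ValueError(f"modulated boundary separation a={a} out of range")
    if not (0.0 < z < 1.0):
        raise ValueError(f"modulated starting point z={z} out of range")
    if t < 0:
        raise ValueError(f"modulated non-decision time t={t} out of range")
    return replace(base, v=v, a=a, z=z, t=t)


def trial_loglik(
    trial,
    base: DDMParameters,
    deltas: RespiratoryDeltas,
    coding: StimulusCoding,
) -> float:
    """Log first-passage density of one trial.

    ``trial`` is any mapping/namespace with ``stimulus_class``, ``choice``
    (a response-category string), ``rt_s`` and ``state``
    ('inspiration'/'expiration').  RT at or below the effective non-decision
    time gives ``-inf``.
    """
    get = trial.get if hasattr(trial, "get") else lambda k: getattr(trial, k)
    state = get("state")
    if state not in ("inspiration", "expiration"):
        raise ValueError(f"trial respiratory state {state!r} cannot be used in the likelihood")
    eff = apply_state_modulation(base, deltas, state)
    boundary = coding.boundary_of(get("choice"))
    dens = wiener_fpt_density(get("rt_s"), boundary, eff.v[get("stimulus_class")], eff.a, eff.z, eff.t)
    if dens <= 0:
        return -np.inf
    return float(np.log(dens))
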