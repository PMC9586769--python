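"""The deterministic Hawkes drug-effect model.

The monitored variable's conditional intensity is

    lambda(t) = mu(t) + sum_{t_i < t} gamma(t - t_i, d_i),

with a sinusoidal baseline

    mu(t) = a0 + b0 * sin(alpha0 * t + beta0),      mu(t) > 0,

and an excitation kernel that multiplies a dose sigmoid by a Gamma-shaped
lag profile,

    gamma(u, d) = [1 / (a1 + b1 * exp(-kappa1 * (m1 + d) * a2))]
                  * u^(kappa2-1) * exp(-b2 * u) / (b2^kappa2 * Gamma(kappa2)).

The sigmoid encodes a saturating dose response (extra dose beyond saturation
adds little effect); the Gamma factor encodes the lag between administration
and effect — zero at lag 0 for kappa2 > 1, a rise to a peak at
(kappa2 - 1) / b2 minutes, then exponential decay.

Note the Gamma factor above is written with a scale-style divisor
``b2^kappa2`` but a rate-style decay ``exp(-b2 u)``, so it is not a unit-mass
density in either parameterization; its mass is ``b2^(-2 kappa2)``.  That
form is the package default for fidelity to the model as published.  Passing
``normalized=True`` substitutes the proper rate-parameterized Gamma density
``b2^kappa2 u^(kappa2-1) exp(-b2 u) / Gamma(kappa2)`` (unit mass), which
keeps the excitation on the scale of the monitored variable and is the
convention the simulation-study helpers use (see docs/methods.md).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.special import gammaln

from .events import EventSchedule

__all__ = [
    "BaselineParams",
    "KernelParams",
    "HawkesParams",
    "PARAM_ORDER",
    "TRUE_PARAMS",
    "PARAM_RANGES",
    "baseline_mu",
    "dose_response",
    "excitation_kernel",
    "intensity",
    "cumulative_effect_curve",
]

#: Canonical flattening order for parameter-vector I/O.
PARAM_ORDER = ("a0", "b0", "alpha0", "beta0", "a1", "b1", "kappa1", "m1", "a2", "kappa2", "b2")


@dataclass(frozen=True)
class BaselineParams:
    """Sinusoidal baseline: level a0, amplitude b0, angular frequency alpha0
    (radians/minute), phase beta0 (radians)."""

    a0: float
    b0: float
    alpha0: float
    beta0: float

    def __post_init__(self) -> None:
        if not (self.alpha0 > 0):
            raise ValueError("alpha0 must be > 0 (zero frequency degenerates the sinusoid)")


@dataclass(frozen=True)
class KernelParams:
    """Excitation-kernel parameters.

    a1 > 0 and b1 >= 0 keep the sigmoid denominator positive; kappa1 is the
    sigmoid steepness per dose unit, m1 a dose offset, a2 a dose scaling.
    kappa2 > 1 (Gamma shape) makes the kernel zero at lag 0 and unimodal;
    b2 > 0 is the Gamma rate.
    """

    a1: float
    b1: float
    kappa1: float
    m1: float
    a2: float
    kappa2: float
    b2: float

    def __post_init__(self) -> None:
        if not (self.a1 > 0):
            raise ValueError("a1 must be > 0")
        if self.b1 < 0:
            raise ValueError("b1 must be >= 0")
        if not (self.kappa2 > 1):
            raise ValueError("kappa2 must be > 1 (kernel rises from zero, then decays)")
        if not (self.b2 > 0):
            raise ValueError("b2 must be > 0")


@dataclass(frozen=True)
class HawkesParams:
    """The full 11-parameter vector theta = baseline + kernel."""

    baseline: BaselineParams
    kernel: KernelParams

    def to_vector(self) -> np.ndarray:
        d = {**asdict(self.baseline), **asdict(self.kernel)}
        return np.array([d[name] for name in PARAM_ORDER], dtype=float)

    @classmethod
    def from_vector(cls, vec) -> "HawkesParams":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (len(PARAM_ORDER),):
            raise ValueError(f"expected a length-{len(PARAM_ORDER)} vector")
        d = dict(zip(PARAM_ORDER, vec))
        return cls(
            BaselineParams(d["a0"], d["b0"], d["alpha0"], d["beta0"]),
            KernelParams(d["a1"], d["b1"], d["kappa1"], d["m1"], d["a2"], d["kappa2"], d["b2"]),
        )

    def to_dict(self) -> dict:
        return {**asdict(self.baseline), **asdict(self.kernel)}

    @classmethod
    def from_dict(cls, d: dict) -> "HawkesParams":
        return cls.from_vector([d[name] for name in PARAM_ORDER])

    def replace(self, **kwargs) -> "HawkesParams":
        """A copy with the named parameters substituted."""
        d = self.to_dict()
        for name, value in kwargs.items():
            if name not in d:
                raise KeyError(name)
            d[name] = value
        return HawkesParams.from_dict(d)


#: The simulation study's true parameter vector.
TRUE_PARAMS = HawkesParams(
    BaselineParams(a0=70.0, b0=5.0, alpha0=1.0, beta0=2.0),
    KernelParams(a1=1.0, b1=1.0, kappa1=0.3, m1=-20.0, a2=3.0, kappa2=5.0, b2=0.4),
)

#: Admissible box per parameter (the default fitting bounds).
PARAM_RANGES: dict[str, tuple[float, float]] = {
    "a0": (1.0, 100.0),
    "b0": (0.1, 10.0),
    "alpha0": (0.1, 10.0),
    "beta0": (0.1, 10.0),
    "a1": (0.1, 50.0),
    "b1": (0.01, 10.0),
    "kappa1": (0.01, 1.0),
    "m1": (-100.0, 98.0),
    "a2": (0.01, 10.0),
    "kappa2": (2.1, 22.0),
    "b2": (0.01, 2.0),
}


def baseline_mu(t, p: BaselineParams, strict: bool = False):
    """Evaluate mu(t) = a0 + b0 sin(alpha0 t + beta0).

    The model requires mu > 0; because admissible boxes allow violating
    parameter combinations (e.g. a0=1, b0=10), positivity is checked at
    evaluation: ``strict=True`` raises, otherwise a warning is emitted once
    per call when any value is non-positive.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("t must be finite")
    mu = p.a0 + p.b0 * np.sin(p.alpha0 * t + p.beta0)
    if np.any(mu <= 0):
        if strict:
            raise ValueError("baseline mu(t) <= 0 for some t; the model requires mu > 0")
        warnings.warn("baseline mu(t) <= 0 for some t", RuntimeWarning, stacklevel=2)
    return mu


def dose_response(dose, p: KernelParams):
    """The sigmoid factor 1 / (a1 + b1 exp(-kappa1 (m1 + dose) a2)).

    Non-decreasing in dose when kappa1 * a2 > 0, bounded in (0, 1/a1].
    """
    dose = np.asarray(dose, dtype=float)
    return 1.0 / (p.a1 + p.b1 * np.exp(-p.kappa1 * (p.m1 + dose) * p.a2))


def _log_gamma_factor(lag, p: KernelParams, normalized: bool):
    # log of lag^(k2-1) e^(-b2 lag) / (b2^k2 Gamma(k2)); log-space guards
    # against overflow of b2^kappa2 * Gamma(kappa2) at large kappa2.
    out = (p.kappa2 - 1.0) * np.log(lag) - p.b2 * lag - gammaln(p.kappa2)
    if normalized:
        out += p.kappa2 * np.log(p.b2)
    else:
        out -= p.kappa2 * np.log(p.b2)
    return out


def excitation_kernel(lag, dose, p: KernelParams, normalized: bool = False):
    """gamma(lag, dose): the dose sigmoid times the Gamma lag profile.

    ``lag`` must be >= 0 (the kernel is causal); the value is 0 at lag 0
    because kappa2 > 1, and decays to 0 as lag grows.  See the module
    docstring for the ``normalized`` switch.
    """
    lag = np.asarray(lag, dtype=float)
    if np.any(lag < 0):
        raise ValueError("lag must be >= 0 (the kernel is causal)")
    out = np.zeros(np.broadcast_shapes(lag.shape, np.shape(np.asarray(dose, float))))
    pos = np.broadcast_to(lag > 0, out.shape)
    lag_b = np.broadcast_to(lag, out.shape)
    sig = np.broadcast_to(dose_response(dose, p), out.shape)
    with np.errstate(over="ignore"):
        out[pos] = sig[pos] * np.exp(_log_gamma_factor(lag_b[pos], p, normalized))
    if out.ndim == 0 or (np.isscalar(lag) and np.isscalar(dose)):
        return float(out) if out.ndim == 0 else out
    return out


def _excitation_sum(t, schedule: EventSchedule, p: KernelParams, normalized: bool):
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if len(schedule) == 0:
        return np.zeros_like(t)
    lags = t[:, None] - schedule.times[None, :]
    out = np.zeros_like(lags)
    pos = lags > 0  # strictly earlier events only (t_i < t)
    sig = np.broadcast_to(dose_response(schedule.doses, p)[None, :], lags.shape)
    with np.errstate(over="ignore"):
        out[pos] = sig[pos] * np.exp(_log_gamma_factor(lags[pos], p, normalized))
    return out.sum(axis=1)


def intensity(
    t,
    schedule: EventSchedule,
    p: HawkesParams,
    normalized: bool = False,
    strict: bool = False,
):
    """lambda(t) = mu(t) + sum over events with t_i < t of gamma(t - t_i, d_i).

    With an empty schedule this is exactly the baseline.  Events at t_i >= t
    contribute nothing (causality); events at t_i == t would contribute zero
    anyway since the kernel vanishes at lag 0.
    """
    t_arr = np.asarray(t, dtype=float)
    lam = baseline_mu(t_arr, p.baseline, strict=strict) + _excitation_sum(
        t_arr, schedule, p.kernel, normalized
    ).reshape(t_arr.shape)
    return float(lam) if np.isscalar(t) or t_arr.ndim == 0 else lam


def cumulative_effect_curve(
    grid,
    schedule: EventSchedule,
    p: KernelParams,
    normalized: bool = False,
):
    """The summed drug effect on a time grid, plus per-event component curves.

    Returns ``(total, components)`` where ``components`` has one row per
    event and ``total`` is their pointwise sum (the intensity minus the
    baseline).  With no events both are zero.
    """
    grid = np.asarray(grid, dtype=float)
    if len(schedule) == 0:
        return np.zeros_like(grid), np.zeros((0, len(grid)))
    lags = grid[None, :] - schedule.times[:, None]
    components = np.zeros_like(lags)
    pos = lags > 0
    sig = np.broadcast_to(dose_response(schedule.doses, p)[:, None], lags.shape)
    with np.errstate(over="ignore"):
        components[pos] = sig[pos] * np.exp(_log_gamma_factor(lags[pos], p, normalized))
    return components.sum(axis=0), components
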