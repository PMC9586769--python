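"""Synthetic-series generation: the simulation-study engine and fixtures.

A clean series is the model intensity evaluated on the uniform grid
(``mode="level"``, the default) or the running sum of per-step intensity
increments (``mode="increment"``, for the reading in which the intensity
models the series' first difference).  Observation noise is additive i.i.d.
Gaussian with a chosen variance; the latent intensity is deterministic given
the event schedule.

The study conditions emulate the motivating ICU data set: roughly 800
one-minute samples of a heart-rate-scale variable (baseline about 70-80)
with about 60 constant-dose-25 drug administrations.  The study helpers use
unit-mass (``normalized=True``) excitation kernels so that the drug effect
stays on the monitored variable's scale; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .events import EventSchedule, MonitoredSeries, generate_event_schedule
from .model import TRUE_PARAMS, HawkesParams, intensity

__all__ = ["SimulationConfig", "simulate_series", "make_icu_like_fixture"]

#: Study-shape constants: ~800 one-minute samples, ~60 events of dose 25.
STUDY_N_STEPS = 800
STUDY_N_EVENTS = 60
STUDY_MEAN_GAP = 13.0
STUDY_DOSE = 25.0


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce one simulated series bit-for-bit."""

    n_steps: int
    schedule: EventSchedule
    params: HawkesParams = TRUE_PARAMS
    dt: float = 1.0
    t0: float = 0.0
    noise_variance: float = 1.0
    seed: int = 0
    mode: str = "level"
    normalized_gamma: bool = True

    def __post_init__(self) -> None:
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be >= 0")
        if self.mode not in ("level", "increment"):
            raise ValueError("mode must be 'level' or 'increment'")
        horizon = self.t0 + self.n_steps * self.dt
        if len(self.schedule) and self.schedule.times.max() >= horizon:
            raise ValueError("all event times must fall before n_steps * dt")

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


def study_schedule(seed: int) -> EventSchedule:
    """The simulation study's event schedule: exponential gaps (mean 13 min),
    60 draws of dose 25, truncated to the 800-minute horizon."""
    return generate_event_schedule(
        STUDY_N_EVENTS, STUDY_MEAN_GAP, STUDY_DOSE, seed=seed, horizon=STUDY_N_STEPS
    )


def study_config(seed: int, noise_variance: float = 1.0) -> SimulationConfig:
    """The study conditions with schedule and noise seeds derived from ``seed``."""
    return SimulationConfig(
        n_steps=STUDY_N_STEPS,
        schedule=study_schedule(seed),
        noise_variance=noise_variance,
        seed=seed,
    )


def simulate_series(config: SimulationConfig) -> tuple[MonitoredSeries, MonitoredSeries]:
    """Simulate ``(noisy, clean)`` series from a parameter truth and schedule.

    The clean series is the intensity on the grid (level mode) or
    ``x_0 + cumulative sum of intensity values`` treated as per-step
    increments (increment mode).  Noise is N(0, noise_variance) i.i.d. from
    ``config.seed``; with zero variance the two outputs coincide.
    """
    grid = config.t0 + config.dt * np.arange(config.n_steps)
    lam = intensity(grid, config.schedule, config.params, normalized=config.normalized_gamma)
    if config.mode == "level":
        clean_values = lam
    else:
        # lambda models the increment x_t - x_{t-1}; integrate from 0.
        clean_values = np.concatenate(([0.0], np.cumsum(lam[1:] * config.dt)))
    rng = np.random.default_rng(config.seed)
    noise = rng.normal(0.0, np.sqrt(config.noise_variance), size=config.n_steps)
    clean = MonitoredSeries(clean_values, t0=config.t0, dt=config.dt, label="x_clean")
    noisy = MonitoredSeries(clean_values + noise, t0=config.t0, dt=config.dt, label="x")
    return noisy, clean


def make_icu_like_fixture(
    seed: int,
    noise_variance: float = 1.0,
) -> tuple[MonitoredSeries, EventSchedule]:
    """A fixture shaped like the motivating real data set.

    812 one-minute samples at heart-rate scale with exactly 63 events of
    constant dose 25.  Event times are uniform order statistics on the
    window (the conditional law of a Poisson process given its event count),
    which guarantees the count; the series is simulated from the study truth
    with unit-mass kernels plus Gaussian noise.  Deterministic in ``seed``.
    """
    n_steps, n_events, dose = 812, 63, 25.0
    rng = np.random.default_rng(seed)
    times = np.sort(rng.uniform(0.0, n_steps, size=n_events))
    schedule = EventSchedule.from_arrays(times, np.full(n_events, dose))
    config = SimulationConfig(
        n_steps=n_steps,
        schedule=schedule,
        noise_variance=noise_variance,
        seed=seed + 1,  # independent of the event draw
    )
    noisy, _ = simulate_series(config)
    return noisy, schedule
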