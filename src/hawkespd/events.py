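"""Domain types for drug-administration events and monitored physiological series.

The model's inputs are a marked point process — administration times ``t_i``
(minutes from series start) with dose marks ``d_i`` — and a regularly sampled
monitored variable ``x_t`` (e.g. heart rate at one-minute resolution).  This
module holds the containers, their CSV readers/writers and a simple
exponential-gap event generator used by the simulation study.

CSV conventions: comma-separated, header row required, ``.`` decimal
separator, UTF-8.  Series files carry ``time,value`` columns, event files
``time,dose``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DrugEvent",
    "EventSchedule",
    "MonitoredSeries",
    "read_series_csv",
    "write_series_csv",
    "read_events_csv",
    "write_events_csv",
    "generate_event_schedule",
]


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


@dataclass(frozen=True)
class DrugEvent:
    """A single drug administration: time in minutes from series start, dose > 0."""

    time: float
    dose: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.time) or self.time < 0:
            raise ValueError(f"event time must be finite and >= 0, got {self.time}")
        if not math.isfinite(self.dose) or self.dose <= 0:
            raise ValueError(f"dose must be finite and > 0, got {self.dose}")


@dataclass(frozen=True)
class EventSchedule:
    """An ordered sequence of :class:`DrugEvent` with strictly increasing times."""

    events: tuple[DrugEvent, ...] = ()

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        for a, b in zip(times, times[1:]):
            if b < a:
                raise ValueError("event times must be non-decreasing")
            if b == a:
                raise ValueError(
                    "duplicate event times; merge explicitly via from_arrays(..., "
                    "on_duplicate='merge') if intended"
                )

    def __len__(self) -> int:
        return len(self.events)

    @property
    def times(self) -> np.ndarray:
        return np.array([e.time for e in self.events], dtype=float)

    @property
    def doses(self) -> np.ndarray:
        return np.array([e.dose for e in self.events], dtype=float)

    @classmethod
    def from_arrays(
        cls,
        times,
        doses,
        on_duplicate: str = "raise",
    ) -> "EventSchedule":
        """Build a schedule from parallel arrays, sorting by time.

        ``on_duplicate`` is ``"raise"`` (default) or ``"merge"`` — merging sums
        the doses of coincident events, which is well defined because the
        intensity sums kernels over events.
        """
        times = np.asarray(times, dtype=float)
        doses = np.asarray(doses, dtype=float)
        if times.shape != doses.shape:
            raise ValueError("times and doses must have equal length")
        order = np.argsort(times, kind="stable")
        times, doses = times[order], doses[order]
        if on_duplicate == "merge" and len(times) > 1:
            uniq, inv = np.unique(times, return_inverse=True)
            merged = np.zeros_like(uniq)
            np.add.at(merged, inv, doses)
            times, doses = uniq, merged
        elif on_duplicate not in ("raise", "merge"):
            raise ValueError(f"unknown duplicate policy {on_duplicate!r}")
        return cls(tuple(DrugEvent(t, d) for t, d in zip(times, doses)))

    def truncated(self, horizon: float) -> "EventSchedule":
        """Drop events at or beyond ``horizon`` (kernel support is causal)."""
        return EventSchedule(tuple(e for e in self.events if e.time < horizon))


@dataclass(frozen=True)
class MonitoredSeries:
    """A uniformly sampled monitored variable.

    The grid is implicit: sample ``k`` sits at ``t0 + k * dt`` minutes.  The
    default resolution is one minute.
    """

    values: np.ndarray
    t0: float = 0.0
    dt: float = 1.0
    label: str = "x"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or len(self.values) < 2:
            raise ValueError("a series needs at least two samples")
        if not (self.dt > 0):
            raise ValueError("dt must be > 0")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def time(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self.values))

    @property
    def horizon(self) -> float:
        """End of the observation window, ``t0 + n*dt``."""
        return self.t0 + self.dt * len(self.values)

    def with_values(self, values, label: str | None = None) -> "MonitoredSeries":
        return MonitoredSeries(values, self.t0, self.dt, label if label is not None else self.label)


def read_series_csv(
    path,
    time_col: str = "time",
    value_col: str = "value",
) -> MonitoredSeries:
    """Read a monitored series, reindexing onto the uniform grid.

    Missing values (empty cells, or missing rows relative to the inferred
    grid step) are forward-filled, with a back-fill for a missing head.  If
    the recorded times do not land on a uniform grid even after gap-filling,
    a :class:`FormatError` is raised.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    if frame.empty:
        raise FormatError(f"{path}: empty series file")
    for col in (time_col, value_col):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    t = frame[time_col].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: a series needs at least two rows")
    diffs = np.diff(np.sort(t))
    pos = diffs[diffs > 0]
    if len(pos) == 0:
        raise FormatError(f"{path}: all time stamps identical")
    dt = float(pos.min())
    k = np.round((t - t[0]) / dt)
    if not np.allclose(t, t[0] + k * dt, rtol=0, atol=1e-6 * dt):
        raise FormatError(f"{path}: time stamps are not on a uniform grid")
    n = int(k.max()) + 1
    values = np.full(n, np.nan)
    values[k.astype(int)] = frame[value_col].to_numpy(dtype=float)
    filled = pd.Series(values).ffill().bfill().to_numpy()
    if np.isnan(filled).any():
        raise FormatError(f"{path}: no finite values to fill from")
    return MonitoredSeries(filled, t0=float(t[0]), dt=dt, label=value_col)


def write_series_csv(series: MonitoredSeries, path) -> None:
    # pandas' default str() formatting is the shortest round-trip representation
    pd.DataFrame({"time": series.time, "value": series.values}).to_csv(path, index=False)


def read_events_csv(path, on_duplicate: str = "raise") -> EventSchedule:
    """Read an event table (``time,dose``), sorted ascending by time.

    An empty table is a valid schedule (the model reduces to its baseline).
    Non-positive doses are rejected; duplicate times follow ``on_duplicate``.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    for col in ("time", "dose"):
        if col not in frame.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if frame.empty:
        return EventSchedule()
    return EventSchedule.from_arrays(
        frame["time"].to_numpy(dtype=float),
        frame["dose"].to_numpy(dtype=float),
        on_duplicate=on_duplicate,
    )


def write_events_csv(schedule: EventSchedule, path) -> None:
    pd.DataFrame({"time": schedule.times, "dose": schedule.doses}).to_csv(path, index=False)


def generate_event_schedule(
    n_events: int,
    mean_gap: float,
    dose: float,
    seed: int,
    horizon: float | None = None,
) -> EventSchedule:
    """Generate a schedule with exponential inter-event gaps and constant dose.

    Event times are cumulative sums of i.i.d. Exponential(mean ``mean_gap``)
    gaps; if ``horizon`` is given, events beyond it are dropped.  The result
    is a pure function of ``(n_events, mean_gap, dose, seed)``.
    """
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    if mean_gap <= 0 or dose <= 0:
        raise ValueError("mean_gap and dose must be > 0")
    if n_events == 0:
        return EventSchedule()
    rng = np.random.default_rng(seed)
    times = np.cumsum(rng.exponential(mean_gap, size=n_events))
    schedule = EventSchedule.from_arrays(times, np.full(n_events, float(dose)))
    if horizon is not None:
        schedule = schedule.truncated(horizon)
    return schedule
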