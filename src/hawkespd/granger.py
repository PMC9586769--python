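"""Granger-causality F-test of the drug series on candidate target series.

The unrestricted regression is

    x_t = c + sum_{i=1..m} alpha_i d_{t-i} + sum_{i=1..m} beta_i x_{t-i} + e_t

and the restricted one drops the drug lags.  Both are fit by OLS on the
common estimable sample and compared by

    F = [(SSR_r - SSR_ur) / m] / [SSR_ur / (n - k)],

with k the number of unrestricted parameters (2m plus the intercept).  A
large F (small p) rejects "the drug series does not Granger-cause x".

The drug regressor is the dose-mark series on the sampling grid: zero
except at event samples, where it carries the dose (a binary-indicator
encoding is available).  To choose the modelling target, the test is run
on every column of the wavelet feature matrix W and the component with the
smallest p-value wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .events import EventSchedule, MonitoredSeries
from .modwt import WaveletDecomposition, get_component

__all__ = [
    "GrangerResult",
    "dose_mark_series",
    "granger_f_test",
    "select_target_variable",
    "results_table",
]

DEFAULT_LAG = 4


@dataclass(frozen=True)
class GrangerResult:
    f_stat: float
    df1: int
    df2: int
    p_value: float
    ssr_restricted: float
    ssr_unrestricted: float
    lag: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.df1 < 1 or self.df2 < 1:
            raise ValueError("degrees of freedom must be >= 1")
        if self.ssr_unrestricted > self.ssr_restricted * (1 + 1e-12) + 1e-12:
            raise ValueError("restricted SSR cannot be below unrestricted SSR")


def dose_mark_series(
    schedule: EventSchedule,
    like: MonitoredSeries,
    encoding: str = "dose",
) -> MonitoredSeries:
    """Place the doses on the series' grid: zeros off events, the dose (or 1
    for ``encoding="indicator"``) at each event's sample.

    An event at time tau maps to sample floor((tau - t0) / dt); several
    events in one sampling interval accumulate.
    """
    if encoding not in ("dose", "indicator"):
        raise ValueError("encoding must be 'dose' or 'indicator'")
    marks = np.zeros(len(like))
    if len(schedule):
        idx = np.floor((schedule.times - like.t0) / like.dt).astype(int)
        if idx.min() < 0 or idx.max() >= len(like):
            raise ValueError("event times fall outside the series window")
        weights = schedule.doses if encoding == "dose" else np.ones(len(schedule))
        np.add.at(marks, idx, weights)
    return like.with_values(marks, label="d")


def _lag_matrix(values: np.ndarray, m: int) -> np.ndarray:
    # column i (0-based) holds the series lagged by i+1, rows t = m..n-1
    n = len(values)
    return np.column_stack([values[m - i - 1 : n - i - 1] for i in range(m)])


def granger_f_test(
    x: MonitoredSeries,
    d: MonitoredSeries,
    m: int = DEFAULT_LAG,
    intercept: bool = True,
) -> GrangerResult:
    """Test whether the drug series ``d`` Granger-causes ``x`` at lag ``m``.

    Both series must share the sampling grid.  If the drug-lag block is
    identically zero the restricted and unrestricted fits coincide and the
    degenerate convention ``F = 0, p = 1`` is returned.
    """
    if len(x) != len(d) or x.dt != d.dt or x.t0 != d.t0:
        raise ValueError("x and d must share the same grid")
    if m < 1:
        raise ValueError("lag m must be >= 1")
    n_total = len(x)
    if n_total <= 2 * m + 1:
        raise ValueError("series too short for the requested lag")
    xv, dv = x.values, d.values
    y = xv[m:]
    own = _lag_matrix(xv, m)
    drug = _lag_matrix(dv, m)
    k = 2 * m + (1 if intercept else 0)
    n = len(y)
    if n <= k:
        raise ValueError("not enough estimable samples for the requested lag")

    restricted_X = sm.add_constant(own, has_constant="add") if intercept else own
    if not np.any(drug):
        # degenerate: no drug information; the two fits coincide
        ssr = float(sm.OLS(y, restricted_X).fit().ssr)
        return GrangerResult(0.0, m, n - k, 1.0, ssr, ssr, m)
    unrestricted_X = np.column_stack([drug, own])
    if intercept:
        unrestricted_X = sm.add_constant(unrestricted_X, has_constant="add")
    if np.linalg.matrix_rank(unrestricted_X) < unrestricted_X.shape[1]:
        raise ValueError("rank-deficient lagged design; reduce m or check the inputs")
    ssr_ur = float(sm.OLS(y, unrestricted_X).fit().ssr)
    ssr_r = float(sm.OLS(y, restricted_X).fit().ssr)
    f = ((ssr_r - ssr_ur) / m) / (ssr_ur / (n - k))
    f = max(f, 0.0)
    p = float(stats.f.sf(f, m, n - k))
    return GrangerResult(f, m, n - k, p, ssr_r, ssr_ur, m)


_KIND_RANK = {"s": 0, "d": 1}  # scale before detail in tie-breaks


def select_target_variable(
    W: WaveletDecomposition,
    d: MonitoredSeries,
    m: int = DEFAULT_LAG,
    intercept: bool = True,
    alpha: float = 0.05,
) -> tuple[MonitoredSeries, str, list[GrangerResult]]:
    """Pick the W component the drug series most significantly predicts.

    Runs :func:`granger_f_test` on all 2J components and returns the one
    with the smallest p-value, its label, and the full result table.  Ties
    are broken deterministically: scale before detail, then lower level.
    If no component reaches ``alpha`` a warning is emitted but a selection
    is still returned.
    """
    candidates: list[tuple[MonitoredSeries, GrangerResult]] = []
    for kind in ("scale", "detail"):
        for j in range(1, W.levels + 1):
            comp = get_component(W, kind, j)
            res = granger_f_test(comp, d, m=m, intercept=intercept)
            candidates.append((comp, GrangerResult(
                res.f_stat, res.df1, res.df2, res.p_value,
                res.ssr_restricted, res.ssr_unrestricted, res.lag, comp.label,
            )))
    best_comp, best_res = min(
        candidates,
        key=lambda cr: (cr[1].p_value, _KIND_RANK[cr[1].label[0]], int(cr[1].label[1:])),
    )
    if best_res.p_value >= alpha:
        warnings.warn(
            f"no component is Granger-caused by the drug series at alpha={alpha} "
            f"(best p={best_res.p_value:.3g} for {best_res.label})",
            RuntimeWarning,
            stacklevel=2,
        )
    return best_comp, best_res.label, [r for _, r in candidates]


def results_table(results: list[GrangerResult]) -> "pd.DataFrame":
    """The per-component table (label, F, df, p, Bonferroni-adjusted p)."""
    import pandas as pd

    n = len(results)
    return pd.DataFrame(
        {
            "label": [r.label for r in results],
            "f_stat": [r.f_stat for r in results],
            "df1": [r.df1 for r in results],
            "df2": [r.df2 for r in results],
            "p_value": [r.p_value for r in results],
            "p_bonferroni": [min(1.0, r.p_value * n) for r in results],
        }
    )
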