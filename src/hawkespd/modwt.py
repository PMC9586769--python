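"""Haar maximal-overlap discrete wavelet transform (MODWT).

The MODWT is the non-decimated, shift-covariant variant of the DWT: every
level keeps the input's length, so coefficient series live on the original
time grid and can be used directly as regression candidates.  With Haar
filters the pyramid is

    s_{j,t} = (s_{j-1,t} + s_{j-1,t-2^{j-1}}) / 2        (scale / smooth)
    d_{j,t} = (s_{j-1,t} - s_{j-1,t-2^{j-1}}) / 2        (detail / wavelet)

with s_0 = x and indices wrapped circularly (periodic boundary, the
default).  The 1/2 filter weights are the MODWT normalization (DWT Haar
filters 1/sqrt(2) rescaled by 2^{-1/2} per level), which gives exact
energy decomposition  ||x||^2 = sum_j ||d_j||^2 + ||s_J||^2  and perfect
reconstruction.

The feature matrix W stacks all detail and scale series for levels 1..J;
``s_J`` carries the smooth trend ("scale information") and the ``d_j`` the
detail information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import MonitoredSeries

__all__ = ["WaveletDecomposition", "haar_modwt", "imodwt", "get_component"]


@dataclass(frozen=True)
class WaveletDecomposition:
    """Level-1..J detail and scale coefficient series of one input series.

    ``detail`` and ``scale`` are (J, n) arrays; row j-1 is level j.  All
    rows have the input's length (the transform is non-decimated).
    """

    detail: np.ndarray
    scale: np.ndarray
    boundary: str
    t0: float = 0.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.detail.shape != self.scale.shape or self.detail.ndim != 2:
            raise ValueError("detail and scale must be equal-shape (J, n) arrays")

    @property
    def levels(self) -> int:
        return self.detail.shape[0]

    @property
    def n(self) -> int:
        return self.detail.shape[1]

    def labels(self) -> list[str]:
        """Column labels of the W matrix: d1..dJ then s1..sJ."""
        J = self.levels
        return [f"d{j}" for j in range(1, J + 1)] + [f"s{j}" for j in range(1, J + 1)]

    def to_frame(self) -> pd.DataFrame:
        """The W matrix: one row per time point, columns d1..dJ, s1..sJ."""
        data = np.vstack([self.detail, self.scale]).T
        frame = pd.DataFrame(data, columns=self.labels())
        frame.insert(0, "time", self.t0 + self.dt * np.arange(self.n))
        return frame


def max_level(n: int) -> int:
    """Default level cap: floor(log2(n))."""
    return int(np.floor(np.log2(n)))


def haar_modwt(x: MonitoredSeries, J: int = 4, boundary: str = "periodic") -> WaveletDecomposition:
    """Decompose a series into level-1..J Haar MODWT coefficients.

    ``boundary`` is ``"periodic"`` (circular wrap, default) or
    ``"reflection"`` (the series is mirrored to length 2n, transformed
    periodically, and the first n coefficients kept).  The level cap is
    floor(log2(n)).
    """
    if J < 1:
        raise ValueError("J must be >= 1")
    n = len(x)
    if J > max_level(n):
        raise ValueError(f"J={J} too large for a length-{n} series (max {max_level(n)})")
    if boundary not in ("periodic", "reflection"):
        raise ValueError(f"unknown boundary rule {boundary!r}")
    v = np.asarray(x.values, dtype=float)
    if boundary == "reflection":
        v = np.concatenate([v, v[::-1]])
    detail, scale = [], []
    for j in range(1, J + 1):
        shifted = np.roll(v, 2 ** (j - 1))
        detail.append((v - shifted) / 2.0)
        scale.append((v + shifted) / 2.0)
        v = scale[-1]
    detail = np.array(detail)[:, :n]
    scale = np.array(scale)[:, :n]
    return WaveletDecomposition(detail, scale, boundary, t0=x.t0, dt=x.dt)


def imodwt(W: WaveletDecomposition) -> MonitoredSeries:
    """Reconstruct the original series from {d_1..d_J, s_J}.

    Exact (to round-off) for the periodic boundary; the reflection variant
    discards coefficients and is not invertible from the stored arrays.
    """
    if W.boundary != "periodic":
        raise ValueError("reconstruction is only supported for the periodic boundary")
    v = W.scale[-1].copy()
    for j in range(W.levels, 0, -1):
        h = 2 ** (j - 1)
        d = W.detail[j - 1]
        # synthesis with the time-reversed MODWT filters:
        # s_{j-1,t} = (d_{j,t} - d_{j,t+h} + s_{j,t} + s_{j,t+h}) / 2
        v = 0.5 * (d - np.roll(d, -h) + v + np.roll(v, -h))
    return MonitoredSeries(v, t0=W.t0, dt=W.dt, label="x")


def get_component(W: WaveletDecomposition, kind: str, j: int) -> MonitoredSeries:
    """Extract one coefficient series ("scale" or "detail", level j) as a
    MonitoredSeries on the input grid, labelled e.g. ``"s4"`` or ``"d2"``."""
    if kind not in ("scale", "detail"):
        raise ValueError("kind must be 'scale' or 'detail'")
    if not (1 <= j <= W.levels):
        raise ValueError(f"level {j} out of range 1..{W.levels}")
    arr = (W.scale if kind == "scale" else W.detail)[j - 1]
    label = ("s" if kind == "scale" else "d") + str(j)
    return MonitoredSeries(arr.copy(), t0=W.t0, dt=W.dt, label=label)
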