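"""Core containers shared by the whole pipeline.

The universal currency is :class:`TimeSeries`: a uniformly sampled,
real-valued scalar signal with a sampling rate.  Windowed analysis turns a
``TimeSeries`` into :class:`PhasePortrait` objects (planar trajectories),
Poincare sections turn portraits into :class:`CrossingSet` objects, their
binned counts are :class:`TrajectoryHistogram` objects, and the assembled
time x bin intensity matrix is the :class:`Phasegram`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


class PhasegramError(Exception):
    """Base class for all errors raised by this package."""


class InvalidParameterError(PhasegramError, ValueError):
    """A configuration or specification value violates its invariants."""


class NumericDomainError(PhasegramError, ArithmeticError):
    """A computed quantity left its mathematically valid domain."""


class SignalTooShortError(PhasegramError, ValueError):
    """The signal is shorter than the analysis window requires."""


@dataclass(frozen=True)
class TimeSeries:
    """Uniformly sampled real-valued signal.

    Parameters
    ----------
    samples : array-like of float
        Ordered amplitudes, arbitrary units.
    fs : float
        Sampling rate in Hz, > 0.
    label : str
        Free-text description carried through the pipeline.
    """

    samples: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise InvalidParameterError(f"fs must be > 0, got {self.fs}")
        if samples.ndim != 1 or samples.size < 2:
            raise InvalidParameterError(
                "samples must be a 1-D array of length >= 2"
            )
        if not np.all(np.isfinite(samples)):
            raise NumericDomainError("samples contain non-finite values")

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        """Signal duration in seconds (n / fs)."""
        return len(self) / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(len(self)) / self.fs

    def replace(self, samples: np.ndarray | None = None,
                fs: float | None = None,
                label: str | None = None) -> "TimeSeries":
        return TimeSeries(
            samples=self.samples if samples is None else samples,
            fs=self.fs if fs is None else fs,
            label=self.label if label is None else label,
        )


@dataclass(frozen=True)
class PhasePortrait:
    """Ordered planar trajectory reconstructed for one analysis window."""

    points: np.ndarray          # (n, 2) array of (u, v) coordinates
    center_time_s: float
    window_span: tuple[int, int]  # (first sample index, last sample index)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise InvalidParameterError("portrait needs >= 2 planar points")
        if not np.all(np.isfinite(pts)):
            raise NumericDomainError("portrait contains non-finite points")

    @property
    def u(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def v(self) -> np.ndarray:
        return self.points[:, 1]


@dataclass(frozen=True)
class CrossingSet:
    """Poincare-section intersections of one portrait.

    ``positions`` are signed distances along the section line (in signal
    amplitude units); ``directions`` records the side the trajectory moved
    to (+1 crossing towards positive perpendicular coordinate).
    """

    positions: np.ndarray
    directions: np.ndarray
    center_time_s: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.float64)
        dirs = np.asarray(self.directions, dtype=np.int64)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "directions", dirs)
        if pos.shape != dirs.shape:
            raise InvalidParameterError("positions/directions length mismatch")
        if pos.size and not np.all(np.isfinite(pos)):
            raise NumericDomainError("crossing positions must be finite")
        if pos.size and not np.all(np.isin(dirs, (-1, 1))):
            raise InvalidParameterError("directions must be +-1")

    def __len__(self) -> int:
        return int(self.positions.size)


@dataclass(frozen=True)
class TrajectoryHistogram:
    """Binned Poincare-crossing positions for one analysis window."""

    bin_edges: np.ndarray   # uniform grid, symmetric about 0
    counts: np.ndarray      # non-negative integers, len(edges) - 1
    center_time_s: float = 0.0

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=np.float64)
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)
        if edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise InvalidParameterError("bin edges must strictly increase")
        if counts.size != edges.size - 1:
            raise InvalidParameterError("counts/edges size mismatch")
        if np.any(counts < 0):
            raise InvalidParameterError("counts must be non-negative")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class Phasegram:
    """Time x bin intensity matrix: the method's central object.

    ``matrix`` has shape (n_windows, n_bins) with intensities in [0, 1];
    row i is the colour-coded trajectory strip at ``times_s[i]``.
    """

    matrix: np.ndarray
    times_s: np.ndarray
    bin_centers: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        t = np.asarray(self.times_s, dtype=np.float64)
        b = np.asarray(self.bin_centers, dtype=np.float64)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "bin_centers", b)
        if m.ndim != 2 or m.shape != (t.size, b.size):
            raise InvalidParameterError(
                f"matrix shape {m.shape} inconsistent with axes "
                f"({t.size} times, {b.size} bins)"
            )
        if m.size and (m.min() < 0 or m.max() > 1):
            raise InvalidParameterError("intensities must lie in [0, 1]")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise InvalidParameterError("times must strictly increase")

    @property
    def n_windows(self) -> int:
        return int(self.times_s.size)

    @property
    def n_bins(self) -> int:
        return int(self.bin_centers.size)

    @property
    def bin_width(self) -> float:
        if self.bin_centers.size > 1:
            return float(self.bin_centers[1] - self.bin_centers[0])
        return float("nan")


@dataclass(frozen=True)
class RegimeSegment:
    """A maximal run of windows sharing one oscillatory-regime label.

    ``label`` is one of ``static``, ``periodic``, ``subharmonic(p)`` (p the
    period multiplier, 2p phasegram lines) or ``irregular``.  ``stability``
    is the fraction of columns whose line positions stay within one bin of
    the segment median.
    """

    t_start: float
    t_end: float
    label: str
    line_count: int
    stability: float

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise InvalidParameterError("segment needs t_start < t_end")

    @property
    def duration_s(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class BifurcationDiagram:
    """Phasegram line positions mapped onto a control parameter.

    Points are split by sweep direction so hysteresis (different regimes on
    the rising vs falling branch over the same control interval) is visible.
    """

    control_rising: np.ndarray    # control values, rising sweep phase
    position_rising: np.ndarray   # matching line positions
    control_falling: np.ndarray
    position_falling: np.ndarray
    labels_rising: np.ndarray     # regime label per rising point
    labels_falling: np.ndarray
    control_name: str = "control"
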