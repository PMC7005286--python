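"""Discrete time-interval grids for binned survival analysis.

A cohort's follow-up axis is cut into half-open intervals
``I_j = [t_{j-1}, t_j)`` for ``j = 1..J``, with ``t_0 = 0`` and, for the
default unit (monthly) width, ``t_J = floor(max duration) + 1``.  Every
observed duration then falls in exactly one interval, and ``t_J`` strictly
exceeds the maximum duration by construction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

#: Sentinel returned by :meth:`TimeBinning.bin_index` for times at or past t_J.
BEYOND = "beyond"


@dataclass(frozen=True)
class TimeBinning:
    """An ordered grid of half-open time intervals.

    Parameters
    ----------
    edges : numpy.ndarray
        Strictly increasing edge times ``t_0 .. t_J`` with ``t_0 = 0``.
        Interval ``j`` (1-based) is ``[edges[j-1], edges[j])``.
    """

    edges: np.ndarray = field()

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("edges must be a 1-d array of at least two times")
        if edges[0] != 0.0:
            raise ValueError("first edge must be 0")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("edges must be strictly increasing")
        object.__setattr__(self, "edges", edges)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_durations(cls, durations, width: float = 1.0) -> "TimeBinning":
        """Build the grid covering a set of observed durations.

        The right end is ``floor(max duration) + 1`` (so the grid strictly
        covers the maximum), extended outward if needed so that the last
        edge is an integer multiple of ``width``.
        """
        durations = np.asarray(durations, dtype=float)
        if durations.size == 0:
            raise ValueError("cannot build a binning from an empty duration list")
        if np.any(durations < 0):
            raise ValueError("durations must be non-negative")
        if width <= 0:
            raise ValueError("bin width must be positive")
        t_end = math.floor(float(durations.max())) + 1.0
        n_bins = int(math.ceil(t_end / width - 1e-12))
        edges = np.arange(n_bins + 1, dtype=float) * width
        return cls(edges)

    # -- queries -----------------------------------------------------------

    @property
    def n_bins(self) -> int:
        """Number of intervals J."""
        return self.edges.size - 1

    @property
    def t_end(self) -> float:
        """Right end t_J of the covered range."""
        return float(self.edges[-1])

    @property
    def midpoints(self) -> np.ndarray:
        """Interval midpoints m_1..m_J."""
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def bin_index(self, t: float):
        """1-based index of the interval containing ``t``, or :data:`BEYOND`.

        Membership is half-open: ``t_{j-1} <= t < t_j``.
        """
        if t < 0:
            raise ValueError("time must be non-negative")
        if t >= self.t_end:
            return BEYOND
        return int(np.searchsorted(self.edges, t, side="right"))

    def bin_indices(self, times) -> np.ndarray:
        """Vectorised :meth:`bin_index`; raises if any time falls beyond t_J."""
        times = np.asarray(times, dtype=float)
        if np.any(times < 0):
            raise ValueError("times must be non-negative")
        if np.any(times >= self.t_end):
            raise ValueError("some times fall at or beyond the last edge t_J")
        return np.searchsorted(self.edges, times, side="right").astype(int)

    # -- serialisation -----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps({"edges": self.edges.tolist()})

    @classmethod
    def from_json(cls, payload: str) -> "TimeBinning":
        return cls(np.asarray(json.loads(payload)["edges"], dtype=float))


def build_binning(durations, width: float = 1.0) -> TimeBinning:
    """Functional alias for :meth:`TimeBinning.from_durations`."""
    return TimeBinning.from_durations(durations, width=width)
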