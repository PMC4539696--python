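"""In-memory representation of a SIM acquisition.

A run is a set of per-mass-channel traces (extracted ion chromatograms).
Channels belong to contiguous acquisition segments: in SIM mode the
instrument switches the monitored mass set between RT windows, so the same
nominal mass may appear in more than one segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np


@dataclass(frozen=True)
class ChannelTrace:
    """Time/intensity trace of one monitored m/z channel.

    ``times`` are in seconds and strictly increasing; intensities are
    non-negative raw (or baseline-corrected) detector counts.
    """

    mass: int
    times: np.ndarray
    intensities: np.ndarray
    segment_id: int = 0
    #: Optional noise-suppressed copy used for peak *detection* only;
    #: quantitative fits and areas always use ``intensities``.
    smoothed: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if t.ndim != 1 or t.size < 1:
            raise ValueError("trace must have at least one sample")
        if t.size != y.size:
            raise ValueError("times and intensities differ in length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)

    @property
    def dt(self) -> float:
        """Median sampling interval in seconds (0 for single-point traces)."""
        if self.times.size < 2:
            return 0.0
        return float(np.median(np.diff(self.times)))

    @property
    def detection_track(self) -> np.ndarray:
        """The signal peaks are detected on: smoothed copy if present."""
        return self.smoothed if self.smoothed is not None else self.intensities

    def with_intensities(self, intensities: np.ndarray) -> "ChannelTrace":
        """New trace with replaced intensities (stale smoothed copy dropped)."""
        return replace(
            self, intensities=np.asarray(intensities, dtype=float), smoothed=None
        )

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class SIMRun:
    """A SIM acquisition: one trace per (nominal mass, segment) pair."""

    run_id: str
    traces: list[ChannelTrace]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.traces:
            raise ValueError("a run must contain at least one trace")
        keys = [(tr.mass, tr.segment_id) for tr in self.traces]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (mass, segment) channel in run")

    def masses(self) -> list[int]:
        return sorted({tr.mass for tr in self.traces})

    def has_mass(self, mass: int) -> bool:
        return any(tr.mass == mass for tr in self.traces)

    def get_trace(self, mass: int, near_time: float | None = None) -> ChannelTrace:
        """Trace for a nominal mass.  If the mass was monitored in several
        segments, ``near_time`` picks the segment covering (or closest to)
        that time."""
        cands = [tr for tr in self.traces if tr.mass == mass]
        if not cands:
            raise KeyError(f"run {self.run_id!r} has no channel for m/z {mass}")
        if len(cands) == 1 or near_time is None:
            return cands[0]

        def distance(tr: ChannelTrace) -> float:
            t0, t1 = tr.times[0], tr.times[-1]
            if t0 <= near_time <= t1:
                return 0.0
            return min(abs(near_time - t0), abs(near_time - t1))

        return min(cands, key=distance)

    def map_traces(self, fn) -> "SIMRun":
        """New run with ``fn`` applied to every trace (e.g. preprocessing)."""
        return SIMRun(self.run_id, [fn(tr) for tr in self.traces], dict(self.metadata))
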