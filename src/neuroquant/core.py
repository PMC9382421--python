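"""Central data model for the quantification pipeline.

All times are in seconds, frames are 0-based, and time bins are half-open
``[t, t + dt)``.  These conventions are shared by every module so that spike
tables, burst intervals, and binned state series line up without off-by-one
adjustments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: Default electrode labels of one multi-electrode-array well (9 electrodes).
DEFAULT_ELECTRODES: tuple[str, ...] = tuple(f"E{i}" for i in range(1, 10))

GENOTYPES = ("WT", "Het", "KO")


def _as_sorted_times(times, duration: float, label: str) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.ndim != 1:
        raise ValueError(f"{label}: spike times must be one-dimensional")
    if t.size and (np.any(t < 0) or np.any(t > duration)):
        raise ValueError(f"{label}: spike times must lie within [0, duration]")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError(f"{label}: spike times must be strictly increasing")
    return t


@dataclass
class SpikeTrain:
    """Sorted spike times of one electrode."""

    electrode_id: str
    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        self.times = _as_sorted_times(self.times, self.duration, self.electrode_id)

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)


@dataclass
class WellRecording:
    """Spike trains of the electrodes of one MEA well plus metadata.

    ``spike_trains`` maps electrode id to a sorted array of spike times in
    seconds; electrodes without activity are present with empty arrays.
    ``metadata`` may carry ``genotype`` (WT/Het/KO), ``treatment`` and
    ``timepoint_min``.
    """

    well_id: str
    spike_trains: dict[str, np.ndarray]
    duration: float
    electrode_ids: Sequence[str] = DEFAULT_ELECTRODES
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        self.electrode_ids = tuple(self.electrode_ids)
        trains = {}
        for eid in self.electrode_ids:
            t = self.spike_trains.get(eid, np.empty(0))
            trains[eid] = _as_sorted_times(t, self.duration, f"{self.well_id}/{eid}")
        extra = set(self.spike_trains) - set(self.electrode_ids)
        if extra:
            raise ValueError(f"{self.well_id}: unknown electrodes {sorted(extra)}")
        self.spike_trains = trains
        g = self.metadata.get("genotype")
        if g is not None and g not in GENOTYPES:
            raise ValueError(f"unknown genotype {g!r}; expected one of {GENOTYPES}")

    def train(self, electrode_id: str) -> SpikeTrain:
        return SpikeTrain(electrode_id, self.spike_trains[electrode_id], self.duration)

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.spike_trains.values()))


@dataclass
class VoltageTrace:
    """Raw extracellular voltage samples of one electrode."""

    samples: np.ndarray
    sampling_rate: float
    electrode_id: str = "E1"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.samples.size < 2:
            raise ValueError("trace must contain at least two samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass(frozen=True)
class Burst:
    """A detected burst: a maximal run of spikes with short inter-spike intervals."""

    start: float
    end: float
    first_index: int
    n_spikes: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("burst end precedes start")
        if self.n_spikes < 2:
            raise ValueError("a burst needs at least two spikes")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class FluorescenceTrace:
    """Per-ROI fluorescence intensity series with its twin background ROI."""

    roi_id: str
    raw: np.ndarray
    background: np.ndarray
    frame_rate: float = 15.3

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.raw.shape != self.background.shape:
            raise ValueError("raw and background traces must have the same length")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.raw.size)

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass(frozen=True)
class Transient:
    """One detected calcium transient (frames are 0-based)."""

    onset_frame: int
    peak_frame: int
    end_frame: int
    amplitude: float
    f0: float
    f0_truncated: bool = False

    def __post_init__(self) -> None:
        if self.peak_frame < self.onset_frame:
            raise ValueError("peak precedes onset")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.f0 <= 0:
            raise ValueError("F0 must be positive")
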