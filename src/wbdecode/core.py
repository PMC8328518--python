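"""Shared domain containers for the wide-band decoding pipeline.

The pipeline passes a small number of array-carrying records between stages:
a raw multichannel recording, a time-aligned behavior table, the wavelet
coefficient tensor the decoder consumes, and a catalog of simulated (or
sorted) units with their spike times and waveform templates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Arena",
    "BehaviorSeries",
    "WidebandRecording",
    "UnitSpec",
    "UnitCatalog",
]


@dataclass(frozen=True)
class Arena:
    """Rectangular open-field environment, dimensions in cm."""

    width: float
    height: float

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError("Arena dimensions must be positive")


@dataclass
class BehaviorSeries:
    """Uniformly sampled behavior: position (cm), head direction (rad), speed (cm/s).

    ``head_direction`` lives in [-pi, pi); ``speed`` is nonnegative. All series
    share one time base of rate ``fs`` (Hz) starting at t = 0.
    """

    fs: float
    position: np.ndarray  # (n, 2) in cm
    head_direction: np.ndarray  # (n,) radians in [-pi, pi)
    speed: np.ndarray  # (n,) cm/s

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.head_direction = np.asarray(self.head_direction, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        n = len(self.position)
        if not (len(self.head_direction) == n and len(self.speed) == n):
            raise ValueError("behavior series must have equal length")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.position)

    @property
    def timestamps(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def target_matrix(self, variables: Sequence[str]) -> np.ndarray:
        """Stack named behavior variables into an (n, d) regression target."""
        cols = []
        for v in variables:
            if v == "position":
                cols.append(self.position)
            elif v == "head_direction":
                cols.append(self.head_direction[:, None])
            elif v == "speed":
                cols.append(self.speed[:, None])
            else:
                raise KeyError(f"unknown behavior variable: {v!r}")
        return np.concatenate(cols, axis=1)


@dataclass
class WidebandRecording:
    """Raw multichannel voltage series, ``data`` shaped (channels, samples)."""

    data: np.ndarray
    fs: float
    channel_ids: Sequence[int] | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")
        if self.channel_ids is None:
            self.channel_ids = list(range(self.data.shape[0]))

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class UnitSpec:
    """Ground-truth parameters of one simulated unit.

    ``kind`` is "place" (Gaussian spatial field, broad spike) or "interneuron"
    (spatially untuned, narrow spike, optionally von-Mises head-direction
    modulated via ``hd_preference`` / ``hd_kappa``).
    """

    kind: str
    peak_rate: float
    baseline_rate: float
    waveform: np.ndarray  # template sampled at fs_neural
    channel_weights: np.ndarray  # per-channel gain
    field_centre: tuple[float, float] | None = None
    field_width: float = 20.0  # cm, Gaussian sigma of the place field
    hd_preference: float | None = None
    hd_kappa: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("place", "interneuron"):
            raise ValueError(f"unknown unit kind: {self.kind!r}")
        if not (self.peak_rate >= self.baseline_rate >= 0):
            raise ValueError("need peak_rate >= baseline_rate >= 0")
        if self.hd_kappa < 0:
            raise ValueError("hd_kappa must be >= 0")
        self.waveform = np.asarray(self.waveform, dtype=float)
        self.channel_weights = np.asarray(self.channel_weights, dtype=float)


@dataclass
class UnitCatalog:
    """Spike times, labels and templates for every unit in a session."""

    spike_times: list[np.ndarray]  # seconds, one array per unit
    labels: list[str]  # "place" | "interneuron"
    waveforms: list[np.ndarray]
    units: list[UnitSpec] = field(default_factory=list)

    @property
    def n_units(self) -> int:
        return len(self.spike_times)

    def spike_counts(self) -> np.ndarray:
        return np.array([len(t) for t in self.spike_times])

    def times_by_label(self, label: str) -> np.ndarray:
        """Pooled, sorted spike times of all units with the given label."""
        pools = [t for t, l in zip(self.spike_times, self.labels) if l == label]
        if not pools:
            return np.empty(0)
        return np.sort(np.concatenate(pools))
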