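"""On-disk formats and run configuration.

HDF5 layout (one file can hold any subset):

    /recording/data        (channels, samples) float
    /recording/fs          scalar
    /behavior/{position,head_direction,speed}; /behavior/fs
    /units/spike_times_<i>; /units/labels; /units/waveform_<i>
    /wavelets/values       (time, freq, channel), chunked along time
    /wavelets/frequencies; /wavelets/fs_effective; /wavelets/{w0,M,normalized}

Behavior also round-trips through CSV with header ``t,x,y,hd,speed``.
Every artifact written by the CLI embeds the YAML run configuration under a
``config`` attribute for provenance.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .core import BehaviorSeries, UnitCatalog, WidebandRecording
from .preprocessing import FrequencyBank, WaveletTensor

__all__ = [
    "RunConfig",
    "load_config",
    "write_recording",
    "read_recording",
    "write_behavior_csv",
    "read_behavior_csv",
    "write_units",
    "read_units",
    "write_tensor",
    "read_tensor",
]


@dataclass
class RunConfig:
    """YAML-serializable configuration; unknown keys are rejected."""

    seed: int = 0
    f_max: float = 15000.0
    f_min: float = 2.0
    w0: float = 6.0
    M: int = 1000
    magnitude: bool = True  # |W| vs |W|^2
    duration: float = 600.0
    fs_neural: float = 30000.0
    n_channels: int = 4
    n_place: int = 20
    n_interneuron: int = 10
    noise_sd: float = 0.2
    arena_width: float = 175.0
    arena_height: float = 125.0
    window: int = 64
    epochs: int = 15
    batches_per_epoch: int = 150
    batch_size: int = 8
    learning_rate: float = 7e-4
    n_partitions: int = 5
    gap_s: float = 2.0

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self))


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _set_config(g: h5py.File | h5py.Group, config: RunConfig | None) -> None:
    if config is not None:
        g.attrs["config"] = config.to_yaml()


def write_recording(
    path: str | Path,
    rec: WidebandRecording,
    behavior: BehaviorSeries | None = None,
    units: UnitCatalog | None = None,
    config: RunConfig | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("recording")
        g.create_dataset("data", data=rec.data)
        g.create_dataset("fs", data=rec.fs)
        g.create_dataset("channel_ids", data=np.asarray(rec.channel_ids))
        if behavior is not None:
            _write_behavior_group(f, behavior)
        if units is not None:
            _write_units_group(f, units)
        _set_config(f, config)


def read_recording(path: str | Path) -> WidebandRecording:
    with h5py.File(path, "r") as f:
        if "recording" not in f:
            raise ValueError("file has no /recording group")
        g = f["recording"]
        if "fs" not in g:
            raise ValueError("missing /recording/fs")
        return WidebandRecording(
            data=g["data"][()],
            fs=float(g["fs"][()]),
            channel_ids=list(g["channel_ids"][()]) if "channel_ids" in g else None,
        )


def _write_behavior_group(f: h5py.File, behavior: BehaviorSeries) -> None:
    g = f.create_group("behavior")
    g.create_dataset("fs", data=behavior.fs)
    g.create_dataset("position", data=behavior.position)
    g.create_dataset("head_direction", data=behavior.head_direction)
    g.create_dataset("speed", data=behavior.speed)


def read_behavior(path: str | Path) -> BehaviorSeries:
    with h5py.File(path, "r") as f:
        g = f["behavior"]
        return BehaviorSeries(
            fs=float(g["fs"][()]),
            position=g["position"][()],
            head_direction=g["head_direction"][()],
            speed=g["speed"][()],
        )


_BEH_COLUMNS = ["t", "x", "y", "hd", "speed"]


def write_behavior_csv(path: str | Path, behavior: BehaviorSeries) -> None:
    df = pd.DataFrame(
        {
            "t": behavior.timestamps,
            "x": behavior.position[:, 0],
            "y": behavior.position[:, 1],
            "hd": behavior.head_direction,
            "speed": behavior.speed,
        }
    )
    df.to_csv(path, index=False)


def read_behavior_csv(path: str | Path) -> BehaviorSeries:
    df = pd.read_csv(path)
    missing = [c for c in _BEH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"behavior CSV missing column(s): {missing}")
    t = df["t"].to_numpy()
    fs = 1.0 / np.median(np.diff(t)) if len(t) > 1 else 1.0
    return BehaviorSeries(
        fs=float(fs),
        position=df[["x", "y"]].to_numpy(),
        head_direction=df["hd"].to_numpy(),
        speed=df["speed"].to_numpy(),
    )


def _write_units_group(f: h5py.File, units: UnitCatalog) -> None:
    g = f.create_group("units")
    g.create_dataset("labels", data=np.array(units.labels, dtype="S"))
    for i, (t, w) in enumerate(zip(units.spike_times, units.waveforms)):
        g.create_dataset(f"spike_times_{i}", data=np.asarray(t))
        g.create_dataset(f"waveform_{i}", data=np.asarray(w))


def write_units(path: str | Path, units: UnitCatalog, config: RunConfig | None = None) -> None:
    with h5py.File(path, "w") as f:
        _write_units_group(f, units)
        _set_config(f, config)


def read_units(path: str | Path) -> UnitCatalog:
    with h5py.File(path, "r") as f:
        g = f["units"]
        labels = [s.decode() for s in g["labels"][()]]
        spikes = [g[f"spike_times_{i}"][()] for i in range(len(labels))]
        wfs = [g[f"waveform_{i}"][()] for i in range(len(labels))]
    return UnitCatalog(spike_times=spikes, labels=labels, waveforms=wfs)


def write_tensor(path: str | Path, tensor: WaveletTensor, config: RunConfig | None = None) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("wavelets")
        t, fr, c = tensor.values.shape
        g.create_dataset(
            "values",
            data=tensor.values,
            chunks=(min(256, t), fr, c),  # chunked along time: windowed reads
        )
        g.create_dataset("frequencies", data=tensor.bank.centre_frequencies)
        g.create_dataset("fs_effective", data=tensor.fs_effective)
        g.attrs["w0"] = tensor.bank.w0
        g.attrs["M"] = tensor.downsample_factor
        g.attrs["normalized"] = tensor.normalized
        _set_config(f, config)


def read_tensor(path: str | Path) -> WaveletTensor:
    with h5py.File(path, "r") as f:
        g = f["wavelets"]
        bank = FrequencyBank(g["frequencies"][()], w0=float(g.attrs["w0"]))
        return WaveletTensor(
            values=g["values"][()],
            fs_effective=float(g["fs_effective"][()]),
            bank=bank,
            downsample_factor=int(g.attrs["M"]),
            normalized=bool(g.attrs["normalized"]),
        )
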