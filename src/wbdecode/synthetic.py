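"""Synthetic wide-band sessions with known ground truth.

Emulates the statistical structure the decoder exploits in hippocampal
recordings: an Ornstein-Uhlenbeck foraging trajectory in a rectangular arena,
Poisson place cells with Gaussian spatial fields and broad biphasic spike
templates, fast-spiking interneurons with narrow templates and optional
von-Mises head-direction modulation, a speed-modulated theta oscillation on
every channel, and additive white noise. A wavelet-level "simulated behavior"
modulation is also provided: selected frequency bands of a coefficient tensor
are multiplied by beta * y_sb(t), giving a regression target whose informative
bands are known exactly.

Everything is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .core import Arena, BehaviorSeries, UnitCatalog, UnitSpec, WidebandRecording
from .preprocessing import WaveletTensor

__all__ = [
    "ThetaParams",
    "synthetic_wavelet_tensor",
    "SimBehaviorModulation",
    "generate_trajectory",
    "make_spike_template",
    "generate_units",
    "synthesize_recording",
    "apply_sim_behavior_modulation",
]

# Trough sigma (ms) of the biphasic templates. The place value gives a trough
# half-width of 0.35 ms and dominant wavelet energy at 469 Hz; the interneuron
# value gives ~0.05 ms and dominant energy at 3750 Hz (verified against the
# wavelet bank in the test suite).
PLACE_TROUGH_SIGMA_MS = 0.15
INTERNEURON_TROUGH_SIGMA_MS = 0.02
REBOUND_WIDTH_RATIO = 3.5  # rebound sigma / trough sigma; sets amp/trough ~ 0.35


@dataclass(frozen=True)
class ThetaParams:
    """Speed-coupled theta oscillation added to every channel."""

    f0: float = 8.0  # Hz at rest
    speed_gain: float = 0.05  # Hz per cm/s
    amplitude: float = 0.5


@dataclass
class SimBehaviorModulation:
    """Wavelet-level planted signal: band centre (Hz) -> modulation gain beta."""

    band_betas: dict[float, float]
    y_sb: np.ndarray | None = None
    seed: int = 0
    y_sb_low: float = 0.05  # uniform support (low, 1]; avoids zeroing bands


def generate_trajectory(
    arena: Arena,
    duration: float,
    fs_beh: float = 30.0,
    seed: int = 0,
    mean_speed: float = 12.0,
    tau: float = 1.0,
) -> BehaviorSeries:
    """Ornstein-Uhlenbeck velocity random walk reflected at the arena walls.

    ``mean_speed`` (cm/s) sets the stationary Rayleigh mean of |velocity|;
    ``tau`` (s) is the velocity correlation time. Head direction is the
    heading of the velocity vector (held at its last value while stationary).
    """
    if duration <= 0 or fs_beh <= 0:
        raise ValueError("duration and fs_beh must be positive")
    if duration < 1.0 / fs_beh:
        raise ValueError("duration shorter than one behavior sample")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs_beh))
    dt = 1.0 / fs_beh
    # per-component stationary sd for the requested Rayleigh mean speed
    sd = mean_speed / np.sqrt(np.pi / 2.0)
    theta = 1.0 / tau
    sigma = sd * np.sqrt(2.0 * theta)

    pos = np.empty((n, 2))
    vel = np.zeros(2) if sigma == 0 else rng.normal(0, sd, size=2)
    p = np.array([rng.uniform(0, arena.width), rng.uniform(0, arena.height)])
    hd = np.empty(n)
    speed = np.empty(n)
    last_hd = 0.0
    lims = np.array([arena.width, arena.height])
    for i in range(n):
        pos[i] = p
        s = float(np.hypot(*vel))
        speed[i] = s
        if s > 1e-9:
            last_hd = float(np.arctan2(vel[1], vel[0]))
        hd[i] = last_hd
        vel = vel + (-theta * vel) * dt + sigma * np.sqrt(dt) * rng.standard_normal(2)
        p = p + vel * dt
        # reflect at walls
        for ax in range(2):
            if p[ax] < 0:
                p[ax] = -p[ax]
                vel[ax] = -vel[ax]
            elif p[ax] > lims[ax]:
                p[ax] = 2 * lims[ax] - p[ax]
                vel[ax] = -vel[ax]
            p[ax] = min(max(p[ax], 0.0), lims[ax])
    return BehaviorSeries(fs=fs_beh, position=pos, head_direction=hd, speed=speed)


def make_spike_template(
    kind: str, fs: float, amplitude: float = 1.0
) -> np.ndarray:
    """Biphasic extracellular spike: narrow negative trough + broad rebound.

    The template is exactly zero-mean so its spectral energy is band-passed;
    trough width controls which wavelet band dominates.
    """
    sigma_ms = (
        PLACE_TROUGH_SIGMA_MS if kind == "place" else INTERNEURON_TROUGH_SIGMA_MS
    )
    s = sigma_ms / 1000.0
    if s * fs < 0.5:
        # trough narrower than the sampling grid: a sampled Gaussian would
        # degenerate into a broadband impulse. Use the discrete high-pass
        # kernel instead — energy concentrated at the highest representable
        # band, away from the broad place-spike bands.
        return amplitude * np.array([0.5, -1.0, 0.5])
    s2 = REBOUND_WIDTH_RATIO * s
    d = 2.0 * s
    half = max(int(np.ceil((4 * s2 + d) * fs)), 2)
    t = (np.arange(2 * half + 1) - half) / fs
    w = -np.exp(-(t**2) / (2 * s**2)) + (s / s2) * np.exp(
        -((t - d) ** 2) / (2 * s2**2)
    )
    w -= w.mean()
    return amplitude * w / np.abs(w).max()


def generate_units(
    n_place: int,
    n_interneuron: int,
    arena: Arena,
    seed: int = 0,
    fs_neural: float = 30000.0,
    n_channels: int = 4,
    hd_fraction: float = 0.5,
    hd_kappa: float = 2.0,
    place_peak_rate: tuple[float, float] = (8.0, 20.0),
    interneuron_rate: tuple[float, float] = (6.0, 12.0),
) -> list[UnitSpec]:
    """Draw unit specifications: uniform place fields, tetrode-like gains.

    ``hd_fraction`` of interneurons receive von-Mises head-direction
    modulation of strength ``hd_kappa``.
    """
    if n_place < 0 or n_interneuron < 0:
        raise ValueError("unit counts must be nonnegative")
    rng = np.random.default_rng(seed)
    units: list[UnitSpec] = []
    for _ in range(n_place):
        centre = (rng.uniform(0, arena.width), rng.uniform(0, arena.height))
        weights = np.full(n_channels, 0.05)
        weights[rng.integers(n_channels)] = 1.0
        units.append(
            UnitSpec(
                kind="place",
                field_centre=centre,
                field_width=rng.uniform(12.0, 20.0),
                peak_rate=rng.uniform(*place_peak_rate),
                baseline_rate=0.1,
                waveform=make_spike_template("place", fs_neural, rng.uniform(0.8, 1.2)),
                channel_weights=weights,
            )
        )
    for j in range(n_interneuron):
        modulated = rng.uniform() < hd_fraction
        base = rng.uniform(*interneuron_rate)
        weights = np.full(n_channels, 0.05)
        weights[rng.integers(n_channels)] = 1.0
        units.append(
            UnitSpec(
                kind="interneuron",
                field_centre=None,
                peak_rate=base * 2.0 if modulated else base,
                baseline_rate=base,
                hd_preference=float(rng.uniform(-np.pi, np.pi)) if modulated else None,
                hd_kappa=hd_kappa if modulated else 0.0,
                waveform=make_spike_template(
                    "interneuron", fs_neural, rng.uniform(0.6, 1.0)
                ),
                channel_weights=weights,
            )
        )
    return units


def _unit_rate(unit: UnitSpec, behavior: BehaviorSeries) -> np.ndarray:
    """Instantaneous firing rate (Hz) at each behavior sample."""
    rate = np.full(behavior.n_samples, float(unit.baseline_rate))
    drive = unit.peak_rate - unit.baseline_rate
    if unit.kind == "place" and unit.field_centre is not None:
        d2 = ((behavior.position - np.asarray(unit.field_centre)) ** 2).sum(axis=1)
        rate = rate + drive * np.exp(-d2 / (2.0 * unit.field_width**2))
    elif unit.hd_kappa > 0 and unit.hd_preference is not None:
        vm = np.exp(
            unit.hd_kappa * (np.cos(behavior.head_direction - unit.hd_preference) - 1.0)
        )
        rate = rate + drive * vm
    return rate


def _poisson_times(
    rate: np.ndarray, fs_beh: float, duration: float, rng: np.random.Generator
) -> np.ndarray:
    """Inhomogeneous Poisson spike times by thinning a homogeneous process."""
    rmax = float(rate.max())
    if rmax <= 0:
        return np.empty(0)
    n = rng.poisson(rmax * duration)
    t = np.sort(rng.uniform(0, duration, size=n))
    r_at = np.interp(t, np.arange(len(rate)) / fs_beh, rate)
    keep = rng.uniform(0, rmax, size=n) < r_at
    return t[keep]


def synthesize_recording(
    units: list[UnitSpec],
    behavior: BehaviorSeries,
    fs_neural: float,
    n_channels: int,
    noise_sd: float = 0.2,
    theta: ThetaParams = ThetaParams(),
    seed: int = 0,
    duration: float | None = None,
) -> tuple[WidebandRecording, UnitCatalog]:
    """Render spikes, theta and noise into a multichannel voltage matrix.

    Each unit fires as an inhomogeneous Poisson process driven by its place
    field and/or head-direction tuning; its template is added at every spike
    time scaled by its per-channel gains. A theta sinusoid with instantaneous
    frequency ``f0 + speed_gain * speed`` rides on all channels, plus white
    noise of ``noise_sd``. The returned catalog records exact spike times.
    """
    if duration is None:
        duration = behavior.duration
    if duration > behavior.duration + 1e-9:
        raise ValueError("behavior does not cover the requested recording duration")
    rng = np.random.default_rng(seed)
    n_samp = int(round(duration * fs_neural))
    data = np.zeros((n_channels, n_samp))

    spike_times: list[np.ndarray] = []
    for k, unit in enumerate(units):
        if len(unit.channel_weights) != n_channels:
            raise ValueError("unit channel_weights do not match n_channels")
        rate = _unit_rate(unit, behavior)
        times = _poisson_times(rate, behavior.fs, duration, rng)
        spike_times.append(times)
        wf = unit.waveform
        half = len(wf) // 2
        idx = np.round(times * fs_neural).astype(int)
        for i in idx:
            lo, hi = i - half, i - half + len(wf)
            wlo, whi = max(0, -lo), len(wf) - max(0, hi - n_samp)
            lo, hi = max(lo, 0), min(hi, n_samp)
            if lo >= hi:
                continue
            seg = wf[wlo:whi]
            for c in range(n_channels):
                data[c, lo:hi] += unit.channel_weights[c] * seg

    if theta.amplitude > 0:
        inst_f = theta.f0 + theta.speed_gain * np.interp(
            np.arange(n_samp) / fs_neural, behavior.timestamps, behavior.speed
        )
        phase = 2.0 * np.pi * np.cumsum(inst_f) / fs_neural
        data += theta.amplitude * np.sin(phase)[None, :]

    if noise_sd > 0:
        data += rng.normal(0, noise_sd, size=data.shape)

    catalog = UnitCatalog(
        spike_times=spike_times,
        labels=[u.kind for u in units],
        waveforms=[u.waveform for u in units],
        units=list(units),
    )
    return WidebandRecording(data, fs=fs_neural), catalog


def synthetic_wavelet_tensor(
    bank,
    n_samples: int,
    fs_effective: float = 30.0,
    n_channels: int = 4,
    seed: int = 0,
    sigma_log: float = 0.5,
    cycles_smoothing: float = 10.0,
) -> WaveletTensor:
    """Magnitude tensor with realistic band statistics but no planted signal.

    Each band's coefficient series is a lognormal amplitude envelope whose
    temporal correlation follows the band's own timescale (an AR(1) with time
    constant ``cycles_smoothing / f``, capped at the session length) and
    whose mean amplitude falls off as 1/sqrt(f) — slow LFP-like bands are
    smooth and large, spike-band coefficients are fast and spiky, as in
    wavelet transforms of real wide-band recordings.
    """
    rng = np.random.default_rng(seed)
    n_bands = bank.n_bands
    values = np.empty((n_samples, n_bands, n_channels), dtype=np.float32)
    dt = 1.0 / fs_effective
    for j, f in enumerate(bank.centre_frequencies):
        tau = min(cycles_smoothing / f, n_samples * dt / 4.0)
        rho = np.exp(-dt / max(tau, dt / 10.0))
        g = rng.standard_normal((n_samples, n_channels))
        if rho > 0:  # AR(1) envelope driver at unit stationary variance
            g = lfilter([np.sqrt(1 - rho**2)], [1.0, -rho], g, axis=0)
        amp = 1.0 / np.sqrt(f)
        values[:, j, :] = amp * np.exp(sigma_log * g)
    return WaveletTensor(values, fs_effective=fs_effective, bank=bank)


def apply_sim_behavior_modulation(
    tensor: WaveletTensor, mod: SimBehaviorModulation
) -> tuple[WaveletTensor, np.ndarray]:
    """Replace chosen bands by ``coeff * beta * y_sb(t)``; return the target.

    ``y_sb`` is uniform noise on (``y_sb_low``, 1] drawn from ``mod.seed``
    unless supplied. Only the listed bands change; ``y_sb`` is broadcast
    across channels within each band.
    """
    idx = {f: tensor.bank.band_index(f) for f in mod.band_betas}  # KeyError if unknown
    if mod.y_sb is None:
        rng = np.random.default_rng(mod.seed)
        y_sb = mod.y_sb_low + (1.0 - mod.y_sb_low) * rng.uniform(
            size=tensor.n_samples
        )
    else:
        y_sb = np.asarray(mod.y_sb, dtype=float)
        if len(y_sb) != tensor.n_samples:
            raise ValueError("y_sb length must match tensor time axis")
    values = tensor.values.copy()
    for f, beta in mod.band_betas.items():
        j = idx[f]
        values[:, j, :] = values[:, j, :] * (beta * y_sb)[:, None]
    out = replace(tensor, values=values)
    return out, y_sb
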