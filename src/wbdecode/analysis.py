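"""Conventional neural analyses used to corroborate what the decoder finds.

* waveform-based interneuron classification (narrow half-width, small
  rebound/trough ratio, high rate, unstable spatial map);
* head-direction modulation: occupancy-normalized polar ratemap, KL
  divergence against the uniform circle with a circular-shift shuffle null,
  plus a first-half/second-half stability test — a unit counts as modulated
  only when both p-values beat 0.01;
* per-band power vs running-speed correlation;
* sharp-wave ripple detection (150-250 Hz band-pass envelope, 5 SD seed /
  0.5 SD expansion, >= 60 ms, stationary);
* replay-trajectory statistics (decode error, path length, coherence
  deviation from a degree-2 polynomial) with a 1000-fold event-permutation
  null restricted to stationary periods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from scipy.signal import butter, hilbert, sosfiltfilt

from .core import Arena, BehaviorSeries, UnitCatalog
from .preprocessing import WaveletTensor

__all__ = [
    "InterneuronCriteria",
    "classify_interneurons",
    "waveform_half_width",
    "hd_modulation",
    "band_speed_correlation",
    "RippleEvent",
    "detect_ripples",
    "TrajectoryStats",
    "replay_stats",
]


# --------------------------------------------------------------------------
# interneuron classification


@dataclass(frozen=True)
class InterneuronCriteria:
    max_half_width_ms: float = 0.15
    max_amp_trough_ratio: float = 0.4
    min_rate_hz: float = 4.0
    max_spatial_stability: float = 0.75


def waveform_half_width(waveform: np.ndarray, fs: float) -> float:
    """Trough width (ms) at half of the trough depth, by linear interpolation."""
    w = np.asarray(waveform, dtype=float)
    i0 = int(np.argmin(w))
    half = w[i0] / 2.0  # negative
    left = i0
    while left > 0 and w[left] < half:
        left -= 1
    right = i0
    while right < len(w) - 1 and w[right] < half:
        right += 1

    def _cross(a, b):  # fractional index where w crosses `half` between a,b
        if w[b] == w[a]:
            return float(b)
        return a + (half - w[a]) / (w[b] - w[a])

    lo = _cross(left, left + 1) if w[left] >= half else float(left)
    hi = _cross(right, right - 1) if w[right] >= half else float(right)
    return abs(hi - lo) / fs * 1000.0


def _spatial_stability(
    times: np.ndarray, behavior: BehaviorSeries, arena: Arena, bin_size: float = 8.0
) -> float:
    """Pearson r between ratemaps from the first and second half of the session."""
    half_t = behavior.duration / 2.0
    maps = []
    nx = max(int(np.ceil(arena.width / bin_size)), 2)
    ny = max(int(np.ceil(arena.height / bin_size)), 2)
    edges = [np.arange(nx + 1) * bin_size, np.arange(ny + 1) * bin_size]
    for lo, hi in ((0.0, half_t), (half_t, behavior.duration)):
        m = (behavior.timestamps >= lo) & (behavior.timestamps < hi)
        occ, _, _ = np.histogram2d(
            behavior.position[m, 0], behavior.position[m, 1], bins=edges
        )
        sel = times[(times >= lo) & (times < hi)]
        j = np.clip(np.round(sel * behavior.fs).astype(int), 0, behavior.n_samples - 1)
        cnt, _, _ = np.histogram2d(
            behavior.position[j, 0], behavior.position[j, 1], bins=edges
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            r = gaussian_filter(cnt, 1.0) / gaussian_filter(occ / behavior.fs, 1.0)
        r[~np.isfinite(r)] = 0.0
        maps.append(r.ravel())
    a, b = maps
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def classify_interneurons(
    units: UnitCatalog,
    behavior: BehaviorSeries,
    arena: Arena,
    fs_waveform: float,
    criteria: InterneuronCriteria = InterneuronCriteria(),
) -> list[bool]:
    """True per unit iff all four interneuron criteria hold.

    Criteria: trough half-width < 0.15 ms, rebound/trough amplitude ratio
    <= 0.4, session mean rate >= 4 Hz, first/second-half spatial-map
    correlation <= 0.75. Units with missing waveforms are skipped (False)
    with a warning.
    """
    out = []
    for times, wf in zip(units.spike_times, units.waveforms):
        if wf is None or len(wf) == 0:
            warnings.warn("unit skipped: missing waveform")
            out.append(False)
            continue
        hw = waveform_half_width(wf, fs_waveform)
        ratio = float(wf.max() / -wf.min()) if wf.min() < 0 else np.inf
        rate = len(times) / behavior.duration
        stab = _spatial_stability(np.asarray(times), behavior, arena)
        out.append(
            hw < criteria.max_half_width_ms
            and ratio <= criteria.max_amp_trough_ratio
            and rate >= criteria.min_rate_hz
            and stab <= criteria.max_spatial_stability
        )
    return out


# --------------------------------------------------------------------------
# head-direction modulation


def _polar_prob(
    angles: np.ndarray, occ_angles: np.ndarray, n_bins: int, smooth: float = 1.0
) -> np.ndarray:
    """Occupancy-normalized angular rate, as a probability over bins."""
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    occ, _ = np.histogram(occ_angles, bins=edges)
    cnt, _ = np.histogram(angles, bins=edges)
    occ_s = gaussian_filter1d(occ.astype(float), smooth, mode="wrap")
    cnt_s = gaussian_filter1d(cnt.astype(float), smooth, mode="wrap")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cnt_s / occ_s
    r[~np.isfinite(r)] = 0.0
    s = r.sum()
    return r / s if s > 0 else np.full(n_bins, 1.0 / n_bins)


def _kl_vs_uniform(p: np.ndarray) -> float:
    n = len(p)
    nz = p > 0
    return float((p[nz] * np.log(p[nz] * n)).sum())


def hd_modulation(
    spike_times: np.ndarray,
    behavior: BehaviorSeries,
    arena: Arena | None = None,
    speed_min: float = 10.0,
    margin_long: float = 25.0,
    margin_short: float = 20.0,
    n_bins: int = 36,
    n_shuffles: int = 1000,
    min_shift_s: float = 20.0,
    min_spikes: int = 100,
    seed: int = 0,
) -> dict:
    """Head-direction tuning strength and significance for one unit.

    Only motion samples (speed > ``speed_min``) in the arena centre
    (``margin_long`` cm from the long walls, ``margin_short`` cm from the
    short walls) enter the polar ratemap. The null distribution circularly
    shifts the spike train by >= ``min_shift_s`` uniform offsets. The unit is
    ``significant`` iff both the KL shuffle p and the stability shuffle p
    beat 0.01.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    rng = np.random.default_rng(seed)
    mask = behavior.speed > speed_min
    if arena is not None:
        x, y = behavior.position[:, 0], behavior.position[:, 1]
        # long walls run along the width; distance from them is in y
        mask &= (y > margin_long) & (y < arena.height - margin_long)
        mask &= (x > margin_short) & (x < arena.width - margin_short)
    occ_angles = behavior.head_direction[mask]

    n = behavior.n_samples
    duration = behavior.duration
    half_mask = behavior.timestamps < duration / 2.0

    def _unit_stats(times: np.ndarray) -> tuple[float, float]:
        j = np.clip(np.round(times * behavior.fs).astype(int), 0, n - 1)
        ok = mask[j]
        ang = behavior.head_direction[j[ok]]
        p = _polar_prob(ang, occ_angles, n_bins)
        kl = _kl_vs_uniform(p)
        j1 = j[ok & half_mask[j]]
        j2 = j[ok & ~half_mask[j]]
        p1 = _polar_prob(behavior.head_direction[j1], behavior.head_direction[mask & half_mask], n_bins)
        p2 = _polar_prob(behavior.head_direction[j2], behavior.head_direction[mask & ~half_mask], n_bins)
        if p1.std() == 0 or p2.std() == 0:
            return kl, 0.0
        return kl, float(np.corrcoef(p1, p2)[0, 1])

    j_all = np.clip(np.round(spike_times * behavior.fs).astype(int), 0, n - 1)
    n_valid = int(mask[j_all].sum())
    if n_valid < min_spikes:
        return {
            "kl": np.nan,
            "kl_p": np.nan,
            "stability_r": np.nan,
            "stability_p": np.nan,
            "significant": False,
            "n_spikes": n_valid,
            "insufficient": True,
        }

    kl_obs, stab_obs = _unit_stats(spike_times)
    shifts = rng.uniform(min_shift_s, duration - min_shift_s, size=n_shuffles)
    kl_null = np.empty(n_shuffles)
    stab_null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        shifted = np.mod(spike_times + shifts[s], duration)
        kl_null[s], stab_null[s] = _unit_stats(shifted)
    kl_p = (1 + np.sum(kl_null >= kl_obs)) / (1 + n_shuffles)
    stab_p = (1 + np.sum(stab_null >= stab_obs)) / (1 + n_shuffles)
    return {
        "kl": kl_obs,
        "kl_p": float(kl_p),
        "stability_r": stab_obs,
        "stability_p": float(stab_p),
        "significant": bool(kl_p < 0.01 and stab_p < 0.01),
        "n_spikes": n_valid,
        "insufficient": False,
    }


# --------------------------------------------------------------------------
# band power vs speed


def band_speed_correlation(
    tensor: WaveletTensor, behavior: BehaviorSeries
) -> np.ndarray:
    """Pearson r between channel-averaged band power and running speed."""
    power = tensor.values.mean(axis=2)  # (time, bands)
    speed = behavior.speed
    if len(speed) != tensor.n_samples:
        t_eff = np.arange(tensor.n_samples) / tensor.fs_effective
        speed = np.interp(t_eff, behavior.timestamps, speed)
    out = np.empty(tensor.bank.n_bands)
    sc = speed - speed.mean()
    denom_s = np.sqrt((sc**2).sum())
    for j in range(tensor.bank.n_bands):
        pc = power[:, j] - power[:, j].mean()
        denom_p = np.sqrt((pc**2).sum())
        out[j] = (pc * sc).sum() / (denom_p * denom_s) if denom_p > 0 and denom_s > 0 else 0.0
    return out


# --------------------------------------------------------------------------
# ripples


@dataclass(frozen=True)
class RippleEvent:
    start: float  # s
    end: float
    peak_power: float  # SD units of the smoothed envelope
    stationary: bool

    @property
    def duration(self) -> float:
        return self.end - self.start


def detect_ripples(
    lfp: np.ndarray,
    fs: float,
    speed: np.ndarray | None = None,
    fs_beh: float | None = None,
    band: tuple[float, float] = (150.0, 250.0),
    seed_sd: float = 5.0,
    edge_sd: float = 0.5,
    min_duration: float = 0.060,
    smooth_s: float = 0.010,
    stationary_speed: float = 3.0,
) -> list[RippleEvent]:
    """Sharp-wave ripple events from one LFP channel.

    Band-pass 150-250 Hz -> Hilbert envelope -> 10-ms Gaussian smoothing ->
    z-score. Events seed where power exceeds 5 SD, expand to the 0.5 SD
    crossings, and are kept when >= 60 ms long and (if a speed series is
    given) the animal is below the stationary threshold throughout.
    Thresholds are SD-relative, so detection is invariant to LFP gain.
    """
    if fs < 600:
        raise ValueError("sampling rate too low for the 150-250 Hz ripple band")
    lfp = np.asarray(lfp, dtype=float)
    sos = butter(4, band, btype="bandpass", fs=fs, output="sos")
    filt = sosfiltfilt(sos, lfp)
    env = np.abs(hilbert(filt))
    env = gaussian_filter1d(env, smooth_s * fs)
    z = (env - env.mean()) / env.std()

    above_seed = z >= seed_sd
    if not above_seed.any():
        return []
    below_edge = z < edge_sd
    events: list[RippleEvent] = []
    i = 0
    n = len(z)
    seeds = np.flatnonzero(above_seed)
    last_end = -1
    for s in seeds:
        if s < last_end:
            continue
        lo = s
        while lo > 0 and not below_edge[lo - 1]:
            lo -= 1
        hi = s
        while hi < n - 1 and not below_edge[hi + 1]:
            hi += 1
        last_end = hi + 1
        dur = (hi - lo + 1) / fs
        if dur < min_duration:
            continue
        stationary = True
        if speed is not None:
            fb = fs_beh if fs_beh is not None else fs
            j0 = int(lo / fs * fb)
            j1 = max(int(hi / fs * fb) + 1, j0 + 1)
            seg = np.asarray(speed)[j0:j1]
            stationary = bool(seg.size == 0 or seg.max() < stationary_speed)
        if stationary:
            events.append(
                RippleEvent(
                    start=lo / fs,
                    end=(hi + 1) / fs,
                    peak_power=float(z[lo : hi + 1].max()),
                    stationary=stationary,
                )
            )
    return events


# --------------------------------------------------------------------------
# replay trajectory statistics


@dataclass
class TrajectoryStats:
    mean_error: float  # cm
    path_length: float  # cm
    coherence_deviation: float  # cm
    p_values: dict[str, float]
    n_permutations: int


def _traj_measures(
    pts: np.ndarray, true_pts: np.ndarray
) -> tuple[float, float, float]:
    err = float(np.sqrt(((pts - true_pts) ** 2).sum(axis=1)).mean())
    length = float(np.sqrt((np.diff(pts, axis=0) ** 2).sum(axis=1)).sum())
    t = np.arange(len(pts), dtype=float)
    if len(pts) >= 3:
        fit = np.stack(
            [np.polyval(np.polyfit(t, pts[:, d], 2), t) for d in range(2)], axis=1
        )
        coh = float(np.sqrt(((pts - fit) ** 2).sum(axis=1)).mean())
    else:
        coh = 0.0
    return err, length, coh


def replay_stats(
    decoded: np.ndarray,
    fs_decoded: float,
    events: list[RippleEvent],
    behavior: BehaviorSeries,
    n_permutations: int = 1000,
    stationary_speed: float = 3.0,
    seed: int = 0,
) -> TrajectoryStats:
    """Replay measures for decoded trajectories during candidate events.

    Per event: mean Euclidean decode error, summed path length, and
    coherence deviation (mean distance to a degree-2 polynomial fitted over
    the event). The null permutes event placements in time (lengths kept)
    over stationary periods, ``n_permutations`` times. One-sided p-values:
    error and length test for event measures exceeding the null; coherence
    tests for the events being at least as coherent (deviation not larger).
    """
    decoded = np.asarray(decoded, dtype=float)
    t_dec = np.arange(len(decoded)) / fs_decoded
    true_x = np.interp(t_dec, behavior.timestamps, behavior.position[:, 0])
    true_y = np.interp(t_dec, behavior.timestamps, behavior.position[:, 1])
    truth = np.stack([true_x, true_y], axis=1)
    speed_dec = np.interp(t_dec, behavior.timestamps, behavior.speed)

    def _measures_at(slices: list[slice]) -> tuple[float, float, float]:
        ms = np.array(
            [_traj_measures(decoded[s], truth[s]) for s in slices if (s.stop - s.start) >= 2]
        )
        return tuple(ms.mean(axis=0)) if len(ms) else (np.nan, np.nan, np.nan)

    ev_slices = [
        slice(int(e.start * fs_decoded), max(int(e.end * fs_decoded), int(e.start * fs_decoded) + 2))
        for e in events
    ]
    obs = _measures_at(ev_slices)

    lengths = [s.stop - s.start for s in ev_slices]
    stationary = speed_dec < stationary_speed
    rng = np.random.default_rng(seed)
    max_len = max(lengths) if lengths else 2
    # candidate starts: event fully inside a stationary stretch
    ok = np.flatnonzero(
        np.convolve(stationary.astype(int), np.ones(max_len, dtype=int), "valid")
        == max_len
    )
    if len(ok) == 0:
        warnings.warn("no stationary placements; permuting over the whole series")
        ok = np.arange(max(len(decoded) - max_len, 1))
    elif len(ok) < n_permutations:
        warnings.warn(
            f"only {len(ok)} valid placements for {n_permutations} permutations; "
            "p-value resolution degraded"
        )
    null = np.empty((n_permutations, 3))
    for p in range(n_permutations):
        starts = rng.choice(ok, size=len(lengths), replace=True)
        null[p] = _measures_at([slice(int(s0), int(s0) + L) for s0, L in zip(starts, lengths)])
    p_err = (1 + np.sum(null[:, 0] >= obs[0])) / (1 + n_permutations)
    p_len = (1 + np.sum(null[:, 1] >= obs[1])) / (1 + n_permutations)
    p_coh = (1 + np.sum(null[:, 2] <= obs[2])) / (1 + n_permutations)
    return TrajectoryStats(
        mean_error=obs[0],
        path_length=obs[1],
        coherence_deviation=obs[2],
        p_values={"error": float(p_err), "length": float(p_len), "coherence": float(p_coh)},
        n_permutations=n_permutations,
    )
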