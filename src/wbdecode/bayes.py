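"""Poisson Bayesian decoding from spike times — the classical comparison.

Per-unit ratemaps are built on 2-cm spatial bins (Gaussian-smoothed counts
over Gaussian-smoothed occupancy, sigma = 1.5 bins), restricted to training
time and to movement above a speed threshold (3 cm/s). Decoding evaluates,
per 0.5-s window with spike counts K = (k_1..k_N),

    P(x | K)  propto  P(x) * prod_i alpha_i(x)^k_i * exp(-T * sum_i alpha_i(x))

in log space, normalizes over visited bins, and takes the argmax bin centre.
An optional continuity prior multiplies the posterior with a Gaussian centred
on the previous decoded position whose width sigma_t = v_t * V tracks the
speed of the previous four decoded steps (floored at one bin so it never
collapses to a delta when the decoder stalls).

The same machinery decodes head direction on angular bins with circular
error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from scipy.special import logsumexp

from .core import Arena, BehaviorSeries, UnitCatalog
from .training import CVPlan

__all__ = [
    "Ratemap",
    "DecodeWindow",
    "ContinuityPrior",
    "build_ratemaps",
    "posterior",
    "continuity_weight",
    "decode_session",
    "PolarRatemapSet",
    "build_polar_ratemaps",
    "decode_session_hd",
]


@dataclass
class Ratemap:
    """Per-unit firing-rate maps plus the occupancy prior on a 2-D grid."""

    rates: np.ndarray  # (n_units, nx, ny), Hz
    occupancy_p: np.ndarray  # (nx, ny), sums to 1 over visited bins
    visited: np.ndarray  # (nx, ny) bool
    x_centres: np.ndarray
    y_centres: np.ndarray
    bin_size: float

    @property
    def n_units(self) -> int:
        return len(self.rates)


@dataclass(frozen=True)
class DecodeWindow:
    """Spike counts of every unit within one decoding bin of length T (s)."""

    T: float
    counts: np.ndarray

    def __post_init__(self) -> None:
        k = np.asarray(self.counts)
        if self.T <= 0:
            raise ValueError("window length must be positive")
        if np.any(k < 0) or not np.issubdtype(k.dtype, np.integer):
            raise ValueError("counts must be nonnegative integers")


@dataclass(frozen=True)
class ContinuityPrior:
    V: float = 1.0  # seconds; sigma_t = v_t * V
    speed_window: int = 4  # previous decoded steps used to estimate v_t
    sigma_floor: float = 2.0  # cm, one bin


def build_ratemaps(
    spikes: UnitCatalog,
    behavior: BehaviorSeries,
    arena: Arena,
    train_mask: np.ndarray | None = None,
    speed_threshold: float = 3.0,
    bin_size: float = 2.0,
    smoothing_sigma: float = 1.5,
) -> Ratemap:
    """Smoothed rate = smoothed spike counts / smoothed occupancy per 2-cm bin."""
    if train_mask is None:
        train_mask = np.ones(behavior.n_samples, dtype=bool)
    train_mask = np.asarray(train_mask, dtype=bool)
    if not train_mask.any():
        raise ValueError("train_mask selects no behavior samples")
    use = train_mask & (behavior.speed > speed_threshold)
    if not use.any():
        raise ValueError("no moving training samples; all bins unvisited")

    nx = max(int(np.ceil(arena.width / bin_size)), 1)
    ny = max(int(np.ceil(arena.height / bin_size)), 1)
    x_edges = np.arange(nx + 1) * bin_size
    y_edges = np.arange(ny + 1) * bin_size
    dt = 1.0 / behavior.fs

    occ, _, _ = np.histogram2d(
        behavior.position[use, 0], behavior.position[use, 1], bins=[x_edges, y_edges]
    )
    occ *= dt
    visited = occ > 0
    if not visited.any():
        raise ValueError("all bins unvisited")
    occ_s = gaussian_filter(occ, smoothing_sigma)

    t_beh = behavior.timestamps
    rates = np.empty((spikes.n_units, nx, ny))
    for i, times in enumerate(spikes.spike_times):
        if len(times):
            j = np.clip(np.round(times * behavior.fs).astype(int), 0, behavior.n_samples - 1)
            ok = use[j]
            sx = behavior.position[j[ok], 0]
            sy = behavior.position[j[ok], 1]
            cnt, _, _ = np.histogram2d(sx, sy, bins=[x_edges, y_edges])
        else:
            cnt = np.zeros((nx, ny))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = gaussian_filter(cnt, smoothing_sigma) / occ_s
        r[~np.isfinite(r)] = 0.0
        r[~visited] = 0.0
        rates[i] = r

    p = np.where(visited, occ, 0.0)
    p = p / p.sum()
    return Ratemap(
        rates=rates,
        occupancy_p=p,
        visited=visited,
        x_centres=(x_edges[:-1] + x_edges[1:]) / 2,
        y_centres=(y_edges[:-1] + y_edges[1:]) / 2,
        bin_size=bin_size,
    )


def _log_posterior_grid(counts: np.ndarray, maps: Ratemap, T: float) -> np.ndarray:
    """Unnormalized log posterior over bins; unvisited bins are -inf."""
    k = np.asarray(counts, dtype=float)
    if k.shape != (maps.n_units,):
        raise ValueError("counts do not align with the ratemap's units")
    alpha = maps.rates  # (N, nx, ny)
    with np.errstate(divide="ignore"):
        log_alpha = np.log(alpha)
        log_p = np.log(maps.occupancy_p)
    with np.errstate(invalid="ignore"):  # 0 * -inf handled by the where
        term = np.where(k[:, None, None] > 0, k[:, None, None] * log_alpha, 0.0)
    term = np.nan_to_num(term, nan=0.0, posinf=np.inf, neginf=-np.inf)
    logpost = log_p + term.sum(axis=0) - T * alpha.sum(axis=0)
    logpost[~maps.visited] = -np.inf
    return logpost


def posterior(window: DecodeWindow, maps: Ratemap) -> np.ndarray:
    """Normalized posterior probability per spatial bin (sums to 1)."""
    lp = _log_posterior_grid(np.asarray(window.counts), maps, window.T)
    finite = np.isfinite(lp)
    if not finite.any():
        warnings.warn("posterior underflow; falling back to uniform over visited bins")
        out = maps.visited / maps.visited.sum()
        return out
    z = logsumexp(lp[finite])
    out = np.zeros_like(lp)
    out[finite] = np.exp(lp[finite] - z)
    return out


def continuity_weight(
    x: np.ndarray, x_prev: np.ndarray, sigma_t: float
) -> np.ndarray:
    """Gaussian continuity factor exp(-||x - x_prev||^2 / (2 sigma_t^2))."""
    d2 = ((np.asarray(x, dtype=float) - np.asarray(x_prev, dtype=float)) ** 2).sum(
        axis=-1
    )
    return np.exp(-d2 / (2.0 * sigma_t**2))


def _window_counts(
    spikes: UnitCatalog, t0: float, t1: float
) -> np.ndarray:
    return np.array(
        [
            np.searchsorted(t, t1) - np.searchsorted(t, t0)
            for t in spikes.spike_times
        ]
    )


def decode_session(
    spikes: UnitCatalog,
    behavior: BehaviorSeries,
    arena: Arena,
    plan: CVPlan,
    T_bin: float = 0.5,
    use_continuity: bool = False,
    prior: ContinuityPrior = ContinuityPrior(),
    speed_threshold: float = 3.0,
    bin_size: float = 2.0,
    smoothing_sigma: float = 1.5,
) -> dict:
    """Cross-validated sequential decoding of position over all folds.

    The plan's sample indexing must match the behavior rate. For each fold
    the ratemaps are fitted on the training region only; the test block is
    tiled with non-overlapping windows of ``T_bin`` seconds, each decoded to
    the argmax bin centre (ties -> first bin index). Reports true and decoded
    positions and Euclidean errors, restricted to windows whose true speed
    exceeds ``speed_threshold``.
    """
    fs = behavior.fs
    decoded, truth, errors, fold_ids = [], [], [], []
    for fold in range(plan.n_partitions):
        maps = build_ratemaps(
            spikes,
            behavior,
            arena,
            plan.train_mask(fold),
            speed_threshold,
            bin_size,
            smoothing_sigma,
        )
        start, end = plan.bounds[fold]
        n_win = int((end - start) / fs / T_bin)
        xc, yc = np.meshgrid(maps.x_centres, maps.y_centres, indexing="ij")
        prev: list[np.ndarray] = []
        for w in range(n_win):
            t0 = start / fs + w * T_bin
            t1 = t0 + T_bin
            k = _window_counts(spikes, t0, t1)
            lp = _log_posterior_grid(k, maps, T_bin)
            if use_continuity and prev:
                v_t = _recent_speed(prev, T_bin, prior.speed_window)
                sigma_t = max(v_t * prior.V, prior.sigma_floor)
                w_cont = -((xc - prev[-1][0]) ** 2 + (yc - prev[-1][1]) ** 2) / (
                    2.0 * sigma_t**2
                )
                lp = lp + w_cont
            flat = np.argmax(lp)  # ties -> first bin index
            i, j = np.unravel_index(flat, lp.shape)
            est = np.array([maps.x_centres[i], maps.y_centres[j]])
            prev.append(est)

            sl = slice(int(t0 * fs), int(t1 * fs))
            true_pos = behavior.position[sl].mean(axis=0)
            true_speed = behavior.speed[sl].mean()
            if true_speed > speed_threshold:
                decoded.append(est)
                truth.append(true_pos)
                errors.append(float(np.hypot(*(est - true_pos))))
                fold_ids.append(fold)
    errors = np.asarray(errors)
    return {
        "decoded": np.asarray(decoded),
        "true": np.asarray(truth),
        "errors": errors,
        "fold": np.asarray(fold_ids),
        "mean_error": float(errors.mean()) if errors.size else np.nan,
        "median_error": float(np.median(errors)) if errors.size else np.nan,
    }


def _recent_speed(prev: list[np.ndarray], T_bin: float, k: int) -> float:
    pts = np.asarray(prev[-(k + 1) :])
    if len(pts) < 2:
        return 0.0
    steps = np.sqrt(((np.diff(pts, axis=0)) ** 2).sum(axis=1))
    return float(steps.mean() / T_bin)


# --------------------------------------------------------------------------
# head-direction variant: identical Poisson machinery on angular bins


@dataclass
class PolarRatemapSet:
    rates: np.ndarray  # (n_units, n_bins), Hz
    occupancy_p: np.ndarray
    bin_centres: np.ndarray  # radians in [-pi, pi)


def build_polar_ratemaps(
    spikes: UnitCatalog,
    behavior: BehaviorSeries,
    train_mask: np.ndarray | None = None,
    n_bins: int = 36,
    smoothing_sigma: float = 1.0,
) -> PolarRatemapSet:
    if train_mask is None:
        train_mask = np.ones(behavior.n_samples, dtype=bool)
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    dt = 1.0 / behavior.fs
    occ, _ = np.histogram(behavior.head_direction[train_mask], bins=edges)
    occ = occ * dt
    occ_s = gaussian_filter1d(occ.astype(float), smoothing_sigma, mode="wrap")
    rates = np.empty((spikes.n_units, n_bins))
    for i, times in enumerate(spikes.spike_times):
        if len(times):
            j = np.clip(np.round(times * behavior.fs).astype(int), 0, behavior.n_samples - 1)
            ok = train_mask[j]
            cnt, _ = np.histogram(behavior.head_direction[j[ok]], bins=edges)
        else:
            cnt = np.zeros(n_bins)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = gaussian_filter1d(cnt.astype(float), smoothing_sigma, mode="wrap") / occ_s
        r[~np.isfinite(r)] = 0.0
        rates[i] = r
    p = occ / occ.sum() if occ.sum() > 0 else np.full(n_bins, 1.0 / n_bins)
    return PolarRatemapSet(rates=rates, occupancy_p=p, bin_centres=(edges[:-1] + edges[1:]) / 2)


def decode_session_hd(
    spikes: UnitCatalog,
    behavior: BehaviorSeries,
    plan: CVPlan,
    T_bin: float = 0.5,
    n_bins: int = 36,
) -> dict:
    """Cross-validated head-direction decoding; circular absolute error."""
    fs = behavior.fs
    errors = []
    for fold in range(plan.n_partitions):
        maps = build_polar_ratemaps(spikes, behavior, plan.train_mask(fold), n_bins)
        with np.errstate(divide="ignore"):
            log_alpha = np.log(maps.rates)
            log_p = np.log(np.where(maps.occupancy_p > 0, maps.occupancy_p, np.nan))
        start, end = plan.bounds[fold]
        n_win = int((end - start) / fs / T_bin)
        for w in range(n_win):
            t0 = start / fs + w * T_bin
            k = _window_counts(spikes, t0, t0 + T_bin)
            with np.errstate(invalid="ignore"):
                term = np.where(k[:, None] > 0, k[:, None] * log_alpha, 0.0)
            term = np.nan_to_num(term, nan=0.0, posinf=np.inf, neginf=-np.inf)
            lp = log_p + term.sum(axis=0) - T_bin * maps.rates.sum(axis=0)
            est = maps.bin_centres[np.nanargmax(lp)]
            sl = slice(int(t0 * fs), int((t0 + T_bin) * fs))
            hd = behavior.head_direction[sl]
            true_hd = np.arctan2(np.sin(hd).mean(), np.cos(hd).mean())
            d = abs(est - true_hd)
            errors.append(min(d, 2 * np.pi - d))
    errors = np.asarray(errors)
    return {
        "errors": errors,
        "mean_error": float(errors.mean()) if errors.size else np.nan,
        "median_error": float(np.median(errors)) if errors.size else np.nan,
    }
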