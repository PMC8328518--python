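"""Post-hoc interpretation of a trained decoder.

Three complementary probes of where the information lives in the
time x frequency x channel input:

* shuffle influence — permute one slice (a frequency band, a channel, or a
  within-window timepoint) across the evaluation set, re-decode without
  retraining, and report the relative error change (e_s - e_o) / e_o;
* event-locked band elimination — overwrite chosen bands with their training
  median around given spike times, to ask how much decoding rests on those
  events specifically;
* single-band models — retrain a reduced decoder per band (all other bands
  zeroed) and rank-correlate per-band performance with shuffle influence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps

from .cnn import ArchitectureSpec, TrainedDecoder, fvaf_r2, per_sample_error
from .preprocessing import WaveletTensor
from .training import (
    CVPlan,
    TrainConfig,
    extract_windows,
    run_fold,
    targets_for,
)

__all__ = [
    "InfluenceMap",
    "shuffle_influence",
    "eliminate_band_at_events",
    "single_band_models",
]


@dataclass
class InfluenceMap:
    """Relative error change per input slice, per decoded variable."""

    axis: str  # "frequency" | "channel" | "time"
    scores: dict[str, np.ndarray]  # head name -> (n_slices,) mean over repeats
    stderr: dict[str, np.ndarray]  # head name -> (n_slices,) SE over repeats
    baseline_error: dict[str, float]  # e_o per head
    n_repeats: int
    seed: int

    def top_slices(self, head: str, k: int = 2) -> np.ndarray:
        return np.argsort(self.scores[head])[::-1][:k]


def _mean_errors(decoder, windows, targets, idx) -> dict[str, float]:
    pred = decoder.predict(windows)
    return {
        h.name: float(
            per_sample_error(h.loss_tag, targets[h.name][idx], pred[h.name]).mean()
        )
        for h in decoder.spec.heads
    }


def shuffle_influence(
    decoder: TrainedDecoder,
    tensor: WaveletTensor,
    behavior,
    plan: CVPlan,
    fold: int,
    axis: str = "frequency",
    n_repeats: int = 10,
    seed: int = 0,
    joint_channels: bool = True,
    stride: int = 1,
) -> InfluenceMap:
    """Shuffle-based influence over the fold's evaluation set.

    For each index on ``axis`` the corresponding slice of the evaluation
    windows is permuted across time (jointly over channels by default),
    decoding is repeated without retraining, and the relative error change is
    averaged over ``n_repeats`` permutations. Slices that are constant in
    time have exactly zero influence.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if axis not in ("frequency", "channel", "time"):
        raise ValueError(f"unknown influence axis {axis!r}")
    rng = np.random.default_rng(seed)
    targets = targets_for(decoder.spec.heads, behavior)
    idx = plan.test_indices(fold)[::stride]
    windows = extract_windows(tensor.values, idx, plan.window)  # (n, T, F, C)
    e_o = _mean_errors(decoder, windows, targets, idx)

    n_slices = {"frequency": windows.shape[2], "channel": windows.shape[3], "time": windows.shape[1]}[axis]
    heads = [h.name for h in decoder.spec.heads]
    acc = {h: np.zeros((n_repeats, n_slices)) for h in heads}
    for r in range(n_repeats):
        for j in range(n_slices):
            shuffled = windows.copy()
            perm = rng.permutation(len(windows))
            if axis == "frequency":
                if joint_channels:
                    shuffled[:, :, j, :] = windows[perm][:, :, j, :]
                else:
                    for c in range(windows.shape[3]):
                        shuffled[:, :, j, c] = windows[rng.permutation(len(windows))][:, :, j, c]
            elif axis == "channel":
                shuffled[:, :, :, j] = windows[perm][:, :, :, j]
            else:  # within-window timepoint across evaluation windows
                shuffled[:, j, :, :] = windows[perm][:, j, :, :]
            e_s = _mean_errors(decoder, shuffled, targets, idx)
            for h in heads:
                acc[h][r, j] = (e_s[h] - e_o[h]) / max(e_o[h], 1e-12)
    scores = {h: acc[h].mean(axis=0) for h in heads}
    stderr = {
        h: acc[h].std(axis=0, ddof=1) / np.sqrt(n_repeats) if n_repeats > 1
        else np.zeros(n_slices)
        for h in heads
    }
    return InfluenceMap(
        axis=axis,
        scores=scores,
        stderr=stderr,
        baseline_error=e_o,
        n_repeats=n_repeats,
        seed=seed,
    )


def eliminate_band_at_events(
    tensor: WaveletTensor,
    band_freqs: list[float],
    event_times: np.ndarray,
    window_s: float = 0.05,
    train_mask: np.ndarray | None = None,
    mode: str = "median",
    seed: int = 0,
) -> WaveletTensor:
    """Remove power in the named bands around each event time.

    ``event_times`` is either one array (events applied to every channel) or
    a sequence of per-channel arrays (surgical per-channel elimination, as
    when each channel is scrubbed at the spike times of its own units).
    Timepoints within ``±window_s`` of an event are replaced by the band's
    per-channel training median (``mode="median"``) or by values drawn from a
    random permutation of the band (``mode="scramble"``).
    """
    band_idx = [tensor.bank.band_index(f) for f in band_freqs]
    n = tensor.n_samples
    n_chan = tensor.values.shape[2]
    if isinstance(event_times, (list, tuple)) and len(event_times) == n_chan:
        per_channel = [np.asarray(t, dtype=float) for t in event_times]
    else:
        t = np.asarray(event_times, dtype=float)
        per_channel = [t] * n_chan

    half = int(np.ceil(window_s * tensor.fs_effective))
    mask = train_mask if train_mask is not None else np.ones(n, dtype=bool)
    rng = np.random.default_rng(seed)
    values = tensor.values.copy()
    for c, times in enumerate(per_channel):
        if not times.size:
            continue
        if times.max() > n / tensor.fs_effective + 1e-6:
            raise ValueError("event time outside the session")
        centers = np.round(times * tensor.fs_effective).astype(int)
        hit = np.zeros(n, dtype=bool)
        for ctr in centers:
            hit[max(ctr - half, 0) : min(ctr + half + 1, n)] = True
        for j in band_idx:
            if mode == "median":
                fill = np.median(tensor.values[mask, j, c])
                values[hit, j, c] = fill
            elif mode == "scramble":
                donor = rng.permutation(tensor.values[:, j, c])[: hit.sum()]
                values[hit, j, c] = donor
            else:
                raise ValueError(f"unknown elimination mode {mode!r}")
    return replace(tensor, values=values)


def single_band_models(
    raw_tensor: WaveletTensor,
    behavior,
    plan: CVPlan,
    spec: ArchitectureSpec,
    cfg: TrainConfig,
    fold: int = 0,
    influence_map: InfluenceMap | None = None,
) -> dict:
    """Train one reduced decoder per band (all other bands zeroed).

    Returns per-band FVAF (first head) and, when an influence map is given,
    the Spearman rank correlation between single-band performance and
    shuffle influence.
    """
    n_bands = raw_tensor.bank.n_bands
    fvafs = np.empty(n_bands)
    head0 = spec.heads[0].name
    for j in range(n_bands):
        reduced = replace(raw_tensor, values=_keep_band(raw_tensor.values, j))
        _, _, rep = run_fold(reduced, behavior, fold, plan, spec, cfg)
        fvafs[j] = rep[head0]["fvaf"]
    out = {"fvaf": fvafs, "band_frequencies": raw_tensor.bank.centre_frequencies}
    if influence_map is not None:
        rho, p = sps.spearmanr(fvafs, influence_map.scores[head0])
        out["spearman_rho"] = float(rho)
        out["spearman_p"] = float(p)
    return out


def _keep_band(values: np.ndarray, j: int) -> np.ndarray:
    out = np.zeros_like(values)
    out[:, j, :] = values[:, j, :]
    return out
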