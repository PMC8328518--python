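"""Cross-validated training of the decoder and its chance-level baseline.

The session is split into contiguous, equal-length partitions (default 5).
For each fold, one partition is held out; training windows whose span comes
within ``gap`` seconds of the held-out block are excluded so that the 2-s
input windows can never leak across the train/test boundary. Windows are
sampled with replacement from the training region; the decoded value of a
window is assigned to its final timestep (causal alignment). Adam drives the
multi-head loss (sum of per-head losses) with a plateau schedule that scales
the learning rate by 0.2 after three epochs without validation improvement.

The chance model retrains the identical architecture after circularly
shifting the behavior by half the session relative to the tensor — the
no-information baseline used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cnn import (
    Adam,
    ArchitectureSpec,
    TrainedDecoder,
    build_decoder,
    fvaf_r2,
    loss_and_grad,
    per_sample_error,
)
from .core import BehaviorSeries
from .preprocessing import WaveletTensor, apply_mad, fit_mad

__all__ = [
    "CVPlan",
    "TrainConfig",
    "make_cv_plan",
    "targets_for",
    "extract_windows",
    "train_fold",
    "evaluate_fold",
    "chance_model",
    "shift_behavior",
]


@dataclass(frozen=True)
class CVPlan:
    """Partition boundaries plus per-fold train/test window indices.

    A "window index" is the index of the window's final timestep; the window
    spans ``[i - window + 1, i]``.
    """

    n_samples: int
    n_partitions: int
    window: int
    gap_samples: int
    bounds: tuple[tuple[int, int], ...]  # [start, end) per partition

    def test_indices(self, fold: int) -> np.ndarray:
        start, end = self.bounds[fold]
        lo = max(start, self.window - 1)
        return np.arange(lo, end)

    def train_indices(self, fold: int) -> np.ndarray:
        """Window end-indices whose span stays ``gap`` clear of the test block."""
        start, end = self.bounds[fold]
        i = np.arange(self.window - 1, self.n_samples)
        span_lo = i - self.window + 1
        # exclude any window whose [span_lo, i] intersects [start-gap, end+gap)
        bad = (i >= start - self.gap_samples) & (span_lo < end + self.gap_samples)
        return i[~bad]

    def train_mask(self, fold: int) -> np.ndarray:
        """Timestep mask of the training region (for normalization fitting)."""
        start, end = self.bounds[fold]
        m = np.ones(self.n_samples, dtype=bool)
        lo = max(start - self.gap_samples, 0)
        hi = min(end + self.gap_samples, self.n_samples)
        m[lo:hi] = False
        return m


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 7e-4
    batches_per_epoch: int = 150
    batch_size: int = 8
    epochs: int = 15
    lr_decay_factor: float = 0.2
    plateau_patience: int = 3
    window: int = 64
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batches_per_epoch, self.batch_size) <= 0:
            raise ValueError("training config values must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be nonnegative")

    @property
    def total_windows(self) -> int:
        return self.epochs * self.batches_per_epoch * self.batch_size


def make_cv_plan(
    n_samples: int,
    fs_effective: float,
    n_partitions: int = 5,
    gap_s: float = 2.0,
    window: int = 64,
) -> CVPlan:
    """Contiguous equal partitions with a gap (in seconds) around test blocks."""
    if n_partitions < 2:
        raise ValueError("need at least two partitions to hold out data")
    gap = int(round(gap_s * fs_effective))
    if n_samples <= n_partitions * (window + gap):
        raise ValueError(
            f"session of {n_samples} samples too short for "
            f"{n_partitions} partitions with window {window} and gap {gap}"
        )
    edges = np.linspace(0, n_samples, n_partitions + 1).astype(int)
    bounds = tuple((int(edges[i]), int(edges[i + 1])) for i in range(n_partitions))
    return CVPlan(
        n_samples=n_samples,
        n_partitions=n_partitions,
        window=window,
        gap_samples=gap,
        bounds=bounds,
    )


def targets_for(
    heads, behavior: BehaviorSeries | np.ndarray | dict
) -> dict[str, np.ndarray]:
    """Per-head target series aligned with the tensor's time axis."""
    if isinstance(behavior, BehaviorSeries):
        out = {}
        for h in heads:
            m = behavior.target_matrix([h.name])
            if m.shape[1] != h.output_dim:
                raise ValueError(f"head {h.name}: dim mismatch")
            out[h.name] = m
        return out
    if isinstance(behavior, dict):
        return {h.name: np.atleast_2d(np.asarray(behavior[h.name]).T).T for h in heads}
    arr = np.asarray(behavior, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if len(heads) != 1 or heads[0].output_dim != arr.shape[1]:
        raise ValueError("array target requires a single matching head")
    return {heads[0].name: arr}


def extract_windows(values: np.ndarray, end_indices: np.ndarray, window: int) -> np.ndarray:
    """Stack windows ``[i-window+1, i]`` -> (n, window, F, C)."""
    end_indices = np.asarray(end_indices)
    offs = np.arange(-window + 1, 1)
    return values[end_indices[:, None] + offs[None, :]]


def train_fold(
    decoder: TrainedDecoder,
    tensor: WaveletTensor,
    behavior: BehaviorSeries | np.ndarray | dict,
    fold: int,
    plan: CVPlan,
    cfg: TrainConfig,
) -> TrainedDecoder:
    """Train in place on the fold's training region; returns the decoder.

    ``tensor`` must already be normalized with statistics fitted on this
    fold's training region only. Reproducible for a fixed ``cfg.seed``.
    """
    if cfg.epochs == 0:
        return decoder
    if not tensor.normalized:
        raise ValueError("tensor must be MAD-normalized before training")
    spec = decoder.spec
    targets = targets_for(spec.heads, behavior)
    idx = plan.train_indices(fold)
    n_val = max(int(len(idx) * cfg.validation_fraction), 1)
    train_idx, val_idx = idx[:-n_val], idx[-n_val:]
    if len(train_idx) == 0:
        raise ValueError("no training windows left after validation split")

    rng = np.random.default_rng(cfg.seed)
    decoder._noise_rng = np.random.default_rng(cfg.seed + 1)
    # learn on standardized targets (single scalar scale per head preserves
    # Euclidean geometry); angles stay in radians
    decoder.target_transform = {}
    for h in spec.heads:
        if h.loss_tag == "cyclical_mae":
            continue
        tr = targets[h.name][idx]
        center = tr.mean(axis=0)
        scale = float(tr.std(axis=0).mean()) or 1.0
        # clamp predictions to the observed target range: linear heads can
        # extrapolate wildly on uninformative windows
        decoder.target_transform[h.name] = (
            center,
            scale,
            (tr.min(axis=0), tr.max(axis=0)),
        )
    scaled_targets = {}
    for k, v in targets.items():
        if k in decoder.target_transform:
            c, sc = decoder.target_transform[k][:2]
            scaled_targets[k] = (v - c) / sc
        else:
            scaled_targets[k] = v
    params = decoder.parameters()
    opt = Adam(params, lr=cfg.learning_rate)
    values = tensor.values
    history: list[dict] = []
    best_val = np.inf
    stall = 0
    # cap validation cost on long sessions
    val_eval = val_idx if len(val_idx) <= 512 else val_idx[:: len(val_idx) // 512 + 1]

    for epoch in range(cfg.epochs):
        epoch_loss = 0.0
        for _ in range(cfg.batches_per_epoch):
            batch = rng.choice(train_idx, size=cfg.batch_size, replace=True)
            x = extract_windows(values, batch, plan.window)
            pred = decoder.forward(x, training=True)
            grads_out = {}
            total = 0.0
            for h in spec.heads:
                li, g = loss_and_grad(
                    h.loss_tag, scaled_targets[h.name][batch], pred[h.name]
                )
                total += li
                grads_out[h.name] = g
            if not np.isfinite(total):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, lr={opt.lr:g}; aborting"
                )
            decoder.backward(grads_out)
            opt.step(decoder.gradients())
            epoch_loss += total
        # validation for the plateau schedule
        pv = decoder.predict(extract_windows(values, val_eval, plan.window))
        val_loss = sum(
            loss_and_grad(h.loss_tag, targets[h.name][val_eval], pv[h.name])[0]
            / (decoder.target_transform.get(h.name, (0.0, 1.0))[1])
            for h in spec.heads
        )
        history.append(
            {
                "epoch": epoch,
                "train_loss": epoch_loss / cfg.batches_per_epoch,
                "val_loss": val_loss,
                "lr": opt.lr,
            }
        )
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            stall = 0
        else:
            stall += 1
            if stall >= cfg.plateau_patience:
                opt.lr *= cfg.lr_decay_factor
                stall = 0
    decoder.training_meta = {
        "seed": cfg.seed,
        "fold": fold,
        "epochs": cfg.epochs,
        "history": history,
    }
    return decoder


def evaluate_fold(
    decoder: TrainedDecoder,
    tensor: WaveletTensor,
    behavior: BehaviorSeries | np.ndarray | dict,
    fold: int,
    plan: CVPlan,
    stride: int = 1,
) -> dict:
    """Sliding decoding over the fold's test block.

    Returns per-head ``{mean_error, median_error, fvaf}`` plus per-sample
    errors and predictions under ``"per_sample"`` / ``"predictions"``.
    """
    spec = decoder.spec
    targets = targets_for(spec.heads, behavior)
    idx = plan.test_indices(fold)[::stride]
    pred = decoder.predict(extract_windows(tensor.values, idx, plan.window))
    report: dict = {"indices": idx, "per_sample": {}, "predictions": pred}
    for h in spec.heads:
        err = per_sample_error(h.loss_tag, targets[h.name][idx], pred[h.name])
        report["per_sample"][h.name] = err
        report[h.name] = {
            "mean_error": float(err.mean()),
            "median_error": float(np.median(err)),
            "fvaf": fvaf_r2(targets[h.name][idx], pred[h.name]),
        }
    return report


def shift_behavior(targets: dict[str, np.ndarray], shift: int) -> dict[str, np.ndarray]:
    return {k: np.roll(v, shift, axis=0) for k, v in targets.items()}


def chance_model(
    raw_tensor: WaveletTensor,
    behavior: BehaviorSeries | np.ndarray | dict,
    fold: int,
    plan: CVPlan,
    spec: ArchitectureSpec,
    cfg: TrainConfig,
    shift: int | None = None,
) -> dict:
    """Retrain the identical decoder with behavior circularly shifted by half
    the session (default) relative to the tensor; evaluate on the shifted
    targets. ``shift=0`` reproduces normal training bit for bit."""
    if shift is None:
        shift = raw_tensor.n_samples // 2
    targets = targets_for(spec.heads, behavior)
    shifted = shift_behavior(targets, shift)
    stats = fit_mad(raw_tensor, plan.train_mask(fold))
    tensor = apply_mad(raw_tensor, stats)
    dec = build_decoder(spec, seed=cfg.seed)
    train_fold(dec, tensor, shifted, fold, plan, cfg)
    report = evaluate_fold(dec, tensor, shifted, fold, plan)
    report["shift"] = shift
    return report


def run_fold(
    raw_tensor: WaveletTensor,
    behavior: BehaviorSeries | np.ndarray | dict,
    fold: int,
    plan: CVPlan,
    spec: ArchitectureSpec,
    cfg: TrainConfig,
) -> tuple[TrainedDecoder, WaveletTensor, dict]:
    """Convenience: fit fold stats, normalize, build, train, evaluate."""
    stats = fit_mad(raw_tensor, plan.train_mask(fold))
    tensor = apply_mad(raw_tensor, stats)
    dec = build_decoder(spec, seed=cfg.seed)
    dec.normalization = stats
    train_fold(dec, tensor, behavior, fold, plan, cfg)
    report = evaluate_fold(dec, tensor, behavior, fold, plan)
    return dec, tensor, report
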