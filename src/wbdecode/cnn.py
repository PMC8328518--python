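"""Shared-weight convolutional regression network, its losses, and FVAF.

The decoder consumes windows of the wavelet tensor shaped
(time, frequency, channel). The first block of 2-D convolutional layers runs
over the (time, frequency) plane with weights shared across recording
channels (channels fold into the batch axis); the second block runs over the
(frequency, channel) plane with weights shared across the remaining
timesteps. Stride-2 layers downsample: alternating time/frequency in the
first block, then the channel axis in the second block (so halving the
channel count removes exactly one downsampling step). A fully connected
trunk feeds one linear regression head per behavioral variable, each with its
own loss (Euclidean distance for 2-D position, MAE for speed, cyclical MAE
for angles). Gaussian noise (sigma = 1 by default) is added to inputs during
training only.

Layers, backprop and the Adam optimizer are implemented here directly on
numpy arrays; the whole network is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Head",
    "ArchitectureSpec",
    "TrainedDecoder",
    "build_decoder",
    "count_parameters",
    "loss",
    "loss_and_grad",
    "fvaf_r2",
    "LOSS_TAGS",
]

LOSS_TAGS = ("euclidean", "mae", "cyclical_mae")


@dataclass(frozen=True)
class Head:
    name: str
    output_dim: int
    loss_tag: str

    def __post_init__(self) -> None:
        if self.loss_tag not in LOSS_TAGS:
            raise ValueError(f"unknown loss tag {self.loss_tag!r}")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Hyperparameters of the shared-weight decoder.

    Defaults follow the full-scale wide-band configuration (64-step window,
    26 bands, 128 channels, 8 channel-shared + 6 time-shared layers, 64 base
    filters doubling in the second block). Reduced configurations simply set
    smaller values; the stride schedule adapts to the input size.
    """

    input_window: int = 64
    n_bands: int = 26
    n_channels: int = 128
    heads: tuple[Head, ...] = (Head("position", 2, "euclidean"),)
    conv_kernel: int = 3
    n_shared_channel_layers: int = 8
    n_shared_time_layers: int = 6
    base_filters: int = 64
    filters_double_every: int = 2  # in the time-shared block
    fc_units: int = 256  # unreported upstream; sized so conv params dominate
    input_noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.input_window < 1 or not self.heads:
            raise ValueError("need input_window >= 1 and at least one head")

    # --- stride schedule -------------------------------------------------
    def stage1_plan(self) -> list[tuple[int, int, int]]:
        """(stride_time, stride_freq, filters) per channel-shared layer."""
        t, f = self.input_window, self.n_bands
        plan = []
        axis = 0  # alternate: time first, starting at layer 2
        for i in range(self.n_shared_channel_layers):
            st = sf = 1
            if i > 0:
                if axis == 0 and t > 2:
                    st, t = 2, -(-t // 2)
                elif f > 2:
                    sf, f = 2, -(-f // 2)
                elif t > 2:
                    st, t = 2, -(-t // 2)
                axis ^= 1
            plan.append((st, sf, self.base_filters))
        return plan

    def stage2_plan(self) -> list[tuple[int, int, int]]:
        """(stride_freq, stride_chan, filters) per time-shared layer."""
        _, f = self._stage1_out_hw()
        c = self.n_channels
        plan = []
        filters = self.base_filters
        for i in range(self.n_shared_time_layers):
            if i % self.filters_double_every == 0:
                filters *= 2
            sf = sc = 1
            # downsample the channel axis only: halving the recording channel
            # count then removes exactly one stride-2 step
            if c > 2:
                sc, c = 2, -(-c // 2)
            plan.append((sf, sc, filters))
        return plan

    def _stage1_out_hw(self) -> tuple[int, int]:
        t, f = self.input_window, self.n_bands
        for st, sf, _ in self.stage1_plan():
            t, f = -(-t // st), -(-f // sf)
        return t, f

    def min_feasible_window(self) -> int:
        n_time_strides = sum(
            1 for i in range(1, self.n_shared_channel_layers) if i % 2 == 1
        )
        return max(2**n_time_strides, 2)

    def n_downsampling_steps(self) -> int:
        s1 = sum(1 for st, sf, _ in self.stage1_plan() if st == 2 or sf == 2)
        s2 = sum(1 for sf, sc, _ in self.stage2_plan() if sf == 2 or sc == 2)
        return s1 + s2


# --------------------------------------------------------------------------
# layers


class _Conv2D:
    """3x3 (configurable) 2-D convolution, SAME padding, optional stride."""

    def __init__(self, cin, cout, k, stride, rng):
        scale = np.sqrt(2.0 / (cin * k * k))  # He init
        self.W = rng.normal(0, scale, size=(cin * k * k, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.k, self.stride = k, stride
        self.cache = None

    @property
    def params(self):
        return [self.W, self.b]

    def out_hw(self, h, w):
        sh, sw = self.stride
        return -(-h // sh), -(-w // sw)

    def _pad(self, h, w):
        k = self.k
        sh, sw = self.stride
        ho, wo = self.out_hw(h, w)
        ph = max((ho - 1) * sh + k - h, 0)
        pw = max((wo - 1) * sw + k - w, 0)
        return (ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)

    def forward(self, x, training=False):
        n, h, w, cin = x.shape
        (pt, pb), (pl, pr) = self._pad(h, w)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        sh, sw = self.stride
        k = self.k
        win = sliding_window_view(xp, (k, k), axis=(1, 2))[:, ::sh, ::sw]
        # win: (n, ho, wo, cin, k, k) -> flatten to (n*ho*wo, cin*k*k)
        n_, ho, wo = win.shape[:3]
        cols = win.reshape(n_ * ho * wo, cin * k * k)
        y = cols @ self.W + self.b
        self.cache = (cols, x.shape, xp.shape, (pt, pl), (ho, wo))
        return y.reshape(n_, ho, wo, -1)

    def backward(self, dy):
        cols, x_shape, xp_shape, (pt, pl), (ho, wo) = self.cache
        n, h, w, cin = x_shape
        k = self.k
        sh, sw = self.stride
        dyf = dy.reshape(-1, dy.shape[-1])
        self.dW = cols.T @ dyf
        self.db = dyf.sum(axis=0)
        dcols = (dyf @ self.W.T).reshape(n, ho, wo, cin, k, k)
        dxp = np.zeros(xp_shape, dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + sh * ho : sh, j : j + sw * wo : sw, :] += dcols[
                    :, :, :, :, i, j
                ]
        return dxp[:, pt : pt + h, pl : pl + w, :]

    @property
    def grads(self):
        return [self.dW, self.db]


class _ReLU:
    params: list = []
    grads: list = []

    def forward(self, x, training=False):
        self.mask = x > 0
        return x * self.mask

    def backward(self, dy):
        return dy * self.mask


class _Dense:
    def __init__(self, cin, cout, rng):
        self.W = rng.normal(0, np.sqrt(2.0 / cin), size=(cin, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        self.x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW = self.x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T

    @property
    def grads(self):
        return [self.dW, self.db]


# --------------------------------------------------------------------------
# decoder


@dataclass
class TrainedDecoder:
    """Architecture + weights + bookkeeping; built untrained by build_decoder."""

    spec: ArchitectureSpec
    stage1: list = field(default_factory=list)
    stage2: list = field(default_factory=list)
    trunk: list = field(default_factory=list)
    heads: dict = field(default_factory=dict)
    seed: int = 0
    normalization: object = None
    training_meta: dict = field(default_factory=dict)
    # per-head (center, scale) applied to targets during training and
    # inverted at prediction, so heads learn on O(1) values regardless of
    # the physical units (angles are never rescaled)
    target_transform: dict = field(default_factory=dict)
    _noise_rng: np.random.Generator | None = None

    # ---- plumbing ----
    def _all_layers(self):
        yield from self.stage1
        yield from self.stage2
        yield from self.trunk
        for h in self.heads.values():
            yield h

    def parameters(self):
        out = []
        for layer in self._all_layers():
            out.extend(layer.params)
        return out

    def gradients(self):
        out = []
        for layer in self._all_layers():
            out.extend(layer.grads)
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # ---- forward / backward ----
    def forward(self, x: np.ndarray, training: bool = False) -> dict[str, np.ndarray]:
        """x: (batch, T, F, C) -> {head name: (batch, dim)} predictions."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        n, t, f, c = x.shape
        if training and self.spec.input_noise_sd > 0:
            x = x + self._noise_rng.normal(
                0, self.spec.input_noise_sd, size=x.shape
            ).astype(np.float32)
        # stage 1: fold channels into batch, convolve over (time, freq)
        h = np.moveaxis(x, 3, 1).reshape(n * c, t, f, 1)
        for layer in self.stage1:
            h = layer.forward(h, training)
        _, t1, f1, k1 = h.shape
        # stage 2: fold time into batch, convolve over (freq, channel)
        h = h.reshape(n, c, t1, f1, k1)
        h = np.moveaxis(h, 1, 3)  # (n, t1, f1, c, k1)
        self._s2_in = h.shape
        h = h.reshape(n * t1, f1, c, k1)
        for layer in self.stage2:
            h = layer.forward(h, training)
        self._s2_out = h.shape
        h = h.reshape(n, -1)
        for layer in self.trunk:
            h = layer.forward(h, training)
        self._trunk_out = h
        return {name: head.forward(h, training) for name, head in self.heads.items()}

    def backward(self, dheads: dict[str, np.ndarray]) -> None:
        dh = None
        for name, head in self.heads.items():
            d = head.backward(np.asarray(dheads[name], dtype=np.float32))
            dh = d if dh is None else dh + d
        for layer in reversed(self.trunk):
            dh = layer.backward(dh)
        dh = dh.reshape(self._s2_out)
        for layer in reversed(self.stage2):
            dh = layer.backward(dh)
        n, t1, f1, c, k1 = self._s2_in
        dh = dh.reshape(n, t1, f1, c, k1)
        dh = np.moveaxis(dh, 3, 1).reshape(n * c, t1, f1, k1)
        for layer in reversed(self.stage1):
            dh = layer.backward(dh)

    def predict(self, windows: np.ndarray, batch_size: int = 256) -> dict[str, np.ndarray]:
        """Deterministic (noise-free) forward pass in physical units."""
        outs: dict[str, list] = {h.name: [] for h in self.spec.heads}
        for i in range(0, len(windows), batch_size):
            pred = self.forward(windows[i : i + batch_size], training=False)
            for k, v in pred.items():
                outs[k].append(v)
        out = {k: np.concatenate(v) for k, v in outs.items()}
        for k, tt in self.target_transform.items():
            center, scale = tt[0], tt[1]
            y = out[k] * scale + center
            if len(tt) > 2:  # clamp to the training target range
                lo, hi = tt[2]
                y = np.clip(y, lo, hi)
            out[k] = y
        return out

    def clone_untrained(self, seed: int | None = None) -> "TrainedDecoder":
        return build_decoder(self.spec, seed=self.seed if seed is None else seed)


def build_decoder(spec: ArchitectureSpec, seed: int = 0) -> TrainedDecoder:
    """Instantiate the (untrained) shared-weight decoder for ``spec``."""
    if spec.input_window < spec.min_feasible_window():
        raise ValueError(
            f"input window {spec.input_window} smaller than total downsampling; "
            f"minimal feasible window is {spec.min_feasible_window()}"
        )
    rng = np.random.default_rng(seed)
    k = spec.conv_kernel
    dec = TrainedDecoder(spec=spec, seed=seed, _noise_rng=np.random.default_rng(seed + 1))

    cin = 1
    for st, sf, cout in spec.stage1_plan():
        dec.stage1 += [_Conv2D(cin, cout, k, (st, sf), rng), _ReLU()]
        cin = cout
    for sf, sc, cout in spec.stage2_plan():
        dec.stage2 += [_Conv2D(cin, cout, k, (sf, sc), rng), _ReLU()]
        cin = cout

    # flattened size after stage 2
    t1, f1 = spec._stage1_out_hw()
    c = spec.n_channels
    for sf, sc, _ in spec.stage2_plan():
        f1, c = -(-f1 // sf), -(-c // sc)
    flat = t1 * f1 * c * cin
    dec.trunk = [_Dense(flat, spec.fc_units, rng), _ReLU()]
    dec.heads = {
        h.name: _Dense(spec.fc_units, h.output_dim, rng) for h in spec.heads
    }
    return dec


def count_parameters(spec: ArchitectureSpec, shared: bool = True) -> int:
    """Trainable-parameter count; ``shared=False`` gives the equivalent
    architecture with separate weights per recording channel (block 1) and
    per timestep (block 2)."""
    k = spec.conv_kernel
    total = 0
    cin = 1
    for _, _, cout in spec.stage1_plan():
        p = (cin * k * k + 1) * cout
        total += p if shared else p * spec.n_channels
        cin = cout
    t1, _ = spec._stage1_out_hw()
    for _, _, cout in spec.stage2_plan():
        p = (cin * k * k + 1) * cout
        total += p if shared else p * t1
        cin = cout
    t1, f1 = spec._stage1_out_hw()
    c = spec.n_channels
    for sf, sc, _ in spec.stage2_plan():
        f1, c = -(-f1 // sf), -(-c // sc)
    flat = t1 * f1 * c * cin
    total += (flat + 1) * spec.fc_units
    for h in spec.heads:
        total += (spec.fc_units + 1) * h.output_dim
    return total


# --------------------------------------------------------------------------
# losses and the FVAF score


def _check_shapes(y_true, y_pred):
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred shapes differ")
    return np.atleast_2d(y_true), np.atleast_2d(y_pred)


def per_sample_error(loss_tag: str, y_true, y_pred) -> np.ndarray:
    """Per-sample error under the named metric (no averaging)."""
    y, yh = _check_shapes(y_true, y_pred)
    if loss_tag == "euclidean":
        return np.sqrt(((yh - y) ** 2).sum(axis=1))
    if loss_tag == "mae":
        return np.abs(yh - y).mean(axis=1)
    if loss_tag == "cyclical_mae":
        # wrap to [-pi, pi); |wrapped| is the circular distance min(|d|, 2pi-|d|)
        d = np.abs(np.mod(yh - y + np.pi, 2 * np.pi) - np.pi)
        return d.mean(axis=1)
    raise ValueError(f"unknown loss tag {loss_tag!r}")


def loss(loss_tag: str, y_true, y_pred) -> float:
    """Mean per-sample error: Euclidean distance, MAE, or circular MAE."""
    return float(per_sample_error(loss_tag, y_true, y_pred).mean())


def loss_and_grad(loss_tag: str, y_true, y_pred) -> tuple[float, np.ndarray]:
    """Loss value and gradient w.r.t. predictions (for training)."""
    y, yh = _check_shapes(y_true, y_pred)
    m = len(y)
    if loss_tag == "euclidean":
        # reported value: mean 2-D distance (the error metric used throughout);
        # training gradient: mean *squared* distance, the printed form of the
        # Euclidean training objective — quadratic penalties keep the head
        # calibrated and tame outlier excursions
        diff = yh - y
        dist = np.sqrt((diff**2).sum(axis=1, keepdims=True))
        grad = 2.0 * diff / m
        return float(dist.mean()), grad
    if loss_tag == "mae":
        diff = yh - y
        return float(np.abs(diff).mean()), np.sign(diff) / diff.size
    if loss_tag == "cyclical_mae":
        # wrap difference to [-pi, pi); |wrapped| is the circular distance
        d = np.mod(yh - y + np.pi, 2 * np.pi) - np.pi
        return float(np.abs(d).mean()), np.sign(d) / d.size
    raise ValueError(f"unknown loss tag {loss_tag!r}")


def fvaf_r2(y_true, y_pred) -> float:
    """Fraction of variance accounted for: 1 - SS_res / SS_tot.

    No rescaling of predictions is allowed (alpha = 1, beta = 0), so the
    score is at most 1 and unbounded below; a wildly scaled prediction scores
    worse than a mildly scaled one.
    """
    y, yh = _check_shapes(y_true, y_pred)
    ss_tot = float(((y - y.mean(axis=0)) ** 2).sum())
    if ss_tot <= 0:
        raise ValueError("fvaf_r2 undefined for zero-variance y_true")
    ss_res = float(((y - yh) ** 2).sum())
    return 1.0 - ss_res / ss_tot


class Adam:
    """Adam on a fixed list of parameter arrays (updated in place)."""

    def __init__(self, params, lr=7e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
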