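"""Desk-scale synthetic benchmarks exercising the full pipeline.

These are the package's standard evaluation conditions: small enough to run
on one CPU in minutes, large enough that the decoder, the chance model, the
influence measure and the elimination analyses behave qualitatively like
their full-scale counterparts. Sessions are 10 minutes long; neural data is
synthesized at a reduced sampling rate whose Nyquist still contains the
bands of interest (3750 Hz for position decoding, 7500 Hz when the
interneuron band must sit well above the place-cell bands), and the decoder
is a reduced configuration of the same shared-weight architecture (3 + 2
convolutional layers, 8 filters, 32-step windows). docs/methods.md discusses
what these benchmarks do and do not establish.

Every function is deterministic given its seed.
"""

from __future__ import annotations

import numpy as np

from .cnn import ArchitectureSpec, Head, build_decoder
from .core import Arena
from .influence import eliminate_band_at_events, shuffle_influence
from .preprocessing import (
    apply_mad,
    fit_mad,
    make_frequency_bank,
    preprocess_recording,
)
from .synthetic import (
    SimBehaviorModulation,
    apply_sim_behavior_modulation,
    generate_trajectory,
    generate_units,
    synthesize_recording,
    synthetic_wavelet_tensor,
)
from .training import (
    TrainConfig,
    chance_model,
    evaluate_fold,
    make_cv_plan,
    run_fold,
    train_fold,
)

__all__ = [
    "ARENA",
    "benchmark_session",
    "decode_benchmark",
    "sim_behavior_influence_benchmark",
    "elimination_benchmark",
]

ARENA = Arena(175.0, 125.0)

# benchmark foraging speed: brisk enough that every CV partition covers the
# arena, as the real 40-min sessions do
BENCH_MEAN_SPEED = 18.0
BENCH_NOISE_SD = 0.07  # spectral density of a 0.2-SD floor at 30 kHz
BENCH_DURATION = 600.0
BENCH_WINDOW = 32


def _reduced_spec(n_bands: int, n_channels: int, heads) -> ArchitectureSpec:
    return ArchitectureSpec(
        input_window=BENCH_WINDOW,
        n_bands=n_bands,
        n_channels=n_channels,
        heads=heads,
        n_shared_channel_layers=3,
        n_shared_time_layers=2,
        base_filters=8,
        fc_units=64,
    )


def benchmark_session(
    seed: int,
    n_place: int = 20,
    n_interneuron: int = 0,
    fs_neural: float = 3750.0,
    n_channels: int = 4,
    duration: float = BENCH_DURATION,
):
    """Standard synthetic session: trajectory, units, recording, tensor.

    Returns ``(behavior, units, catalog, bank, tensor)``. The wavelet bank is
    anchored at the session Nyquist and descends by sqrt(2) to 2 Hz, so it is
    the corresponding subset of the canonical wide-band bank (contains
    468.75 and 663 Hz).
    """
    beh = generate_trajectory(
        ARENA, duration, 30.0, seed=seed, mean_speed=BENCH_MEAN_SPEED
    )
    units = generate_units(
        n_place,
        n_interneuron,
        ARENA,
        seed=seed + 100,
        fs_neural=fs_neural,
        n_channels=n_channels,
        place_peak_rate=(15.0, 30.0),
        interneuron_rate=(5.0, 9.0),
    )
    rng = np.random.default_rng(seed + 300)
    for u in units:
        if u.kind == "place":
            u.field_width = rng.uniform(18.0, 30.0)
    rec, catalog = synthesize_recording(
        units, beh, fs_neural, n_channels, noise_sd=BENCH_NOISE_SD, seed=seed + 200
    )
    bank = make_frequency_bank(fs_neural / 2.0, 2.0)
    M = int(round(fs_neural / 30.0))
    tensor = preprocess_recording(rec, bank, M=M)
    return beh, units, catalog, bank, tensor


def decode_benchmark(seed: int, epochs: int = 5) -> dict:
    """Train the reduced decoder on a 20-place-cell session and compare with
    the half-session-shifted chance model (criterion: planted spatial signal
    must beat chance)."""
    beh, units, catalog, bank, tensor = benchmark_session(seed)
    spec = _reduced_spec(bank.n_bands, tensor.n_channels, (Head("position", 2, "euclidean"),))
    plan = make_cv_plan(tensor.n_samples, tensor.fs_effective, 5, 2.0, window=BENCH_WINDOW)
    cfg = TrainConfig(
        learning_rate=7e-4,
        epochs=epochs,
        batches_per_epoch=75,
        batch_size=16,
        window=BENCH_WINDOW,
        seed=seed,
    )
    _, _, report = run_fold(tensor, beh, 0, plan, spec, cfg)
    chance = chance_model(tensor, beh, 0, plan, spec, cfg)
    return {
        "fvaf": report["position"]["fvaf"],
        "chance_fvaf": chance["position"]["fvaf"],
        "mean_error": report["position"]["mean_error"],
        "chance_mean_error": chance["position"]["mean_error"],
        "median_error": report["position"]["median_error"],
    }


def sim_behavior_influence_benchmark(
    seed: int,
    betas: dict[float, float] | None = None,
    n_samples: int = 9000,
    n_channels: int = 4,
) -> dict:
    """The wavelet-level planted-signal validation of the influence measure.

    A band-structured synthetic tensor is normalized (stats from the
    unmodulated data, as when modulating already-preprocessed wavelets), two
    bands are modulated by beta * y_sb, a reduced decoder regresses y_sb, and
    shuffle influence over frequencies is computed. Reports whether the two
    modulated bands are the top-2 influences and whether the beta = 2 band
    ranks first.
    """
    if betas is None:
        betas = {58.59: 2.0, 3750.0: 1.0}
    bank = make_frequency_bank(15000.0, 2.0)
    base = synthetic_wavelet_tensor(bank, n_samples, 30.0, n_channels, seed=seed)
    plan = make_cv_plan(n_samples, 30.0, 5, 2.0, window=8)
    stats = fit_mad(base, plan.train_mask(0))
    mod = SimBehaviorModulation(betas, seed=seed + 1000)
    modulated, y_sb = apply_sim_behavior_modulation(base, mod)
    norm = apply_mad(modulated, stats)

    spec = ArchitectureSpec(
        input_window=8,
        n_bands=bank.n_bands,
        n_channels=n_channels,
        heads=(Head("y_sb", 1, "mae"),),
        n_shared_channel_layers=3,
        n_shared_time_layers=2,
        base_filters=8,
        fc_units=32,
    )
    cfg = TrainConfig(
        learning_rate=1e-3,
        epochs=6,
        batches_per_epoch=100,
        batch_size=8,
        window=8,
        seed=seed,
    )
    dec = build_decoder(spec, seed=seed)
    train_fold(dec, norm, y_sb, 0, plan, cfg)
    report = evaluate_fold(dec, norm, y_sb, 0, plan, stride=2)
    imap = shuffle_influence(
        dec, norm, y_sb, plan, 0, "frequency", n_repeats=2, seed=seed, stride=4
    )
    top2 = imap.top_slices("y_sb", 2)
    idx = sorted(bank.band_index(f) for f in betas)
    beta_first = max(betas, key=betas.get)
    return {
        "fvaf": report["y_sb"]["fvaf"],
        "influence": imap,
        "top2": top2,
        "top2_correct": set(top2) == set(idx),
        "strong_band_first": top2[0] == bank.band_index(beta_first),
    }


def elimination_benchmark(seed: int) -> dict:
    """Event-locked elimination contrast on a mixed place/interneuron session.

    Trains the reduced position decoder at fs 7500 Hz (interneuron energy at
    3750 Hz, two octaves above the place bands), then scrubs the 469/663 Hz
    bands per channel at the channel's own place-cell spike times versus an
    equal global count of interneuron spike times, and reports both error
    decrements.
    """
    fs = 7500.0
    beh, units, catalog, bank, tensor = benchmark_session(
        seed, n_place=20, n_interneuron=6, fs_neural=fs
    )
    n_chan = tensor.n_channels
    spec = _reduced_spec(bank.n_bands, n_chan, (Head("position", 2, "euclidean"),))
    plan = make_cv_plan(tensor.n_samples, tensor.fs_effective, 5, 2.0, window=BENCH_WINDOW)
    cfg = TrainConfig(
        learning_rate=7e-4,
        epochs=6,
        batches_per_epoch=75,
        batch_size=16,
        window=BENCH_WINDOW,
        seed=seed,
    )
    stats = fit_mad(tensor, plan.train_mask(0))
    norm = apply_mad(tensor, stats)
    dec = build_decoder(spec, seed=seed)
    train_fold(dec, norm, beh, 0, plan, cfg)
    base = evaluate_fold(dec, norm, beh, 0, plan, stride=2)["position"]["mean_error"]

    rng = np.random.default_rng(seed + 400)

    def pools(label):
        out = [[] for _ in range(n_chan)]
        for u, t, l in zip(units, catalog.spike_times, catalog.labels):
            if l == label:
                out[int(np.argmax(u.channel_weights))].append(t)
        return [np.sort(np.concatenate(p)) if p else np.empty(0) for p in out]

    place_pool = pools("place")
    int_pool = pools("interneuron")
    n_place = sum(len(a) for a in place_pool)
    n_int = sum(len(a) for a in int_pool)
    if n_int > n_place:  # equal global event counts
        frac = n_place / n_int
        int_pool = [
            np.sort(rng.choice(a, int(round(len(a) * frac)), replace=False))
            if len(a)
            else a
            for a in int_pool
        ]
    mask = plan.train_mask(0)
    bands = [468.75, 663.0]
    win = 1.0 / tensor.fs_effective  # +/- one effective-rate bin

    def decrement(pool):
        scrubbed = eliminate_band_at_events(norm, bands, pool, win, mask)
        e = evaluate_fold(dec, scrubbed, beh, 0, plan, stride=2)["position"]["mean_error"]
        return e - base

    return {
        "base_error": base,
        "place_decrement": decrement(place_pool),
        "interneuron_decrement": decrement(int_pool),
        "n_place_events": n_place,
        "n_interneuron_events": sum(len(a) for a in int_pool),
    }
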