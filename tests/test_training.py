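"""Cross-validation plans, training mechanics, chance model."""

import numpy as np
import pytest

from wbdecode.cnn import ArchitectureSpec, Head, build_decoder
from wbdecode.preprocessing import WaveletTensor, apply_mad, fit_mad, make_frequency_bank
from wbdecode.synthetic import synthetic_wavelet_tensor
from wbdecode.training import (
    TrainConfig,
    chance_model,
    evaluate_fold,
    make_cv_plan,
    train_fold,
    targets_for,
)

SMALL_BANK = make_frequency_bank(16.0, 2.0)  # 7 bands

SPEC = ArchitectureSpec(
    input_window=8,
    n_bands=7,
    n_channels=2,
    heads=(Head("y", 1, "mae"),),
    n_shared_channel_layers=2,
    n_shared_time_layers=1,
    base_filters=4,
    fc_units=8,
)


def _data(seed=0, n=1500):
    base = synthetic_wavelet_tensor(SMALL_BANK, n, 30.0, 2, seed=seed)
    rng = np.random.default_rng(seed + 50)
    # target: smoothed function of band-0 power, learnable quickly
    y = base.values[:, 0, :].mean(axis=1).astype(float)
    y = (y - y.mean()) / y.std() + 0.1 * rng.standard_normal(n)
    return base, y[:, None]


class TestCvPlan:
    def test_five_partitions_of_1000(self):
        plan = make_cv_plan(1000, 30.0, 5, 2.0, window=8)
        assert [e - s for s, e in plan.bounds] == [200] * 5
        for fold in range(5):
            train = set(plan.train_indices(fold))
            test = set(plan.test_indices(fold))
            assert not train & test

    def test_single_partition_rejected(self):
        with pytest.raises(ValueError):
            make_cv_plan(1000, 30.0, 1, 2.0, window=8)

    def test_session_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            make_cv_plan(300, 30.0, 5, 2.0, window=8)

    def test_gap_soundness_exhaustive(self):
        """No sample of any training window comes within the gap of the test
        block (brute-force index scan)."""
        plan = make_cv_plan(600, 10.0, 3, 1.5, window=6)
        gap = plan.gap_samples
        for fold in range(3):
            start, end = plan.bounds[fold]
            test_zone = set(range(max(start - gap, 0), min(end + gap, 600)))
            for i in plan.train_indices(fold):
                window_samples = set(range(i - 5, i + 1))
                assert not window_samples & test_zone

    def test_test_blocks_cover_session(self):
        plan = make_cv_plan(1000, 30.0, 5, 2.0, window=8)
        covered = np.concatenate([np.arange(s, e) for s, e in plan.bounds])
        np.testing.assert_array_equal(np.sort(covered), np.arange(1000))


class TestTrainFold:
    def test_default_config_draws_18000_windows(self):
        assert TrainConfig().total_windows == 18000

    def test_plateau_decay_arithmetic(self):
        cfg = TrainConfig()
        assert cfg.learning_rate * cfg.lr_decay_factor == pytest.approx(0.00014)

    def test_zero_epochs_is_noop(self):
        base, y = _data()
        plan = make_cv_plan(1500, 30.0, 5, 2.0, window=8)
        tensor = apply_mad(base, fit_mad(base, plan.train_mask(0)))
        dec = build_decoder(SPEC, seed=0)
        w0 = [p.copy() for p in dec.parameters()]
        train_fold(dec, tensor, y, 0, plan, TrainConfig(epochs=0, window=8))
        for a, b in zip(w0, dec.parameters()):
            np.testing.assert_array_equal(a, b)

    def test_unnormalized_tensor_rejected(self):
        base, y = _data()
        plan = make_cv_plan(1500, 30.0, 5, 2.0, window=8)
        dec = build_decoder(SPEC, seed=0)
        with pytest.raises(ValueError, match="normalized"):
            train_fold(dec, base, y, 0, plan, TrainConfig(epochs=1, window=8))

    def test_training_reduces_loss_and_is_deterministic(self):
        base, y = _data()
        plan = make_cv_plan(1500, 30.0, 5, 2.0, window=8)
        tensor = apply_mad(base, fit_mad(base, plan.train_mask(0)))
        cfg = TrainConfig(epochs=3, batches_per_epoch=40, batch_size=8, window=8, seed=3)

        def run():
            dec = build_decoder(SPEC, seed=3)
            train_fold(dec, tensor, y, 0, plan, cfg)
            return dec

        a, b = run(), run()
        ha = [h["train_loss"] for h in a.training_meta["history"]]
        hb = [h["train_loss"] for h in b.training_meta["history"]]
        assert ha == hb  # bit-identical loss history
        assert ha[-1] < ha[0]  # learning happened
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa, pb)


class _OracleDecoder:
    """Stub decoder: emits the true targets for the evaluated windows."""

    def __init__(self, spec, targets, window):
        self.spec = spec
        self._t = targets
        self._w = window
        self._i = None

    def bind(self, indices):
        self._i = np.asarray(indices)

    def predict(self, windows, batch_size=256):
        return {"y": self._t[self._i]}


class TestEvaluateAndChance:
    def test_oracle_decoder_scores_perfectly(self):
        base, y = _data()
        plan = make_cv_plan(1500, 30.0, 5, 2.0, window=8)
        dec = _OracleDecoder(SPEC, y, 8)
        dec.bind(plan.test_indices(0))
        rep = evaluate_fold(dec, base, y, 0, plan)
        assert rep["y"]["mean_error"] == 0.0
        assert rep["y"]["fvaf"] == pytest.approx(1.0)

    def test_mean_decoder_scores_zero_fvaf(self):
        base, y = _data()
        plan = make_cv_plan(1500, 30.0, 5, 2.0, window=8)
        idx = plan.test_indices(0)
        mean_targets = np.full_like(y, y[idx].mean())
        dec = _OracleDecoder(SPEC, mean_targets, 8)
        dec.bind(idx)
        rep = evaluate_fold(dec, base, y, 0, plan)
        assert rep["y"]["fvaf"] == pytest.approx(0.0, abs=1e-9)

    def test_chance_with_zero_shift_is_identical_to_normal_training(self):
        base, y = _data()
        plan = make_cv_plan(1500, 30.0, 5, 2.0, window=8)
        cfg = TrainConfig(epochs=2, batches_per_epoch=30, batch_size=8, window=8, seed=5)
        chance = chance_model(base, y, 0, plan, SPEC, cfg, shift=0)
        tensor = apply_mad(base, fit_mad(base, plan.train_mask(0)))
        dec = build_decoder(SPEC, seed=5)
        train_fold(dec, tensor, y, 0, plan, cfg)
        normal = evaluate_fold(dec, tensor, y, 0, plan)
        assert chance["y"]["mean_error"] == normal["y"]["mean_error"]
        np.testing.assert_array_equal(chance["per_sample"]["y"], normal["per_sample"]["y"])

    def test_chance_shift_removes_signal(self):
        base, y = _data(seed=9)
        plan = make_cv_plan(1500, 30.0, 5, 2.0, window=8)
        cfg = TrainConfig(epochs=3, batches_per_epoch=40, batch_size=8, window=8, seed=5)
        chance = chance_model(base, y, 0, plan, SPEC, cfg)
        assert chance["y"]["fvaf"] < 0.1


class TestTargets:
    def test_array_and_dict_targets(self):
        heads = (Head("y", 1, "mae"),)
        arr = np.arange(10.0)
        t = targets_for(heads, arr)
        assert t["y"].shape == (10, 1)
        t2 = targets_for(heads, {"y": arr})
        np.testing.assert_array_equal(t["y"], t2["y"])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            targets_for((Head("y", 2, "mae"),), np.arange(10.0))


class TestMultiTask:
    def test_extra_heads_do_not_collapse_position_decoding(self):
        """Adding head-direction and speed heads leaves position FVAF within
        0.1 of the single-head model on the synthetic benchmark."""
        from wbdecode.benchmark import BENCH_WINDOW, _reduced_spec, benchmark_session

        beh, units, cat, bank, tensor = benchmark_session(0)
        plan = make_cv_plan(tensor.n_samples, 30.0, 5, 2.0, window=BENCH_WINDOW)
        cfg = TrainConfig(
            learning_rate=7e-4, epochs=5, batches_per_epoch=75, batch_size=16,
            window=BENCH_WINDOW, seed=0,
        )
        from wbdecode.training import run_fold

        single = _reduced_spec(
            bank.n_bands, tensor.n_channels, (Head("position", 2, "euclidean"),)
        )
        multi = _reduced_spec(
            bank.n_bands,
            tensor.n_channels,
            (
                Head("position", 2, "euclidean"),
                Head("head_direction", 1, "cyclical_mae"),
                Head("speed", 1, "mae"),
            ),
        )
        _, _, rep1 = run_fold(tensor, beh, 0, plan, single, cfg)
        _, _, rep3 = run_fold(tensor, beh, 0, plan, multi, cfg)
        assert abs(rep1["position"]["fvaf"] - rep3["position"]["fvaf"]) < 0.1
        assert rep3["speed"]["fvaf"] > 0.0  # speed is genuinely decodable
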