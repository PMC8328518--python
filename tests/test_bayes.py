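"""Poisson Bayesian decoder: oracle equivalence, priors, session decoding."""

import numpy as np
import pytest

from wbdecode.bayes import (
    ContinuityPrior,
    DecodeWindow,
    Ratemap,
    build_polar_ratemaps,
    build_ratemaps,
    continuity_weight,
    decode_session,
    decode_session_hd,
    posterior,
)
from wbdecode.core import Arena
from wbdecode.synthetic import generate_trajectory, generate_units, synthesize_recording
from wbdecode.training import make_cv_plan


def _maps(rates, prior=None):
    """1 x n_bins ratemap grid from explicit per-unit rate rows."""
    rates = np.asarray(rates, dtype=float)[:, :, None]  # (units, nx, 1)
    n = rates.shape[1]
    p = np.full((n, 1), 1.0 / n) if prior is None else np.asarray(prior)[:, None]
    return Ratemap(
        rates=rates,
        occupancy_p=p,
        visited=np.ones((n, 1), bool),
        x_centres=np.arange(n) * 2.0 + 1.0,
        y_centres=np.array([1.0]),
        bin_size=2.0,
    )


def _brute_posterior(k, rates, T, prior):
    """Direct product-form evaluation of the Poisson posterior."""
    rates = np.asarray(rates, dtype=float)
    scores = prior.copy().astype(float)
    for i, ki in enumerate(np.asarray(k)):
        scores = scores * rates[i] ** ki
    scores = scores * np.exp(-T * rates.sum(axis=0))
    return scores / scores.sum()


class TestPosterior:
    def test_hand_worked_two_bin_example(self):
        # one cell, alpha = (2, 8) Hz, T = 0.5 s, k = 4, uniform prior:
        # unnormalized scores 2^4 e^-1 = 5.886 and 8^4 e^-4 = 75.02
        maps = _maps([[2.0, 8.0]])
        lo = 2.0**4 * np.exp(-1.0)
        hi = 8.0**4 * np.exp(-4.0)
        assert lo == pytest.approx(5.886, abs=5e-4)
        assert hi == pytest.approx(75.02, abs=5e-3)
        post = posterior(DecodeWindow(0.5, np.array([4])), maps)
        np.testing.assert_allclose(
            post.ravel(), [lo / (lo + hi), hi / (lo + hi)], rtol=1e-12
        )
        assert np.argmax(post.ravel()) == 1

    def test_matches_brute_force_on_random_small_instances(self, rng):
        for _ in range(50):
            n_cells = rng.integers(1, 3)
            n_bins = rng.integers(1, 4)
            rates = rng.uniform(0.1, 10.0, size=(n_cells, n_bins))
            prior = rng.dirichlet(np.ones(n_bins))
            k = rng.poisson(2.0, size=n_cells)
            T = float(rng.uniform(0.1, 1.0))
            maps = _maps(rates, prior)
            post = posterior(DecodeWindow(T, k), maps).ravel()
            brute = _brute_posterior(k, rates, T, prior)
            np.testing.assert_allclose(post, brute, atol=1e-12)
            assert np.argmax(post) == np.argmax(brute)

    def test_normalization_sums_to_one(self, rng):
        maps = _maps(rng.uniform(0, 5, size=(2, 3)))
        post = posterior(DecodeWindow(0.5, np.array([1, 2])), maps)
        assert post.sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_counts_favor_low_rate_bins(self):
        maps = _maps([[1.0, 10.0]])
        post = posterior(DecodeWindow(0.5, np.array([0])), maps).ravel()
        assert post[0] > post[1]
        np.testing.assert_allclose(
            post, _brute_posterior([0], [[1.0, 10.0]], 0.5, np.array([0.5, 0.5])),
            atol=1e-12,
        )

    def test_flat_rates_return_prior(self):
        prior = np.array([0.2, 0.5, 0.3])
        maps = _maps([[4.0, 4.0, 4.0]], prior)
        post = posterior(DecodeWindow(0.5, np.array([3])), maps).ravel()
        np.testing.assert_allclose(post, prior, rtol=1e-12)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            DecodeWindow(0.0, np.array([1]))
        with pytest.raises(ValueError):
            DecodeWindow(0.5, np.array([-1]))
        with pytest.raises(ValueError):
            DecodeWindow(0.5, np.array([0.5]))


class TestContinuity:
    def test_zero_displacement_weight_one(self):
        assert continuity_weight([3.0, 4.0], [3.0, 4.0], 5.0) == pytest.approx(1.0)

    def test_worked_example(self):
        # 10 cm step, v = 10 cm/s, V = 1 s -> sigma = 10 cm, weight e^-0.5
        w = continuity_weight([10.0, 0.0], [0.0, 0.0], 10.0)
        assert w == pytest.approx(np.exp(-0.5), rel=1e-12)

    def test_infinite_speed_limit_flat(self):
        w = continuity_weight([100.0, 100.0], [0.0, 0.0], 1e9)
        assert w == pytest.approx(1.0, abs=1e-9)

    def test_default_prior_parameters(self):
        p = ContinuityPrior()
        assert p.V == 1.0 and p.speed_window == 4 and p.sigma_floor == 2.0


@pytest.fixture(scope="module")
def small_session():
    arena = Arena(100.0, 80.0)
    beh = generate_trajectory(arena, 240.0, 30.0, seed=21, mean_speed=18.0)
    units = generate_units(
        12, 0, arena, seed=22, fs_neural=1500.0, n_channels=2,
        place_peak_rate=(15.0, 25.0),
    )
    _, catalog = synthesize_recording(units, beh, 1500.0, 2, noise_sd=0.0, seed=23)
    return arena, beh, units, catalog


class TestRatemaps:
    def test_single_bin_firing_peaks_there(self, small_session):
        arena, beh, units, catalog = small_session
        maps = build_ratemaps(catalog, beh, arena)
        for i, u in enumerate(units[:5]):
            ix, iy = np.unravel_index(np.argmax(maps.rates[i]), maps.rates[i].shape)
            peak = np.array([maps.x_centres[ix], maps.y_centres[iy]])
            # smoothed ratemap peak within ~1.5 field widths of the truth
            assert np.hypot(*(peak - np.asarray(u.field_centre))) < 1.5 * u.field_width

    def test_zero_spike_unit_has_zero_map(self, small_session):
        arena, beh, units, catalog = small_session
        from wbdecode.core import UnitCatalog

        silent = UnitCatalog([np.empty(0)], ["place"], [units[0].waveform])
        maps = build_ratemaps(silent, beh, arena)
        assert np.allclose(maps.rates, 0.0)

    def test_speed_threshold_excludes_slow_occupancy(self, small_session):
        arena, beh, units, catalog = small_session
        lo = build_ratemaps(catalog, beh, arena, speed_threshold=3.0)
        hi = build_ratemaps(catalog, beh, arena, speed_threshold=25.0)
        assert hi.visited.sum() < lo.visited.sum()

    def test_all_stationary_rejected(self, small_session):
        arena, beh, units, catalog = small_session
        with pytest.raises(ValueError):
            build_ratemaps(catalog, beh, arena, speed_threshold=1e9)


class TestSessionDecoding:
    def test_synthetic_session_beats_trajectory_shuffle(self, small_session):
        arena, beh, units, catalog = small_session
        plan = make_cv_plan(beh.n_samples, beh.fs, 5, 2.0, window=8)
        res = decode_session(catalog, beh, arena, plan, T_bin=0.5)
        assert res["mean_error"] < 25.0  # informative decoding
        # shuffled control: rotate spike trains by half the session
        from wbdecode.core import UnitCatalog

        half = beh.duration / 2.0
        shuffled = UnitCatalog(
            [np.sort(np.mod(t + half, beh.duration)) for t in catalog.spike_times],
            catalog.labels,
            catalog.waveforms,
        )
        res_sh = decode_session(shuffled, beh, arena, plan, T_bin=0.5)
        assert res["mean_error"] < res_sh["mean_error"]

    def test_continuity_prior_never_breaks_decoding(self, small_session):
        arena, beh, units, catalog = small_session
        plan = make_cv_plan(beh.n_samples, beh.fs, 5, 2.0, window=8)
        res = decode_session(catalog, beh, arena, plan, T_bin=0.5, use_continuity=True)
        assert np.isfinite(res["mean_error"])
        assert res["mean_error"] < 30.0

    def test_hd_variant_runs_with_circular_error(self, small_session):
        arena, beh, units, catalog = small_session
        plan = make_cv_plan(beh.n_samples, beh.fs, 5, 2.0, window=8)
        res = decode_session_hd(catalog, beh, plan, T_bin=0.5)
        assert np.all(res["errors"] >= 0) and np.all(res["errors"] <= np.pi)

    def test_polar_ratemaps_cover_circle(self, small_session):
        arena, beh, units, catalog = small_session
        maps = build_polar_ratemaps(catalog, beh)
        assert maps.rates.shape[1] == 36
        assert maps.bin_centres.min() > -np.pi and maps.bin_centres.max() < np.pi
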