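"""Convolutional layer: IF dynamics, lateral inhibition, STDP, pooling."""

import numpy as np
import pytest

from spikespeech import (
    SILENT,
    ConvConfig,
    StdpParams,
    encode_first_spike,
    forward_sample,
    init_weights,
    normalize_map,
    pool_dataset,
    select_stdp_winners,
    stdp_update,
    train,
)

from .conftest import random_raster
from .oracles import naive_forward, naive_stdp, naive_winner_selection

DIGITS_CFG = ConvConfig()  # spoken-digit defaults: 50 maps, 6x40 window, 9 sections, threshold 23


class TestInitWeights:
    def test_gaussian_statistics(self):
        bank = init_weights(DIGITS_CFG, seed=0)
        assert bank.size >= 10_000
        assert abs(bank.mean() - 0.8) < 0.01
        assert bank.min() >= 0.0 and bank.max() <= 1.0

    def test_degenerate_sd_gives_constant(self):
        cfg = ConvConfig(init_sd=0.0)
        assert np.all(init_weights(cfg, seed=3) == 0.8)

    def test_seed_reproducibility(self):
        np.testing.assert_array_equal(
            init_weights(DIGITS_CFG, seed=42), init_weights(DIGITS_CFG, seed=42)
        )


class TestForwardSample:
    def test_threshold_equality_fires_first_update_step(self):
        cfg = DIGITS_CFG
        bank = np.ones((cfg.n_maps, cfg.n_sections, cfg.win_len, cfg.n_bands))
        raster = np.full((cfg.n_frames, cfg.n_bands), SILENT)
        # exactly 23 input spikes at step 0 inside the first window
        raster.ravel()[:23] = 0
        fw = forward_sample(raster, bank, cfg)
        assert fw.fired_at[0, 0] == 1
        assert fw.fire_potential[0, 0] == pytest.approx(23.0)

    def test_all_silent_raster_is_inert(self):
        bank = init_weights(DIGITS_CFG, 0)
        fw = forward_sample(np.full((41, 40), SILENT), bank, DIGITS_CFG)
        assert np.all(fw.fired_at == SILENT)
        assert fw.pooling.sum() == 0

    def test_lateral_inhibition_bounds_spikes(self, rng):
        """At most one spike per position: <= 36 spikes, <= 8% active pool."""
        bank = init_weights(DIGITS_CFG, 1)
        for _ in range(10):
            raster = random_raster(rng, 41, 40, n_steps=30)
            fw = forward_sample(raster, bank, DIGITS_CFG)
            per_position = (fw.fired_at != SILENT).sum(axis=0)
            assert per_position.max() <= 1
            assert fw.pooling.sum() <= DIGITS_CFG.n_positions == 36
            assert (fw.pooling > 0).mean() <= 36 / 450
            assert fw.pooling.max() <= DIGITS_CFG.section_len

    def test_matches_naive_oracle(self, rng, small_cfg):
        """Elementwise agreement with a per-neuron per-step simulation."""
        for _ in range(100):
            bank = np.clip(
                rng.normal(0.5, 0.2, (2, 3, 3, 3)), 0, 1
            )
            raster = random_raster(rng, 8, 3, n_steps=8)
            fw = forward_sample(raster, bank, small_cfg)
            fa, fp, pool = naive_forward(raster, bank, small_cfg)
            np.testing.assert_array_equal(fw.fired_at, fa)
            np.testing.assert_allclose(fw.fire_potential, fp, atol=1e-12)
            np.testing.assert_array_equal(fw.pooling, pool)

    def test_monotone_efficacy_single_map(self, rng):
        """An earlier input spike never delays a neuron's first spike."""
        cfg = ConvConfig(n_maps=1, v_thresh=4.0, n_frames=10, win_len=3,
                         n_sections=2, n_bands=4, init_sd=0.0)
        bank = init_weights(cfg, 0)
        for _ in range(30):
            raster = random_raster(rng, 10, 4, n_steps=12)
            base = forward_sample(raster, bank, cfg).fired_at.astype(float)
            base[base == SILENT] = np.inf
            # advance one random input spike
            i, j = rng.integers(10), rng.integers(4)
            bumped = raster.copy()
            bumped[i, j] = 0 if raster[i, j] == SILENT else max(raster[i, j] - 3, 0)
            out = forward_sample(bumped, bank, cfg).fired_at.astype(float)
            out[out == SILENT] = np.inf
            assert np.all(out <= base)

    def test_monotone_efficacy_positionwise(self, rng, small_cfg):
        """Across maps, a position's first spike is never delayed."""
        bank = init_weights(small_cfg, 5)
        for _ in range(30):
            raster = random_raster(rng, 8, 3, n_steps=8)
            def first_spike_per_pos(r):
                fa = forward_sample(r, bank, small_cfg).fired_at.astype(float)
                fa[fa == SILENT] = np.inf
                return fa.min(axis=0)
            base = first_spike_per_pos(raster)
            i, j = rng.integers(8), rng.integers(3)
            bumped = raster.copy()
            bumped[i, j] = 0
            assert np.all(first_spike_per_pos(bumped) <= base)

    def test_shape_mismatch_rejected(self):
        bank = init_weights(DIGITS_CFG, 0)
        with pytest.raises(ValueError, match="raster shape"):
            forward_sample(np.zeros((10, 40), dtype=int), bank, DIGITS_CFG)

    def test_single_section_is_global_sharing(self, rng):
        """Replicating one shared matrix across sections reproduces the
        global-sharing network: identical spikes, summed pooling."""
        cfg1 = ConvConfig(n_maps=3, v_thresh=5.0, n_sections=1, n_frames=17,
                          win_len=6, n_bands=8)
        cfg9 = ConvConfig(n_maps=3, v_thresh=5.0, n_sections=3, n_frames=17,
                          win_len=6, n_bands=8)
        bank1 = init_weights(cfg1, 2)
        bank9 = np.repeat(bank1, 3, axis=1)
        for _ in range(10):
            raster = random_raster(rng, 17, 8)
            fw1 = forward_sample(raster, bank1, cfg1)
            fw9 = forward_sample(raster, bank9, cfg9)
            np.testing.assert_array_equal(fw1.fired_at, fw9.fired_at)
            np.testing.assert_array_equal(
                fw1.pooling[:, 0], fw9.pooling.sum(axis=1)
            )


class TestStdpUpdate:
    def test_direct_arithmetic(self, small_cfg):
        bank = np.full((2, 3, 3, 3), 0.8)
        raster = np.zeros((8, 3), dtype=int)  # all inputs spike at step 0
        params = StdpParams(a_plus=0.004, a_minus=0.003)
        new, delta = stdp_update(bank, raster, [(0, 0, 2)], params, small_cfg)
        # pre (t=0) before post (t=2): dw = 0.004 * 0.8 * 0.2
        assert delta == pytest.approx(0.00064)
        np.testing.assert_allclose(new[0, 0], 0.8 + 0.00064)
        np.testing.assert_array_equal(new[1], bank[1])  # other map untouched

    def test_soft_bound_fixes_extremes(self, small_cfg):
        params = StdpParams()
        for w0 in (0.0, 1.0):
            bank = np.full((2, 3, 3, 3), w0)
            raster = random_raster(np.random.default_rng(0), 8, 3)
            new, delta = stdp_update(bank, raster, [(0, 2, 3)], params, small_cfg)
            assert delta == 0.0
            np.testing.assert_array_equal(new, bank)

    def test_matches_per_synapse_oracle(self, rng, small_cfg):
        params = StdpParams(a_plus=0.1, a_minus=0.07)
        for _ in range(50):
            bank = rng.random((2, 3, 3, 3))
            raster = random_raster(rng, 8, 3)
            winners = [(int(rng.integers(2)), int(rng.integers(6)), int(rng.integers(1, 8)))]
            got, gd = stdp_update(bank, raster, winners, params, small_cfg)
            want, wd = naive_stdp(bank, raster, winners, 0.1, 0.07, small_cfg)
            np.testing.assert_allclose(got, want, atol=1e-12)
            assert gd == pytest.approx(wd)

    def test_silent_winner_rejected(self, small_cfg):
        bank = np.full((2, 3, 3, 3), 0.5)
        with pytest.raises(ValueError, match="did not fire"):
            stdp_update(bank, np.zeros((8, 3), int), [(0, 0, SILENT)],
                        StdpParams(), small_cfg)

    def test_weights_stay_bounded_after_many_updates(self, rng, small_cfg):
        """Soft bound: 10^4 random updates never leave [0, 1]."""
        params = StdpParams(a_plus=0.9, a_minus=0.9)
        bank = rng.random((2, 3, 3, 3))
        for _ in range(10_000):
            raster = random_raster(rng, 8, 3, n_steps=6)
            winners = [(int(rng.integers(2)), int(rng.integers(6)), int(rng.integers(1, 7)))]
            bank, _ = stdp_update(bank, raster, winners, params, small_cfg)
        assert bank.min() >= 0.0 and bank.max() <= 1.0


class TestWinnerSelection:
    def test_single_spike_is_sole_winner(self, small_cfg):
        fired = np.full((2, 6), SILENT)
        pot = np.zeros((2, 6))
        fired[1, 4] = 3
        winners = select_stdp_winners(fired, pot, StdpParams(), small_cfg)
        assert winners == [(1, 4, 3)]

    def test_neighborhood_blocks_same_map(self, small_cfg):
        fired = np.full((1, 6), SILENT)
        pot = np.zeros((1, 6))
        fired[0, 1] = 2
        fired[0, 2] = 2
        winners = select_stdp_winners(
            fired, pot, StdpParams(neighborhood_radius=4), small_cfg
        )
        assert winners == [(0, 1, 2)]  # tie broken toward the lower position

    def test_matches_exhaustive_oracle(self, rng, small_cfg):
        params = StdpParams(neighborhood_radius=2)
        for _ in range(200):
            fired = rng.integers(-1, 6, size=(2, 6))
            pot = rng.random((2, 6)) * (fired != SILENT)
            got = select_stdp_winners(fired, pot, params, small_cfg)
            want = naive_winner_selection(fired, pot, radius=2)
            assert got == want


class TestTrain:
    def test_silent_dataset_leaves_bank_unchanged(self, small_cfg):
        """No spikes -> no winners -> no updates."""
        dataset = [np.full((8, 3), SILENT)] * 5
        bank0 = init_weights(small_cfg, 4)
        res = train(dataset, small_cfg, StdpParams(max_epochs=2), seed=0, bank=bank0)
        np.testing.assert_array_equal(res.bank, bank0)
        assert all(d == 0 for d in res.delta_history)

    def test_zero_rates_freeze_weights(self, rng, small_cfg):
        dataset = [random_raster(rng, 8, 3) for _ in range(5)]
        params = StdpParams(a_plus=0.0, a_minus=0.0, max_epochs=2)
        bank0 = init_weights(small_cfg, 9)
        res = train(dataset, small_cfg, params, seed=0, bank=bank0)
        np.testing.assert_array_equal(res.bank, bank0)
        assert all(d == 0 for d in res.delta_history)

    def test_empty_dataset_rejected(self, small_cfg):
        with pytest.raises(ValueError, match="empty"):
            train([], small_cfg, StdpParams(), seed=0)

    def test_training_is_reproducible(self, rng, small_cfg):
        dataset = [random_raster(rng, 8, 3) for _ in range(10)]
        r1 = train(dataset, small_cfg, StdpParams(max_epochs=3), seed=5)
        r2 = train(dataset, small_cfg, StdpParams(max_epochs=3), seed=5)
        np.testing.assert_array_equal(r1.bank, r2.bank)


class TestPooling:
    def test_output_dimension_paper_configs(self):
        assert ConvConfig(n_maps=50).output_dim == 450
        assert ConvConfig(n_maps=70).output_dim == 630

    def test_pool_dataset_deterministic(self, rng, small_cfg):
        bank = init_weights(small_cfg, 0)
        dataset = [random_raster(rng, 8, 3) for _ in range(6)]
        X1 = pool_dataset(dataset, bank, small_cfg)
        X2 = pool_dataset(dataset, bank, small_cfg)
        np.testing.assert_array_equal(X1, X2)
        assert X1.shape == (6, small_cfg.output_dim)


def test_config_validation():
    with pytest.raises(ValueError, match="divisible"):
        ConvConfig(n_sections=7)  # 36 positions not divisible by 7
    with pytest.raises(ValueError, match="v_thresh"):
        ConvConfig(v_thresh=0.0, v_rest=0.0)
    with pytest.raises(ValueError, match="stride"):
        ConvConfig(stride=0)
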