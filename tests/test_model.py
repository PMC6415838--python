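"""Architecture geometry, masked loss, patch sampling, training, inference."""

import math

import numpy as np
import pytest

from vesselkit.core import ImageStack
from vesselkit.model import (
    ModelConfig,
    PRESETS,
    VesselPatchCNN,
    binary_entropy,
    build_model,
    entropy_map,
    masked_cross_entropy,
    predict_volume,
    sample_patches,
    train,
)


@pytest.fixture(scope="module")
def tiny_model():
    return build_model(ModelConfig(seed=123))


class TestArchitecture:
    def test_forward_maps_input_tile_to_output_tile(self, tiny_model):
        x = np.random.default_rng(0).random((2, 7, 33, 33), dtype=np.float32)
        out = tiny_model.forward(x)
        assert out.shape == (2, 5, 5, 1, 2)

    def test_forward_deterministic_without_dropout(self, tiny_model):
        x = np.random.default_rng(1).random((3, 7, 33, 33), dtype=np.float32)
        assert np.array_equal(tiny_model.forward(x), tiny_model.forward(x))

    def test_parameter_count_matches_layer_arithmetic(self, tiny_model):
        # conv1: 3*3*3*1*32+32      =     896
        # conv2/3: 3*3*3*32*32+32   =  27 680 each
        # conv4: 3*3*32*64+64       =  18 496
        # conv5: 3*3*64*64+64       =  36 928
        # fc1: (5*5*64)*1024+1024   = 1 639 424
        # fc2: 1024*(5*5*1*2)+50    =  51 250
        assert tiny_model.n_parameters == 1_802_354

    def test_wrong_tile_geometry_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.forward(np.zeros((1, 7, 32, 33), dtype=np.float32))

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(dropout_rate=1.0)
        with pytest.raises(ValueError):
            ModelConfig(hidden_nodes=0)

    def test_exploration_preset_uses_published_settings(self):
        cfg = PRESETS["exploration"]
        assert cfg.epochs == 100 and cfg.learning_rate == 1e-4

    def test_save_load_roundtrip(self, tiny_model, tmp_path):
        x = np.random.default_rng(2).random((1, 7, 33, 33), dtype=np.float32)
        tiny_model.save(tmp_path / "w.npz", tmp_path / "w.json")
        again = VesselPatchCNN.load(tmp_path / "w.npz", config_path=tmp_path / "w.json")
        assert np.array_equal(tiny_model.forward(x), again.forward(x))


class TestMaskedCrossEntropy:
    def test_all_true_negatives_give_zero_loss(self):
        y = np.zeros((4, 4, 1))
        p = np.full((4, 4, 1), 0.2)
        assert masked_cross_entropy(y, p) == 0.0

    def test_single_positive_at_half_probability(self):
        assert math.isclose(masked_cross_entropy(np.ones(1), np.full(1, 0.5)), math.log(2))

    def test_matches_per_voxel_summation_oracle(self):
        rng = np.random.default_rng(17)
        y = (rng.random((4, 4, 1)) > 0.5).astype(float)
        p = rng.uniform(0.01, 0.99, (4, 4, 1))
        expected = 0.0
        for yi, pi in zip(y.ravel(), p.ravel()):
            predicted_fg = pi >= 0.5
            if yi == 0 and not predicted_fg:
                continue  # true negative: excluded
            expected += -(yi * math.log(pi) + (1 - yi) * math.log(1 - pi))
        assert math.isclose(masked_cross_entropy(y, p), expected, rel_tol=1e-12)

    def test_equals_full_ce_minus_tn_term(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            y = (rng.random(40) > 0.7).astype(float)
            p = rng.uniform(1e-6, 1 - 1e-6, 40)
            full = -(y * np.log(p) + (1 - y) * np.log(1 - p)).sum()
            tn = ((y == 0) & (p < 0.5))
            tn_term = -((1 - y) * np.log(1 - p))[tn].sum()
            assert math.isclose(masked_cross_entropy(y, p), full - tn_term, rel_tol=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            masked_cross_entropy(np.zeros(3), np.zeros(4))

    def test_loss_nonnegative_and_vanishes_at_perfect_prediction(self):
        y = np.array([0.0, 1.0, 1.0, 0.0])
        p = np.array([1e-9, 1 - 1e-9, 1 - 1e-9, 1e-9])
        loss = masked_cross_entropy(y, p)
        assert 0 <= loss < 1e-6


class TestSamplePatches:
    def _volume(self):
        rng = np.random.default_rng(0)
        img = rng.random((20, 40, 40)).astype(np.float32)
        labels = np.zeros((20, 40, 40), np.uint8)
        labels[8:12, 15:25, 15:25] = 1
        return img, labels

    def test_deterministic(self):
        img, labels = self._volume()
        a = sample_patches(img, labels, 100, seed=9)
        b = sample_patches(img, labels, 100, seed=9)
        assert np.array_equal(a.inputs, b.inputs)
        assert np.array_equal(a.centers, b.centers)

    def test_full_balance_means_all_targets_have_foreground(self):
        img, labels = self._volume()
        ps = sample_patches(img, labels, 64, balance=1.0, seed=1)
        assert all(t.any() for t in ps.targets)

    def test_balance_fraction_achieved(self):
        img, labels = self._volume()
        ps = sample_patches(img, labels, 1000, balance=0.5, seed=2)
        frac = np.mean([t.any() for t in ps.targets])
        assert abs(frac - 0.5) < 0.05  # well inside any binomial 99% bound

    def test_no_foreground_with_positive_balance_raises(self):
        img, _ = self._volume()
        with pytest.raises(ValueError):
            sample_patches(img, np.zeros_like(img, dtype=np.uint8), 10, balance=0.5)


class TestTraining:
    def _patches(self, n=24):
        rng = np.random.default_rng(0)
        img = rng.random((16, 40, 40)).astype(np.float32)
        labels = (rng.random((16, 40, 40)) > 0.9).astype(np.uint8)
        return sample_patches(img, labels, n, seed=0)

    def test_zero_learning_rate_leaves_weights_unchanged(self):
        cfg = ModelConfig(seed=0, learning_rate=0.0, epochs=1, minibatch=8)
        model = build_model(cfg)
        before = {k: v.copy() for k, v in model.params.items()}
        train(model, self._patches(), cfg, validation_fraction=0.0)
        for k in before:
            assert np.array_equal(model.params[k], before[k])

    def test_loss_history_recorded_per_epoch(self):
        cfg = ModelConfig(seed=0, learning_rate=1e-3, epochs=2, minibatch=16)
        model = build_model(cfg)
        result = train(model, self._patches(), cfg, validation_fraction=0.0)
        assert len(result.loss_history) == 2
        assert all(np.isfinite(result.loss_history))

    def test_training_reduces_loss_on_separable_phantom_data(self):
        # intensity-separable task: a few epochs must bring the loss down
        # for (nearly) every seed
        from vesselkit import phantom

        spec = phantom.PhantomSpec(volume_shape=(32, 48, 48), n_vessels=2,
                                   noise_sigma=0.05, seed=2, motion_max_shift_px=0)
        out = phantom.add_noise_and_depth_decay(phantom.generate_tube_network(spec), spec)
        decreased = 0
        seeds = (0, 1, 2)
        for seed in seeds:
            patches = sample_patches(out.image, out.truth_mask, 120, seed=seed)
            cfg = ModelConfig(seed=seed, learning_rate=1e-3, epochs=4, minibatch=64)
            model = build_model(cfg)
            res = train(model, patches, cfg, validation_fraction=0.0)
            h = res.loss_history
            if all(b < a for a, b in zip(h, h[1:])):
                decreased += 1
        assert decreased >= len(seeds) - 1


class TestPredictVolume:
    def test_constant_volume_gives_block_periodic_probability(self, tiny_model):
        # every tile sees identical constant input, so all 5x5 output blocks
        # are identical (within a block the output head may vary by position)
        vol = np.full((7, 15, 15), 0.4, dtype=np.float32)
        prob, mask = predict_volume(tiny_model, vol)
        assert prob.shape == vol.shape
        ref = prob[0, 0:5, 0:5]
        for z in range(7):
            for y0 in range(0, 15, 5):
                for x0 in range(0, 15, 5):
                    assert np.allclose(prob[z, y0 : y0 + 5, x0 : x0 + 5], ref, atol=1e-6)
        assert set(np.unique(mask)) <= {0, 1}

    def test_tiled_equals_manual_tiling_oracle(self, tiny_model):
        rng = np.random.default_rng(4)
        vol = rng.random((7, 15, 20), dtype=np.float32)
        prob, _ = predict_volume(tiny_model, vol)
        nz, ny, nx = vol.shape
        yb, xb = 15, 20
        pad = np.pad(vol, ((3, 3), (14, 14), (14, 14)), mode="reflect")
        expected = np.empty((nz, yb, xb), np.float32)
        for z in range(nz):
            for y0 in range(0, yb, 5):
                for x0 in range(0, xb, 5):
                    tile = pad[z : z + 7, y0 : y0 + 33, x0 : x0 + 33]
                    expected[z, y0 : y0 + 5, x0 : x0 + 5] = tiny_model.predict_proba(tile[None])[0]
        assert np.allclose(prob, expected, atol=1e-6)

    def test_tiled_matches_voxel_centered_prediction_at_block_centers(self, tiny_model):
        rng = np.random.default_rng(6)
        vol = rng.random((7, 15, 15), dtype=np.float32)
        prob, _ = predict_volume(tiny_model, vol)
        pad = np.pad(vol, ((3, 3), (16, 16), (16, 16)), mode="reflect")
        for z in range(7):
            for cy in (2, 7, 12):
                for cx in (2, 7, 12):
                    tile = pad[z : z + 7, cy : cy + 33, cx : cx + 33]
                    single = tiny_model.predict_proba(tile[None])[0][2, 2]
                    assert prob[z, cy, cx] == pytest.approx(single, abs=1e-6)

    def test_output_partitions_volume(self, tiny_model):
        vol = np.random.default_rng(7).random((8, 17, 23), dtype=np.float32)
        prob, mask = predict_volume(tiny_model, vol)
        assert prob.shape == vol.shape and mask.shape == vol.shape
        assert np.isfinite(prob).all()

    def test_thin_volume_rejected_with_advice(self, tiny_model):
        with pytest.raises(ValueError, match="pad"):
            predict_volume(tiny_model, np.zeros((5, 20, 20), dtype=np.float32))


class TestEntropy:
    def test_maximum_entropy_at_half(self):
        assert binary_entropy(np.array(0.5)) == 1.0

    def test_degenerate_probabilities_have_zero_entropy(self):
        assert np.all(binary_entropy(np.array([0.0, 1.0])) == 0.0)

    def test_two_pass_average_entropy_by_direct_formula(self):
        pbar = np.mean([0.2, 0.6])
        expected = -(pbar * math.log2(pbar) + (1 - pbar) * math.log2(1 - pbar))
        assert binary_entropy(np.array(pbar)) == pytest.approx(expected, rel=1e-12)
        assert pbar == pytest.approx(0.4)

    def test_entropy_map_consistent_with_mean_probability(self, tiny_model):
        vol = np.random.default_rng(8).random((7, 15, 15), dtype=np.float32)
        ent, pbar = entropy_map(tiny_model, vol, n_samples=3, seed=0)
        assert ent.shape == vol.shape
        assert np.allclose(ent, binary_entropy(pbar))
        assert (ent >= 0).all() and (ent <= 1).all()

    def test_too_few_samples_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            entropy_map(tiny_model, np.zeros((7, 15, 15), dtype=np.float32), n_samples=1)
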