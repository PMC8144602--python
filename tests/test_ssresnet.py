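"""SS-ResNet: normalization, layers, architecture contracts, training."""

import numpy as np
import pytest

from srskit.simulate import TrainingPair, corrupt, make_pair
from srskit.ssresnet import (
    DenoiserConfig,
    SSConvBlock,
    build_denoiser,
    denoise,
    fine_tune,
    load_model,
    percentile_normalize,
    save_model,
    ss_conv_block,
    train_denoiser,
)
from srskit.ssresnet.model import NormalizationParams

TINY = DenoiserConfig(
    n_levels=2, blocks_per_level=2, base_channels=8,
    learning_rate=1e-3, batch_size=2, n_epochs=4, steps_per_epoch=4,
    patch_shape=(16, 32, 32), seed=0,
)


class TestPercentileNormalize:
    def test_integer_ramp_matches_order_statistics_oracle(self):
        x = np.arange(1000, dtype=float)
        normed, params = percentile_normalize(x, 0.3, 99.7)
        # linear-interpolation quantile oracle: q = pct/100 * (n - 1)
        lo = 0.3 / 100 * 999
        hi = 99.7 / 100 * 999
        assert params.lo == pytest.approx(lo, abs=1e-9)   # ~3
        assert params.hi == pytest.approx(hi, abs=1e-9)   # ~996
        np.testing.assert_allclose(normed, (x - lo) / (hi - lo), atol=1e-6)
        # renormalizing its own output anchors at 0 and 1
        _, params2 = percentile_normalize(normed, 0.3, 99.7)
        assert params2.lo == pytest.approx(0.0, abs=1e-6)
        assert params2.hi == pytest.approx(1.0, abs=1e-6)

    def test_no_clipping_above_one(self):
        x = np.concatenate([np.linspace(0.0, 1.0, 999), [100.0]])
        normed, _ = percentile_normalize(x, 0.3, 99.7)
        assert normed.max() > 1.0  # hot pixel excluded from scale, not clipped

    def test_constant_stack_rejected(self):
        with pytest.raises(ValueError):
            percentile_normalize(np.ones((4, 4, 4)))


class TestSSConvBlock:
    def test_zero_input_zero_bias_gives_zero(self):
        rng = np.random.default_rng(0)
        block = SSConvBlock(3, rng)
        out = block.forward(np.zeros((1, 3, 4, 6, 6), np.float32))
        assert not out.any()

    def test_identity_spectral_kernel(self):
        # spatial path zeroed, spectral kernel = centred delta: out = relu(x)
        c = 2
        sw = np.zeros((c, c, 3, 3), np.float32)
        pw = np.zeros((c, c, 3), np.float32)
        for i in range(c):
            pw[i, i, 1] = 1.0
        rng = np.random.default_rng(1)
        x = rng.normal(size=(c, 5, 6, 6)).astype(np.float32)
        out = ss_conv_block(x, sw, pw)
        np.testing.assert_allclose(out, np.maximum(x, 0.0), atol=1e-6)

    def test_matches_nested_loop_convolution_oracle(self):
        rng = np.random.default_rng(2)
        c_in = c_out = 2
        x = rng.normal(size=(c_in, 4, 5, 5)).astype(np.float32)
        sw = rng.normal(size=(c_out, c_in, 3, 3)).astype(np.float32) * 0.3
        pw = rng.normal(size=(c_out, c_in, 3)).astype(np.float32) * 0.3
        got = ss_conv_block(x, sw, pw, relu=False)

        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
        expected = np.zeros_like(got)
        for o in range(c_out):
            for c in range(c_in):
                for d in range(4):
                    for y in range(5):
                        for xx in range(5):
                            acc = 0.0
                            for i in range(3):
                                for j in range(3):
                                    acc += sw[o, c, i, j] * xp[c, d + 1, y + i, xx + j]
                            for i in range(3):
                                acc += pw[o, c, i] * xp[c, d + i, y + 1, xx + 1]
                            expected[o, d, y, xx] += acc
        np.testing.assert_allclose(got, expected, atol=1e-5)


class TestArchitecture:
    @pytest.mark.parametrize("patch", [(8, 16, 16), (16, 32, 32), (12, 24, 40)])
    def test_output_shape_equals_input_shape(self, patch):
        cfg = DenoiserConfig(n_levels=2, blocks_per_level=1, base_channels=4,
                             patch_shape=patch, seed=0)
        model = build_denoiser(cfg)
        x = np.random.default_rng(0).normal(size=(1, 1, *patch)).astype(np.float32)
        assert model.net.forward(x).shape == x.shape

    def test_zeroed_residual_head_is_identity(self):
        model = build_denoiser(TINY)
        model.zero_residual_head()
        x = np.random.default_rng(1).normal(size=(2, 1, 16, 32, 32)).astype(np.float32)
        np.testing.assert_array_equal(model.net.forward(x), x)

    def test_parameter_count_matches_hand_tally(self):
        cfg = DenoiserConfig(n_levels=2, blocks_per_level=2, base_channels=8,
                             patch_shape=(8, 16, 16), seed=0)
        model = build_denoiser(cfg)
        # level-by-level tally, written out independently of the layer code:
        # encoder level 0: 1x1x1 (1->8): 1*8+8 ; 2 blocks of
        #   spatial 8*8*9 + spectral 8*8*3 + bias 8
        # encoder level 1: 1x1x1 (8->16): 8*16+16 ; 2 blocks at width 16
        # decoder level 0: 1x1x1 ((16+8)->8): 24*8+8 ; 2 blocks at width 8
        # head: 1x1x1 (8->1): 8+1
        block8 = 8 * 8 * 9 + 8 * 8 * 3 + 8
        block16 = 16 * 16 * 9 + 16 * 16 * 3 + 16
        expected = (
            (1 * 8 + 8) + 2 * block8
            + (8 * 16 + 16) + 2 * block16
            + (24 * 8 + 8) + 2 * block8
            + (8 * 1 + 1)
        )
        assert model.n_parameters == expected

    def test_incompatible_patch_and_pooling_rejected(self):
        with pytest.raises(ValueError):
            DenoiserConfig(n_levels=3, patch_shape=(8, 18, 18))

    def test_gradients_match_finite_differences(self):
        cfg = DenoiserConfig(n_levels=2, blocks_per_level=1, base_channels=3,
                             patch_shape=(4, 8, 8), seed=1)
        net = build_denoiser(cfg).net
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 1, 4, 8, 8)).astype(np.float32)
        y = rng.standard_normal((2, 1, 4, 8, 8)).astype(np.float32)

        net.zero_grad()
        pred = net.forward(x)
        net.backward((2.0 / pred.size * (pred - y)).astype(np.float32))
        params, grads = net.parameters()

        def loss():
            return float(np.mean((net.forward(x) - y) ** 2))

        check_rng = np.random.default_rng(1)
        for pi in [0, 3, 7, len(params) - 2, len(params) - 1]:
            p = params[pi]
            idx = tuple(check_rng.integers(s) for s in p.shape)
            eps, orig = 1e-3, p[idx]
            p[idx] = orig + eps
            lp = loss()
            p[idx] = orig - eps
            lm = loss()
            p[idx] = orig
            fd = (lp - lm) / (2 * eps)
            assert grads[pi][idx] == pytest.approx(fd, rel=0.02, abs=1e-4)


def _tiny_pairs(clean_stack, signal_mask, n=2, seed0=100):
    return [
        make_pair(clean_stack, 4, 1.4, seed0 + i, signal_mask) for i in range(n)
    ]


class TestTraining:
    def test_loss_decreases(self, clean_stack, signal_mask):
        model = train_denoiser(_tiny_pairs(clean_stack, signal_mask), TINY)
        assert model.training_history[-1] < model.training_history[0]
        assert len(model.training_history) == TINY.n_epochs

    def test_deterministic_given_seed(self, clean_stack, signal_mask):
        pairs = _tiny_pairs(clean_stack, signal_mask)
        a = train_denoiser(pairs, TINY)
        b = train_denoiser(pairs, TINY)
        for pa, pb in zip(a.net.parameters()[0], b.net.parameters()[0]):
            np.testing.assert_array_equal(pa, pb)

    def test_clean_targets_keep_near_identity(self, clean_stack, signal_mask):
        # raw == ground truth: the residual stays near zero and loss is tiny
        noisy = corrupt(clean_stack, 10.0, signal_mask, seed=0)
        pairs = [TrainingPair(raw=noisy, ground_truth=noisy, n_avg=1, seed=0)]
        model = train_denoiser(pairs, TINY)
        assert model.training_history[-1] < 1e-3
        out = denoise(noisy, model)
        rel = np.abs(out.data - noisy.data).mean() / np.abs(noisy.data).mean()
        assert rel < 0.2

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            train_denoiser([], TINY)


class TestDenoise:
    @staticmethod
    def _identity_model():
        model = build_denoiser(TINY)
        model.zero_residual_head()
        model.normalization = NormalizationParams(lo=0.0, hi=2.0)
        model.training_history = [0.0]
        return model

    def test_zeroed_head_round_trips_input(self, noisy_pair):
        out = denoise(noisy_pair.raw, self._identity_model())
        np.testing.assert_allclose(out.data, noisy_pair.raw.data, atol=1e-6)

    def test_untrained_model_rejected(self, noisy_pair):
        with pytest.raises(RuntimeError):
            denoise(noisy_pair.raw, build_denoiser(TINY))

    def test_tiled_matches_whole_stack(self, library3):
        # wide stack forces tiling along x; with a margin covering the
        # receptive field, crop-stitched tiles must agree with the single
        # whole-stack pass to well below the 1e-3 blending tolerance
        from srskit.simulate import build_phantom, random_cell_scene, render_clean_stack

        rng = np.random.default_rng(17)
        scene = random_cell_scene((32, 96), 3, rng, n_cells=3)
        maps = build_phantom(scene, 3)
        clean = render_clean_stack(maps, library3, 0.05)
        mask = maps.sum(axis=2) > 0
        model = train_denoiser(_tiny_pairs(clean, mask), TINY)
        raw = _tiny_pairs(clean, mask, n=1, seed0=500)[0].raw
        tiled = denoise(raw, model, tile_shape=(16, 32, 32))
        norm = model.normalization
        whole = norm.invert(model.net.forward(norm.apply(raw.data)[None, None])[0, 0])
        scale = norm.hi - norm.lo
        assert np.max(np.abs(tiled.data - whole)) / scale < 1e-3


class TestFineTune:
    def test_zero_epochs_leaves_model_unchanged(self, clean_stack, signal_mask):
        model = train_denoiser(_tiny_pairs(clean_stack, signal_mask), TINY)
        before = [p.copy() for p in model.net.parameters()[0]]
        fine_tune(model, _tiny_pairs(clean_stack, signal_mask), n_epochs=0)
        for b, p in zip(before, model.net.parameters()[0]):
            np.testing.assert_array_equal(b, p)

    def test_source_domain_loss_does_not_increase(self, clean_stack, signal_mask):
        pairs = _tiny_pairs(clean_stack, signal_mask)
        model = train_denoiser(pairs, TINY)
        before = model.training_history[-1]
        fine_tune(model, pairs, n_epochs=2)
        assert model.training_history[-1] < before * 1.5
        assert len(model.training_history) == TINY.n_epochs + 2

    def test_untrained_model_rejected(self, clean_stack, signal_mask):
        with pytest.raises(RuntimeError):
            fine_tune(build_denoiser(TINY), _tiny_pairs(clean_stack, signal_mask))


class TestCheckpoint:
    def test_save_load_roundtrip(self, tmp_path, clean_stack, signal_mask):
        model = train_denoiser(_tiny_pairs(clean_stack, signal_mask), TINY)
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        assert loaded.config == model.config
        assert loaded.training_history == model.training_history
        assert loaded.normalization == model.normalization
        x = np.random.default_rng(3).normal(
            size=(1, 1, 16, 32, 32)
        ).astype(np.float32)
        np.testing.assert_array_equal(
            loaded.net.forward(x), model.net.forward(x)
        )
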