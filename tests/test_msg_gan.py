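"""Multi-scale GAN: pyramids, relativistic hinge losses, gradient flow."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msgaug import (GanConfig, MsgGan, RelativisticScores, discriminator_loss,
                    generator_loss, real_pyramid, sample_images, train_gan)
from msgaug.msg_gan import load_checkpoint, save_checkpoint
from msgaug.nn import Tensor


def _scores(sr, sf):
    return RelativisticScores(np.asarray(sr, float), np.asarray(sf, float))


def _oracle_losses(sr, sf):
    """Element-wise re-evaluation of the joint hinge loss in plain numpy."""
    sr, sf = np.asarray(sr, float), np.asarray(sf, float)
    rf = sr - sf.mean()
    fr = sf - sr.mean()
    d = np.maximum(1 - rf, 0).mean() + np.maximum(1 + fr, 0).mean()
    g = np.maximum(1 + rf, 0).mean() + np.maximum(1 - fr, 0).mean()
    return d, g


class TestRelativisticLoss:
    @pytest.mark.parametrize("sr, sf, d_expect, g_expect", [
        ([3.0, 3.0], [3.0, 3.0], 2.0, 2.0),       # equal scores
        ([1.0, 1.0], [-1.0, -1.0], 0.0, 6.0),     # separated by margin
        ([2.0, 0.0], [0.0, -2.0], 0.0, 6.0),      # separated, unequal
    ])
    def test_analytic_cases(self, sr, sf, d_expect, g_expect):
        s = _scores(sr, sf)
        assert discriminator_loss(s) == pytest.approx(d_expect, abs=1e-7)
        assert generator_loss(s) == pytest.approx(g_expect, abs=1e-7)

    def test_rf_fr_definitional_identities(self, rng):
        sr, sf = rng.normal(size=13), rng.normal(size=7)
        s = _scores(sr, sf)
        assert np.array_equal(s.rf, sr - sf.mean())
        assert np.array_equal(s.fr, sf - sr.mean())

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_plain_arithmetic_oracle(self, seed):
        r = np.random.default_rng(seed)
        sr = r.normal(scale=3.0, size=r.integers(1, 20))
        sf = r.normal(scale=3.0, size=r.integers(1, 20))
        d_o, g_o = _oracle_losses(sr, sf)
        s = _scores(sr, sf)
        assert discriminator_loss(s) == pytest.approx(d_o, abs=1e-6)
        assert generator_loss(s) == pytest.approx(g_o, abs=1e-6)

    @given(st.floats(-50, 50))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_common_score_shift(self, c):
        r = np.random.default_rng(99)
        sr, sf = r.normal(size=9), r.normal(size=9)
        s0, s1 = _scores(sr, sf), _scores(sr + c, sf + c)
        assert np.allclose(s0.rf, s1.rf) and np.allclose(s0.fr, s1.fr)
        assert discriminator_loss(s0) == pytest.approx(discriminator_loss(s1), abs=1e-6)
        assert generator_loss(s0) == pytest.approx(generator_loss(s1), abs=1e-6)

    def test_empty_scores_rejected(self):
        with pytest.raises(ValueError):
            RelativisticScores([], [1.0])

    def test_zero_iff_margin_satisfied(self):
        assert discriminator_loss(_scores([1.5, 2.0], [-1.5, -2.0])) == 0.0
        # rf = 0.8 < 1: margin not met, loss strictly positive
        assert discriminator_loss(_scores([0.4], [-0.4])) > 0.0


class TestRealPyramid:
    def test_constant_image_constant_at_every_level(self):
        batch = np.full((2, 16, 16, 3), 0.25, np.float32)
        for level in real_pyramid(batch, 3):
            assert np.allclose(level, 0.25)

    def test_checkerboard_averages_to_zero_one_level_down(self):
        tile = np.array([[1.0, -1.0], [-1.0, 1.0]], np.float32)
        board = np.tile(tile, (8, 8))[None, :, :, None].repeat(3, axis=3)
        levels = real_pyramid(board, 3)
        assert np.allclose(levels[1], 0.0)   # 8x8 level: every 2x2 block sums to 0
        assert np.allclose(levels[0], 0.0)

    def test_top_level_is_input_bitwise(self, tiny_dataset):
        batch = tiny_dataset.images[:4]
        levels = real_pyramid(batch, 3)
        assert np.array_equal(levels[-1], batch.transpose(0, 3, 1, 2))
        assert [lv.shape[-1] for lv in levels] == [4, 8, 16]

    def test_resolution_mismatch_rejected(self):
        with pytest.raises(ValueError):
            real_pyramid(np.zeros((1, 16, 16, 3), np.float32), depth=4)


class TestNetworks:
    @pytest.mark.parametrize("depth, resolutions", [
        (3, (4, 8, 16)),
        (4, (4, 8, 16, 32)),
        (7, (4, 8, 16, 32, 64, 128, 256)),   # reference-scale block count
    ])
    def test_generator_pyramid_resolutions(self, depth, resolutions):
        cfg = GanConfig(latent_dim=16, depth=depth, base_channels=16, seed=0)
        gan = MsgGan(cfg)
        pyr = gan.generator(Tensor(np.random.default_rng(0)
                                   .standard_normal((2, 16))))
        assert tuple(lv.shape[-1] for lv in pyr) == resolutions
        for lv in pyr:
            assert np.abs(lv.data).max() <= 1.0    # tanh range

    def test_forward_deterministic_given_seeded_state(self):
        cfg = GanConfig(latent_dim=8, depth=3, base_channels=16, seed=5)
        z = np.random.default_rng(1).standard_normal((3, 8))
        a = [lv.data for lv in MsgGan(cfg).generator(Tensor(z))]
        b = [lv.data for lv in MsgGan(cfg).generator(Tensor(z))]
        for x, y in zip(a, b):
            assert np.array_equal(x, y)

    def test_latent_dim_mismatch_rejected(self):
        gan = MsgGan(GanConfig(latent_dim=8, depth=3, base_channels=16))
        with pytest.raises(ValueError):
            gan.generator(Tensor(np.zeros((2, 9))))

    def test_discriminator_returns_finite_scores(self):
        cfg = GanConfig(latent_dim=8, depth=3, base_channels=16, seed=2)
        gan = MsgGan(cfg)
        pyr = gan.generator(Tensor(np.random.default_rng(0).standard_normal((8, 8))))
        scores = gan.discriminator(pyr)
        assert scores.shape == (8,)
        assert np.all(np.isfinite(scores.data))

    def test_discriminator_depth_mismatch_rejected(self):
        gan = MsgGan(GanConfig(latent_dim=8, depth=3, base_channels=16))
        pyr = gan.generator(Tensor(np.zeros((1, 8), np.float32)))
        with pytest.raises(ValueError):
            gan.discriminator(pyr[:2])

    def test_every_pyramid_level_influences_score(self):
        """Finite-difference check: perturbing any single level moves D(x)."""
        cfg = GanConfig(latent_dim=8, depth=3, base_channels=16, seed=3)
        gan = MsgGan(cfg)
        levels = [np.random.default_rng(k).standard_normal(
            (2, 3, 2 ** (k + 2), 2 ** (k + 2))).astype(np.float32) * 0.3
            for k in range(3)]
        base = gan.discriminator([Tensor(lv) for lv in levels]).data.copy()
        for k in range(3):
            bumped = [lv.copy() for lv in levels]
            bumped[k] += 0.05
            new = gan.discriminator([Tensor(lv) for lv in bumped]).data
            assert np.abs(new - base).max() > 0

    def test_generator_loss_backward_reaches_every_block(self):
        """The multi-scale mechanism: one backward pass puts nonzero gradient
        into every generator block's parameters."""
        from msgaug.msg_gan import _gen_loss_t
        cfg = GanConfig(latent_dim=8, depth=3, base_channels=16, seed=4)
        gan = MsgGan(cfg)
        z = Tensor(np.random.default_rng(0).standard_normal((4, 8)))
        fake = gan.generator(z)
        sr = Tensor(np.random.default_rng(1).normal(size=4))
        sf = gan.discriminator(fake)
        gan.generator.zero_grad()
        _gen_loss_t(sr, sf).backward()
        for i in range(cfg.depth):
            block = getattr(gan.generator, f"block{i}")
            norms = [np.linalg.norm(p.grad) for p in block.parameters()
                     if p.grad is not None]
            assert norms and max(norms) > 0, f"no gradient in generator block {i}"


@pytest.fixture(scope="module")
def trained(tiny_dataset):
    cfg = GanConfig(latent_dim=32, depth=3, base_channels=16,
                    epochs=2, seed=7)
    return train_gan(tiny_dataset.restrict_to_class(1), cfg), cfg


class TestTraining:

    def test_run_completes_with_finite_losses(self, trained):
        (gan, log), cfg = trained
        assert len(log) == 2 * (40 // cfg.batch_size)
        assert np.isfinite(log.d_loss).all() and np.isfinite(log.g_loss).all()
        assert list(log.columns) == ["step", "epoch", "d_loss", "g_loss"]

    def test_same_seed_reproduces_loss_log(self, trained, tiny_dataset):
        (gan, log), cfg = trained
        _, log2 = train_gan(tiny_dataset.restrict_to_class(1), cfg)
        assert np.array_equal(log.values, log2.values)

    def test_mixed_class_input_rejected(self, tiny_dataset):
        with pytest.raises(ValueError):
            train_gan(tiny_dataset, GanConfig(latent_dim=8, depth=3,
                                              base_channels=16, epochs=1))

    def test_sampling_contract(self, trained):
        (gan, log), cfg = trained
        imgs = sample_images(gan, 10, seed=3)
        assert imgs.images.shape == (10, 16, 16, 3)
        assert np.all(imgs.labels == 1)
        assert imgs.images.min() >= -1 and imgs.images.max() <= 1
        again = sample_images(gan, 10, seed=3)
        assert np.array_equal(imgs.images, again.images)
        with pytest.raises(ValueError):
            sample_images(gan, 0, seed=1)

    def test_checkpoint_roundtrip_preserves_samples(self, trained, tmp_path):
        (gan, log), cfg = trained
        path = tmp_path / "gan.npz"
        save_checkpoint(gan, path)
        restored = load_checkpoint(path)
        a = sample_images(gan, 5, seed=11).images
        b = sample_images(restored, 5, seed=11).images
        assert np.array_equal(a, b)
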