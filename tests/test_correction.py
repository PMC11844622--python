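"""Correction losses (L1, perceptual, data consistency) and the Swin U-net."""

import numpy as np
import pytest
from scipy import ndimage

from mrimoco.correction import (CorrectionConfig, Corrector, FeatureExtractor,
                                dc_loss, l1_loss, lpips_loss, total_loss)
from mrimoco.kspace import ImageSlice


@pytest.fixture(scope="module")
def fe():
    return FeatureExtractor(seed=1234)


class TestL1Loss:
    def test_identical_images_zero(self, phantom64):
        assert l1_loss(phantom64.pixels, phantom64.pixels) == 0.0

    def test_constant_offset_closed_form(self):
        a = np.zeros((16, 16))
        assert l1_loss(a + 0.3, a) == pytest.approx(0.3, abs=1e-12)

    def test_symmetry(self, rng):
        a, b = rng.random((8, 8)), rng.random((8, 8))
        assert l1_loss(a, b) == l1_loss(b, a)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            l1_loss(np.zeros((4, 4)), np.zeros((5, 5)))


class TestLpipsLoss:
    def test_identical_inputs_zero(self, fe, phantom64):
        assert lpips_loss(phantom64.pixels, phantom64.pixels, fe) < 1e-8

    def test_symmetric_in_arguments(self, fe, rng):
        a, b = rng.random((32, 32)), rng.random((32, 32))
        assert lpips_loss(a, b, fe) == pytest.approx(lpips_loss(b, a, fe))

    def test_deterministic_for_fixed_seed(self, phantom64, rng):
        noisy = np.clip(phantom64.pixels + rng.normal(0, 0.1, (64, 64)), 0, 1)
        a = lpips_loss(noisy, phantom64.pixels, FeatureExtractor(seed=5))
        b = lpips_loss(noisy, phantom64.pixels, FeatureExtractor(seed=5))
        assert a == b

    def test_ranks_noise_above_blur_at_matched_l2(self, phantom64):
        """High-frequency noise should look perceptually worse than blur."""
        clean = phantom64.pixels
        blurred = ndimage.gaussian_filter(clean, 1.5)
        l2_blur = np.linalg.norm(blurred - clean)
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            noise = rng.standard_normal(clean.shape)
            noise *= l2_blur / np.linalg.norm(noise)  # matched L2 distortion
            fe_s = FeatureExtractor(seed=seed)
            if lpips_loss(clean + noise, clean, fe_s) > lpips_loss(
                    blurred, clean, fe_s):
                wins += 1
        assert wins >= 8  # monotone-in-perceptual-distortion spot check


class TestDcLoss:
    def test_identical_images_zero(self, phantom64):
        mask = np.ones(64)
        assert dc_loss(phantom64.pixels, phantom64.pixels, mask) == 0.0

    def test_all_zero_mask_ignores_any_difference(self, rng):
        a, b = rng.random((16, 16)), rng.random((16, 16))
        assert dc_loss(a, b, np.zeros(16)) == 0.0

    def test_support_property_single_frequency_oracle(self, phantom64):
        """Zero iff the spectral difference lives on unmasked lines only.

        A vertical cosine of frequency f occupies exactly the two centred
        PE lines 32 +/- f (all energy in the ky axis), so the loss's
        support can be probed line by line.
        """
        y = np.arange(64)[:, None]
        clean = phantom64.pixels
        mask = np.zeros(64)
        mask[20:24] = 1.0
        # f=5 -> rows 27 and 37: both unmasked -> loss exactly ignores it
        off_support = clean + 0.1 * np.cos(2 * np.pi * 5 * y / 64) * np.ones((1, 64))
        assert dc_loss(off_support, clean, mask) < 1e-24
        # f=12 -> rows 20 and 44: row 20 is masked -> strictly positive
        on_support = clean + 0.1 * np.cos(2 * np.pi * 12 * y / 64) * np.ones((1, 64))
        assert dc_loss(on_support, clean, mask) > 1e-8

    def test_per_sample_mask_batch(self, rng):
        a = rng.random((2, 8, 8))
        b = rng.random((2, 8, 8))
        masks = np.stack([np.ones(8), np.zeros(8)])
        batched = dc_loss(a, b, masks)
        assert batched > 0


class TestTotalLoss:
    def test_identical_images_all_terms_zero(self, fe, phantom64):
        cfg = CorrectionConfig()
        total, parts = total_loss(phantom64.pixels, phantom64.pixels,
                                  np.ones(64), cfg, fe)
        assert float(total) == 0.0
        assert parts == {"l1": 0.0, "lpips": 0.0, "dc": 0.0}

    def test_weighted_arithmetic(self):
        # L1=0.1, Llpips=0.2, Ldc=0.01 at default weights -> 2.1
        assert 10.0 * 0.1 + 0.5 * 0.2 + 100.0 * 0.01 == pytest.approx(2.1)
        cfg = CorrectionConfig()
        assert (cfg.lambda_r, cfg.lambda_l, cfg.lambda_d) == (10.0, 0.5, 100.0)

    def test_zeroed_weights_reduce_to_pure_l1(self, fe, phantom64, rng):
        cfg = CorrectionConfig(lambda_l=0.0, lambda_d=0.0)
        noisy = np.clip(phantom64.pixels + rng.normal(0, 0.05, (64, 64)), 0, 1)
        total, _ = total_loss(noisy, phantom64.pixels, np.ones(64), cfg, fe)
        assert float(total) == pytest.approx(
            10.0 * l1_loss(noisy, phantom64.pixels), rel=1e-12)

    def test_linear_in_each_weight(self, fe, phantom64, rng):
        noisy = np.clip(phantom64.pixels + rng.normal(0, 0.05, (64, 64)), 0, 1)
        mask = np.ones(64)
        base, parts = total_loss(noisy, phantom64.pixels, mask,
                                 CorrectionConfig(), fe)
        doubled, _ = total_loss(noisy, phantom64.pixels, mask,
                                CorrectionConfig(lambda_r=20.0), fe)
        assert float(doubled) - float(base) == pytest.approx(
            10.0 * parts["l1"], rel=1e-9)


class TestCorrector:
    def test_invalid_dc_mask_rejected(self):
        with pytest.raises(ValueError, match="dc_mask"):
            CorrectionConfig(dc_mask="oracle")

    def test_untrained_net_is_identity_with_zero_init_head(self, phantom64):
        corr = Corrector(CorrectionConfig(depth=2, base_width=4, window=4))
        out = corr.correct(phantom64)
        assert np.abs(out.pixels - phantom64.pixels).max() < 1e-3
        assert out.pixels.min() >= 0 and out.pixels.max() <= 1

    def test_output_shape_and_finiteness(self, rng):
        corr = Corrector(CorrectionConfig(depth=2, base_width=4, window=4))
        x = rng.random((32, 32))
        out = corr.correct(ImageSlice(x))
        assert out.pixels.shape == (32, 32)
        assert np.isfinite(out.pixels).all()

    def test_incompatible_shape_rejected_with_padding_hint(self):
        corr = Corrector(CorrectionConfig(depth=2, base_width=4, window=4))
        with pytest.raises(ValueError, match="pad to"):
            corr.correct(ImageSlice(np.zeros((24, 24))))
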