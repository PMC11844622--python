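"""Spatial averaging, segmentation losses and the detector's contracts."""

import numpy as np
import pytest

from mrimoco.detection import (DetectionConfig, Detector, bce_loss, dice_loss,
                               kspace_channels, peripheral_exclusion_mask,
                               spatial_average)
from mrimoco.kspace import to_kspace
from mrimoco.motion import simulate
from mrimoco.nn.engine import Tensor


class TestSpatialAverage:
    def test_row_mean_oracle(self):
        raw = np.zeros((4, 6))
        raw[1] = [0, 1, 0, 1, 0, 1]  # alternating line -> 0.5
        raw[2] = 0.25
        mask = spatial_average(raw)
        assert mask.values[0] == 0
        assert mask.values[1] == pytest.approx(0.5)
        assert mask.values[2] == pytest.approx(0.25)

    def test_idempotent_on_row_constant_maps(self):
        rng = np.random.default_rng(0)
        col = rng.random(8)
        raw = np.repeat(col[:, None], 5, axis=1)
        assert np.allclose(spatial_average(raw).values, col)

    def test_projection_property(self):
        rng = np.random.default_rng(1)
        raw = rng.random((8, 8))
        once = spatial_average(raw)
        twice = spatial_average(once.to_2d(8))
        assert np.allclose(once.values, twice.values)

    def test_all_zero_map_gives_zero_mask(self):
        assert spatial_average(np.zeros((6, 6))).values.sum() == 0

    def test_tensor_path_matches_numpy_path(self):
        rng = np.random.default_rng(2)
        raw = rng.random((3, 1, 8, 8))
        t = spatial_average(Tensor(raw))
        assert t.shape == (3, 1, 8, 1)
        assert np.allclose(t.data[0, 0, :, 0], raw[0, 0].mean(axis=1))


class TestDiceLoss:
    def test_perfect_overlap_near_zero(self):
        m = np.array([0, 1, 1, 0, 1], dtype=float)
        assert dice_loss(m, m) <= 1e-6

    def test_disjoint_masks_near_one(self):
        a = np.array([1, 1, 0, 0], dtype=float)
        b = np.array([0, 0, 1, 1], dtype=float)
        assert dice_loss(a, b) >= 1 - 1e-5

    def test_hand_worked_example(self):
        """|Mp ∩ MGT| = 1, |Mp| + |MGT| = 3 -> loss 1 - 2/3 = 1/3."""
        mgt = np.array([1, 1, 0, 0], dtype=float)
        mp = np.array([1, 0, 0, 0], dtype=float)
        assert dice_loss(mp, mgt) == pytest.approx(1 / 3, abs=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            dice_loss(np.zeros(3), np.zeros(4))


class TestBceLoss:
    def test_uniform_half_prediction_is_ln2(self):
        mgt = np.array([0, 1, 1, 0], dtype=float)
        assert bce_loss(np.full(4, 0.5), mgt) == pytest.approx(np.log(2), abs=1e-9)

    def test_confident_correct_prediction_near_zero(self):
        mgt = np.array([0.0, 1.0])
        assert bce_loss(mgt, mgt) < 1e-5

    def test_confident_wrong_prediction_hits_clip_ceiling(self):
        mgt = np.array([1.0, 0.0])
        wrong = np.array([0.0, 1.0])
        assert bce_loss(wrong, mgt, clip=1e-7) == pytest.approx(-np.log(1e-7),
                                                               rel=1e-6)

    def test_gradient_flows_through_tensor_inputs(self):
        mp = Tensor(np.array([0.3, 0.7]), requires_grad=True)
        loss = bce_loss(mp, Tensor(np.array([0.0, 1.0])))
        loss.backward()
        assert mp.grad is not None and np.isfinite(mp.grad).all()


class TestDetector:
    def test_averaged_mask_constant_along_frequency_axis(self, phantom64):
        corrupted, _, _ = simulate(phantom64, "minor", seed=0)
        det = Detector(DetectionConfig(depth=2, base_width=4))
        pm = det.detect(to_kspace(corrupted))
        two_d = pm.averaged.to_2d(64)
        assert np.all(two_d == two_d[:, :1])  # structural guarantee

    def test_untrained_outputs_within_unit_interval(self, phantom64):
        corrupted, _, _ = simulate(phantom64, "moderate", seed=1)
        det = Detector(DetectionConfig(depth=2, base_width=4, init_seed=9))
        pm = det.detect(to_kspace(corrupted))
        assert pm.raw.min() >= 0 and pm.raw.max() <= 1
        assert set(np.unique(pm.binary.values)) <= {0.0, 1.0}

    def test_peripheral_lines_forced_to_zero(self, phantom64):
        corrupted, _, _ = simulate(phantom64, "moderate", seed=1)
        det = Detector(DetectionConfig(depth=2, base_width=4))
        pm = det.detect(to_kspace(corrupted))
        n_edge = int(round(0.05 * 64))
        assert pm.averaged.values[:n_edge].sum() == 0
        assert pm.averaged.values[-n_edge:].sum() == 0

    def test_indivisible_input_rejected_with_padding_hint(self):
        det = Detector(DetectionConfig(depth=2, base_width=4))
        bad = np.zeros((30, 30), dtype=complex)
        with pytest.raises(ValueError, match="pad to"):
            det.detect(bad)

    def test_kspace_channels_are_finite_and_standardised(self, phantom64):
        ks = to_kspace(phantom64)
        ch = kspace_channels(ks)
        assert ch.shape == (2, 64, 64)
        assert np.isfinite(ch).all()
        assert abs(ch[0].mean()) < 1e-10

    def test_peripheral_exclusion_mask_width(self):
        keep = peripheral_exclusion_mask(64, 0.05)
        assert keep[:3].sum() == 0 and keep[-3:].sum() == 0
        assert keep.sum() == 64 - 6
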