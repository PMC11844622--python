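"""Motion events, corruption masks and k-space line splicing."""

import numpy as np
import pytest

from mrimoco.kspace import to_kspace
from mrimoco.motion import (PRESETS, LineMask, MotionEvent, SeverityPreset,
                            build_mask, center_band, corrupt, sample_events,
                            simulate)


class TestSampling:
    @pytest.mark.parametrize("name,n", [("minor", 5), ("moderate", 10),
                                        ("heavy", 15)])
    def test_preset_slab_counts_and_width_bounds(self, name, n):
        events = sample_events(PRESETS[name], height=256, rng=0)
        assert len(events) == n
        assert all(3 <= e.slab_width <= 7 for e in events)

    def test_zero_slabs_gives_empty_list(self):
        preset = SeverityPreset("none", 0)
        assert sample_events(preset, height=64, rng=0) == []

    def test_parameter_distribution_bounds_and_mean(self):
        rng = np.random.default_rng(42)
        thetas, txs = [], []
        for _ in range(2000):  # 2000 draws x 5 events = 10,000 samples
            for e in sample_events(PRESETS["minor"], height=256, rng=rng):
                thetas.append(e.theta_deg)
                txs.append(e.tx_mm)
        thetas = np.array(thetas)
        assert thetas.min() >= -7 and thetas.max() <= 7
        assert np.array(txs).min() >= -5 and np.array(txs).max() <= 5
        sigma = 7 / np.sqrt(3) / np.sqrt(thetas.size)  # SE of uniform mean
        assert abs(thetas.mean()) < 3 * sigma

    def test_slabs_disjoint_and_clear_of_centre(self):
        rng = np.random.default_rng(1)
        lo, hi = center_band(128)
        for _ in range(50):
            events = sample_events(PRESETS["heavy"], height=128, rng=rng)
            lines = [r for e in events for r in e.lines]
            assert len(lines) == len(set(lines))          # pairwise disjoint
            assert all(r < lo or r >= hi for r in lines)  # centre protected

    def test_too_small_grid_raises_with_required_height(self):
        with pytest.raises(ValueError, match="at least"):
            sample_events(PRESETS["heavy"], height=16, rng=0)


class TestMask:
    def test_no_events_gives_zero_mask(self):
        assert build_mask([], 64).values.sum() == 0

    def test_mask_counts_equal_total_slab_width(self):
        events = sample_events(PRESETS["moderate"], height=128, rng=3)
        mask = build_mask(events, 128)
        assert mask.values.sum() == sum(e.slab_width for e in events)

    def test_centre_band_stays_zero_even_for_overlapping_event(self):
        lo, hi = center_band(64)
        ev = MotionEvent(1.0, 0.0, 0.0, slab_start=lo - 1,
                         slab_width=(hi - lo) + 2)
        mask = build_mask([ev], 64)
        assert mask.values[lo:hi].sum() == 0
        assert mask.values[lo - 1] == 1 and mask.values[hi] == 1

    def test_binary_line_mask_validates_values(self):
        with pytest.raises(ValueError):
            LineMask(np.array([0.0, 0.5, 1.0]), binary=True)
        m = LineMask(np.array([0.2, 0.8]), binary=False)
        assert m.to_2d(3).shape == (2, 3)
        assert np.all(m.to_2d(3)[1] == 0.8)


class TestCorrupt:
    def test_empty_event_list_is_identity(self, phantom64):
        ks = to_kspace(phantom64)
        out, mask = corrupt(ks, [])
        assert np.array_equal(out.coeffs, ks.coeffs)
        assert mask.values.sum() == 0

    def test_identity_transform_slab_within_tolerance(self, phantom64):
        ks = to_kspace(phantom64)
        ev = MotionEvent(0.0, 0.0, 0.0, slab_start=5, slab_width=4)
        out, _ = corrupt(ks, [ev])
        assert np.abs(out.coeffs - ks.coeffs).max() < 1e-10

    def test_per_line_splice_exactness(self, phantom64):
        from mrimoco.kspace import kspace_rigid
        ks = to_kspace(phantom64)
        ev = MotionEvent(5.0, 2.0, 0.0, slab_start=10, slab_width=4)
        out, mask = corrupt(ks, [ev])
        transformed = kspace_rigid(ks, 5.0, 2.0, 0.0)
        assert np.array_equal(out.coeffs[10:14], transformed.coeffs[10:14])
        # neighbours untouched, bit-exactly
        assert np.array_equal(out.coeffs[9], ks.coeffs[9])
        assert np.array_equal(out.coeffs[14], ks.coeffs[14])
        assert np.array_equal(mask.values[10:14], np.ones(4))

    def test_uncorrupted_lines_bit_identical(self, phantom64):
        ks = to_kspace(phantom64)
        rng = np.random.default_rng(9)
        events = sample_events(PRESETS["moderate"], height=64, rng=rng)
        out, mask = corrupt(ks, events)
        untouched = mask.values == 0
        assert np.array_equal(out.coeffs[untouched], ks.coeffs[untouched])


class TestSimulate:
    def test_seeded_runs_are_identical(self, phantom64):
        a, ma, _ = simulate(phantom64, "minor", seed=11)
        b, mb, _ = simulate(phantom64, "minor", seed=11)
        assert np.array_equal(a.pixels, b.pixels)
        assert np.array_equal(ma.values, mb.values)

    def test_minor_preset_changes_the_image(self, phantom64):
        corrupted, _, _ = simulate(phantom64, "minor", seed=2)
        assert np.abs(corrupted.pixels - phantom64.pixels).max() > 1e-6

    def test_mask_matches_event_provenance(self, phantom64):
        _, mask, events = simulate(phantom64, "moderate", seed=5)
        rebuilt = build_mask(events, 64)
        assert np.array_equal(mask.values, rebuilt.values)
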