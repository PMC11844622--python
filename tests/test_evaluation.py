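"""Metric correctness vs independent references, bootstrap and group tests."""

import numpy as np
import pytest
from skimage.metrics import peak_signal_noise_ratio as sk_psnr
from skimage.metrics import structural_similarity as sk_ssim

from mrimoco.evaluation import (bootstrap_ci, compare_methods, difference_map,
                                evaluate_pairs, nmse, psnr, ssim)


class TestPsnr:
    def test_identical_images_capped_at_100db(self, phantom64):
        assert psnr(phantom64.pixels, phantom64.pixels) == 100.0

    def test_closed_form_mse_1e4_is_40db(self):
        a = np.zeros((100, 100))
        b = np.full((100, 100), 0.01)   # MSE = 1e-4 at range 1
        assert psnr(a, b) == pytest.approx(40.0, abs=1e-9)

    def test_noise_strictly_decreases_psnr(self, phantom64, rng):
        mild = np.clip(phantom64.pixels + rng.normal(0, 0.01, (64, 64)), 0, 1)
        strong = np.clip(phantom64.pixels + rng.normal(0, 0.1, (64, 64)), 0, 1)
        assert psnr(strong, phantom64.pixels) < psnr(mild, phantom64.pixels)

    def test_matches_skimage_reference(self, rng):
        for _ in range(20):
            a, b = rng.random((32, 32)), rng.random((32, 32))
            assert psnr(a, b) == pytest.approx(
                sk_psnr(b, a, data_range=1.0), abs=1e-6)


class TestSsim:
    def test_self_similarity_is_one(self, phantom64):
        assert ssim(phantom64.pixels, phantom64.pixels) == pytest.approx(1.0)

    def test_symmetric(self, rng):
        a, b = rng.random((48, 48)), rng.random((48, 48))
        assert ssim(a, b) == pytest.approx(ssim(b, a), abs=1e-12)

    def test_matches_skimage_reference(self, rng):
        """Independent oracle: Gaussian-weighted SSIM, 20 random pairs."""
        for _ in range(20):
            a, b = rng.random((48, 48)), rng.random((48, 48))
            ref = sk_ssim(a, b, data_range=1.0, gaussian_weights=True,
                          sigma=1.5, use_sample_covariance=True)
            assert ssim(a, b) == pytest.approx(ref, abs=1e-4)


class TestNmse:
    def test_identical_images_zero(self, phantom64):
        assert nmse(phantom64.pixels, phantom64.pixels) == 0.0

    def test_zero_prediction_is_100_percent(self, phantom64):
        assert nmse(np.zeros((64, 64)), phantom64.pixels) == pytest.approx(100.0)

    def test_definition_squared_norm_ratio(self, rng):
        a, b = rng.random((16, 16)), rng.random((16, 16)) + 0.1
        expect = np.sum((a - b) ** 2) / np.sum(b ** 2) * 100
        assert nmse(a, b) == pytest.approx(expect, abs=1e-8)

    def test_zero_energy_reference_rejected(self):
        with pytest.raises(ValueError, match="zero-energy"):
            nmse(np.ones((8, 8)), np.zeros((8, 8)))


class TestBootstrap:
    def test_constant_sample_zero_width(self):
        lo, hi = bootstrap_ci(np.full(20, 3.5))
        assert lo == hi == 3.5

    def test_percentile_width_matches_asymptotic_normal(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(1000)
        lo, hi = bootstrap_ci(x, n_iter=10_000, method="percentile", seed=1)
        assert lo < 0 < hi
        expected_width = 2 * 1.96 / np.sqrt(1000)
        assert abs((hi - lo) - expected_width) / expected_width < 0.20

    def test_bca_close_to_percentile_for_symmetric_sample(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(400)
        p = bootstrap_ci(x, n_iter=5000, method="percentile", seed=3)
        b = bootstrap_ci(x, n_iter=5000, method="bca", seed=3)
        assert p[0] == pytest.approx(b[0], abs=1e-2)
        assert p[1] == pytest.approx(b[1], abs=1e-2)

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci(np.array([1.0]))


class TestCompareMethods:
    def test_type_i_error_calibration(self):
        """Same-distribution groups: p > 0.05 in at least 90% of replicates."""
        rng = np.random.default_rng(4)
        not_rejected = 0
        for _ in range(50):
            g1 = rng.standard_normal(200)
            g2 = rng.standard_normal(200)
            res = compare_methods({"a": g1, "b": g2})
            not_rejected += res["anova"]["p"] > 0.05
        assert not_rejected >= 45

    def test_power_for_large_offset(self):
        rng = np.random.default_rng(5)
        g1 = rng.standard_normal(100)
        g2 = rng.standard_normal(100) + 5.0  # 5 SD apart
        res = compare_methods({"a": g1, "b": g2})
        assert res["anova"]["p"] < 1e-6
        assert res["tukey"][0]["significant"]

    def test_tukey_pair_count(self):
        rng = np.random.default_rng(6)
        groups = {f"m{i}": rng.standard_normal(30) for i in range(4)}
        res = compare_methods(groups)
        assert len(res["tukey"]) == 4 * 3 // 2

    def test_tukey_meandiffs_match_group_means(self):
        rng = np.random.default_rng(7)
        groups = {"a": rng.standard_normal(50),
                  "b": rng.standard_normal(50) + 1.0}
        res = compare_methods(groups)
        pair = res["tukey"][0]
        expect = groups["b"].mean() - groups["a"].mean()
        assert pair["meandiff"] == pytest.approx(expect, abs=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 groups"):
            compare_methods({"only": np.arange(5.0)})


class TestDifferenceMapAndReport:
    def test_identical_images_zero_map(self, phantom64):
        assert np.all(difference_map(phantom64.pixels, phantom64.pixels) == 0)

    def test_linearity_of_mean_and_max(self, rng):
        a, b = rng.random((16, 16)), rng.random((16, 16))
        d = difference_map(a, b)
        assert d.mean() == pytest.approx(a.mean() - b.mean(), abs=1e-10)
        assert np.abs(d).max() == np.abs(a - b).max()

    def test_report_summary_orders_ci_around_mean(self, rng):
        preds = rng.random((6, 32, 32))
        refs = np.clip(preds + rng.normal(0, 0.05, preds.shape), 0, 1)
        report = evaluate_pairs(preds, refs, method="test", severity="minor")
        summary = report.summarize(n_iter=500, method="percentile", seed=0)
        for metric in ("psnr_db", "ssim", "nmse_pct"):
            s = summary[metric]
            assert s["ci_low"] <= s["mean"] <= s["ci_high"]
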