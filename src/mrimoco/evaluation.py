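"""Image-quality metrics, bootstrap confidence intervals and group tests.

Metric definitions (``x`` is the reference, ``xhat`` the reconstruction,
both in [0, 1] unless another data range is given):

* PSNR  = 10 log10(range^2 / MSE), in dB; identical images report the
  100 dB cap so perfect reconstructions aggregate finitely.
* SSIM  with the standard 11x11 Gaussian window (sigma 1.5), K1=0.01,
  K2=0.03.
* NMSE  = ||xhat - x||_2^2 / ||x||_2^2 * 100, in percent.  NMSE
  conventions vary; this is the squared-norm ratio.

Group summaries use 95% bootstrap confidence intervals (percentile or
BCa), and between-method comparisons use one-way ANOVA followed by Tukey's
HSD at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

PSNR_CAP_DB = 100.0

__all__ = [
    "MetricReport", "psnr", "ssim", "nmse", "evaluate_pairs",
    "bootstrap_ci", "compare_methods", "difference_map", "PSNR_CAP_DB",
]


def _check_pair(xhat, x) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(xhat, dtype=np.float64)
    b = np.asarray(x, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def psnr(xhat, x, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB, capped at 100 dB."""
    a, b = _check_pair(xhat, x)
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return PSNR_CAP_DB
    return float(min(10.0 * np.log10(data_range ** 2 / mse), PSNR_CAP_DB))


def ssim(xhat, x, data_range: float = 1.0, sigma: float = 1.5,
         win_size: int = 11, k1: float = 0.01, k2: float = 0.03) -> float:
    """Mean structural similarity with a Gaussian weighting window."""
    a, b = _check_pair(xhat, x)
    truncate = (win_size - 1) / 2 / sigma  # Gaussian support = win_size
    blur = lambda im: ndimage.gaussian_filter(im, sigma, truncate=truncate,
                                              mode="reflect")
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    mu_a, mu_b = blur(a), blur(b)
    mu_aa, mu_bb, mu_ab = mu_a * mu_a, mu_b * mu_b, mu_a * mu_b
    var_a = blur(a * a) - mu_aa
    var_b = blur(b * b) - mu_bb
    cov = blur(a * b) - mu_ab
    # sample-variance correction as in the standard implementation
    npix = win_size ** 2
    corr = npix / (npix - 1)
    var_a, var_b, cov = var_a * corr, var_b * corr, cov * corr
    s = ((2 * mu_ab + c1) * (2 * cov + c2)) / (
        (mu_aa + mu_bb + c1) * (var_a + var_b + c2))
    pad = (win_size - 1) // 2  # crop the filter's edge effects
    return float(s[pad:-pad, pad:-pad].mean())


def nmse(xhat, x) -> float:
    """Normalised mean square error in percent: ||e||^2 / ||x||^2 * 100."""
    a, b = _check_pair(xhat, x)
    denom = float(np.sum(b ** 2))
    if denom == 0.0:
        raise ValueError("NMSE undefined for a zero-energy reference image")
    return float(np.sum((a - b) ** 2) / denom * 100.0)


@dataclass
class MetricReport:
    """Per-image metrics for one (method, severity) group plus 95% CIs."""

    method: str
    severity: str
    psnr_db: np.ndarray
    ssim: np.ndarray
    nmse_pct: np.ndarray
    summary: dict = field(default_factory=dict)

    def summarize(self, n_iter: int = 10_000, method: str = "bca",
                  seed: int = 0) -> dict:
        self.summary = {}
        for name in ("psnr_db", "ssim", "nmse_pct"):
            vals = np.asarray(getattr(self, name), dtype=np.float64)
            lo, hi = bootstrap_ci(vals, n_iter=n_iter, method=method, seed=seed)
            self.summary[name] = {"mean": float(vals.mean()),
                                  "ci_low": lo, "ci_high": hi}
        return self.summary


def evaluate_pairs(predictions: np.ndarray, references: np.ndarray,
                   method: str = "", severity: str = "") -> MetricReport:
    """Per-slice PSNR/SSIM/NMSE for stacks of shape (n, H, W)."""
    preds = np.asarray(predictions)
    refs = np.asarray(references)
    if preds.shape != refs.shape:
        raise ValueError(f"stack shapes differ: {preds.shape} vs {refs.shape}")
    ps, ss, nm = [], [], []
    for a, b in zip(preds, refs):
        ps.append(psnr(a, b))
        ss.append(ssim(a, b))
        nm.append(nmse(a, b))
    return MetricReport(method=method, severity=severity,
                        psnr_db=np.array(ps), ssim=np.array(ss),
                        nmse_pct=np.array(nm))


def bootstrap_ci(samples, n_iter: int = 10_000, method: str = "percentile",
                 confidence: float = 0.95, seed: int | None = 0,
                 ) -> tuple[float, float]:
    """95% bootstrap CI of the mean (percentile or BCa), seeded.

    A constant sample yields the degenerate zero-width interval (c, c).
    """
    x = np.asarray(samples, dtype=np.float64).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 samples for a bootstrap CI")
    if np.ptp(x) == 0.0:
        return float(x[0]), float(x[0])
    rng = np.random.default_rng(seed)
    if method == "percentile":
        idx = rng.integers(0, x.size, size=(n_iter, x.size))
        means = x[idx].mean(axis=1)
        alpha = (1.0 - confidence) / 2.0
        lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
        return float(lo), float(hi)
    if method == "bca":
        res = stats.bootstrap((x,), np.mean, n_resamples=n_iter,
                              confidence_level=confidence, method="BCa",
                              random_state=rng, vectorized=True, axis=-1)
        return float(res.confidence_interval.low), float(res.confidence_interval.high)
    raise ValueError(f"unknown bootstrap method {method!r}")


def compare_methods(groups: dict[str, np.ndarray], alpha: float = 0.05) -> dict:
    """One-way ANOVA across methods, then all-pairs Tukey HSD.

    ``groups`` maps method name to a 1-D array of per-image metric values.
    Returns ``{"anova": {"F", "p"}, "tukey": [...pairs...]}``.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to compare")
    arrays = {k: np.asarray(v, dtype=np.float64).ravel() for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs at least 2 observations")
    f_stat, p_val = stats.f_oneway(*arrays.values())
    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[k] * v.size for k, v in arrays.items()])
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    from itertools import combinations
    pair_names = list(combinations(tukey.groupsunique, 2))
    pairs = []
    for (g1, g2), diff, p_adj, lo, hi, reject in zip(
            pair_names, tukey.meandiffs, tukey.pvalues,
            tukey.confint[:, 0], tukey.confint[:, 1], tukey.reject):
        pairs.append({"group1": str(g1), "group2": str(g2),
                      "meandiff": float(diff), "p_adj": float(p_adj),
                      "ci_low": float(lo), "ci_high": float(hi),
                      "significant": bool(reject)})
    return {"anova": {"F": float(f_stat), "p": float(p_val)}, "tukey": pairs}


def difference_map(xhat, x, out_png: str | None = None):
    """Signed difference ``xhat - x`` with an optional symmetric rendering."""
    a, b = _check_pair(xhat, x)
    diff = a - b
    if out_png is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        vmax = np.abs(diff).max() or 1.0
        fig, ax = plt.subplots(figsize=(4, 4))
        im = ax.imshow(diff, cmap="seismic", vmin=-vmax, vmax=vmax)
        fig.colorbar(im, ax=ax, shrink=0.8)
        ax.set_axis_off()
        fig.savefig(out_png, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return diff
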