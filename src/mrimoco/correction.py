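"""Motion correction: residual Swin U-net and the composite loss.

The corrector maps a motion-corrupted magnitude image to a corrected one.
Its training loss combines three terms::

    L = lambda_r * L1  +  lambda_l * L_perc  +  lambda_d * L_dc

* ``L1`` — mean absolute error in the image domain (data fidelity).
* ``L_perc`` — perceptual distance: summed squared differences between
  activation maps of a fixed convolutional feature extractor (an
  LPIPS-style metric).  With no pretrained weights supplied, a fixed-seed
  random-weight extractor is used — random convolutional features are a
  serviceable perceptual metric for ranking distortions.
* ``L_dc`` — k-space data consistency: squared error between the Fourier
  transforms of output and ground truth restricted to the corrupted lines
  given by a mask (predicted by the detector, or ground truth by config).

Default weights are ``lambda_r=10, lambda_l=0.5, lambda_d=100``.  All
norms use mean reductions so the weights transfer across image sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kspace import ImageSlice
from .nn.engine import Tensor, conv2d
from .nn.layers import Conv2d, Module
from .nn.swin import SwinUNet

__all__ = [
    "CorrectionConfig", "FeatureExtractor", "Corrector",
    "l1_loss", "lpips_loss", "dc_loss", "total_loss",
]


@dataclass(frozen=True)
class CorrectionConfig:
    lambda_r: float = 10.0
    lambda_l: float = 0.5
    lambda_d: float = 100.0
    depth: int = 2
    base_width: int = 16
    window: int = 8
    n_heads: int = 2
    blocks_per_stage: int = 2
    dc_mask: str = "predicted"          # {"predicted", "ground_truth"}
    feature_seed: int = 1234
    init_seed: int = 0

    def __post_init__(self):
        if self.dc_mask not in ("predicted", "ground_truth"):
            raise ValueError(f"dc_mask must be 'predicted' or 'ground_truth', got {self.dc_mask!r}")


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def _as_batch(x) -> Tensor:
    """Promote (H,W) / (N,H,W) to an (N,1,H,W) tensor."""
    t = _as_tensor(x)
    if t.ndim == 2:
        t = t.reshape(1, 1, *t.shape)
    elif t.ndim == 3:
        t = t.reshape(t.shape[0], 1, *t.shape[1:])
    return t


def l1_loss(xhat, xgt):
    """Mean absolute error between two images (or batches)."""
    a, b = _as_tensor(xhat), _as_tensor(xgt)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    out = (a - b).abs().mean()
    return out if isinstance(xhat, Tensor) else float(out.data)


class FeatureExtractor(Module):
    """Three-stage strided conv net providing activation maps phi_i.

    Weights are fixed (never trained): drawn once from a seeded generator,
    or loaded from a checkpoint of pretrained weights when available.
    Outputs are deterministic for fixed weights and input.
    """

    def __init__(self, seed: int = 1234, base_width: int = 8,
                 state: dict[str, np.ndarray] | None = None):
        rng = np.random.default_rng(seed)
        w = base_width
        self.stages = [
            Conv2d(1, w, 3, rng, stride=1),   # full-resolution stage
            Conv2d(w, 2 * w, 3, rng, stride=2),
            Conv2d(2 * w, 4 * w, 3, rng, stride=2),
        ]
        params = self.named_parameters()   # capture before freezing
        if state is not None:
            if set(state) != set(params):
                raise KeyError(f"feature-extractor state keys do not match: {sorted(params)}")
            for k, p in params.items():
                p.data = np.asarray(state[k], dtype=np.float64).reshape(p.data.shape).copy()
        for p in params.values():          # frozen: features only, never trained
            p.requires_grad = False

    def features(self, x: Tensor) -> list[Tensor]:
        """Channel-unit-normalised activation maps, one per stage.

        Unit normalisation across channels (as in LPIPS) stops
        high-amplitude edge responses from drowning out spatially
        distributed distortions such as noise.
        """
        feats = []
        for stage in self.stages:
            x = conv2d(x, stage.w, stage.b, stride=stage.stride,
                       padding=stage.padding).leaky_relu()
            norm = ((x * x).sum(axis=1, keepdims=True) + 1e-8) ** -0.5
            feats.append(x * norm)
        return feats


def lpips_loss(xhat, xgt, fe: FeatureExtractor):
    """Perceptual loss: sum over stages of mean squared feature distance."""
    a, b = _as_batch(xhat), _as_batch(xgt)
    fa, fb = fe.features(a), fe.features(b)
    total = None
    for pa, pb in zip(fa, fb):
        term = ((pa - pb) ** 2.0).mean()
        total = term if total is None else total + term
    return total if isinstance(xhat, Tensor) else float(total.data)


def dc_loss(xhat, xgt, mask_lines: np.ndarray):
    """k-space data-consistency loss on masked phase-encoding lines.

    ``mask_lines`` is a per-line vector (H,) in [0, 1]; the loss is the
    mean squared difference of the centred orthonormal spectra of the two
    images, restricted to masked lines.  It is identically zero when the
    images agree on every masked line, whatever happens elsewhere.
    """
    a, b = _as_batch(xhat), _as_batch(xgt)
    m = np.asarray(getattr(mask_lines, "values", mask_lines), dtype=np.float64)
    ka, kb = a.fft2c(), b.fft2c()            # (N,1,2,H,W)
    if m.ndim == 1:                          # one mask for the whole batch
        mask = Tensor(m[None, None, None, :, None])
    elif m.ndim == 2:                        # per-sample (N, H) masks
        mask = Tensor(m[:, None, None, :, None])
    else:
        raise ValueError(f"mask must be (H,) or (N, H), got shape {m.shape}")
    diff = (ka - kb) * mask
    out = (diff ** 2.0).mean()
    return out if isinstance(xhat, Tensor) else float(out.data)


def total_loss(xhat, xgt, mask_lines, cfg: CorrectionConfig,
               fe: FeatureExtractor):
    """Composite correction loss with per-term breakdown.

    Returns ``(total, breakdown)`` where breakdown maps term names to
    unweighted float values.
    """
    lr = l1_loss(xhat, xgt)
    ll = lpips_loss(xhat, xgt, fe)
    ld = dc_loss(xhat, xgt, mask_lines)
    total = cfg.lambda_r * lr + cfg.lambda_l * ll + cfg.lambda_d * ld
    as_float = (lambda v: float(v.data) if isinstance(v, Tensor) else float(v))
    breakdown = {"l1": as_float(lr), "lpips": as_float(ll), "dc": as_float(ld)}
    return total, breakdown


class Corrector:
    """Residual Swin U-net restoring a corrupted magnitude image."""

    def __init__(self, config: CorrectionConfig = CorrectionConfig()):
        self.config = config
        rng = np.random.default_rng(config.init_seed)
        self.net = SwinUNet(rng, c_in=1, depth=config.depth,
                            base_width=config.base_width,
                            window=config.window, n_heads=config.n_heads,
                            blocks_per_stage=config.blocks_per_stage)

    def forward(self, batch: np.ndarray) -> Tensor:
        """(N,1,H,W) batch -> corrected batch tensor in [0, 1]."""
        return self.net(Tensor(batch))

    def correct(self, img: ImageSlice | np.ndarray) -> ImageSlice:
        pixels = img.pixels if isinstance(img, ImageSlice) else np.asarray(img)
        spacing = img.pixel_spacing if isinstance(img, ImageSlice) else 1.0
        out = self.forward(pixels[None, None]).data[0, 0]
        if not np.isfinite(out).all():
            raise FloatingPointError("corrector produced non-finite output")
        return ImageSlice(out, pixel_spacing=spacing)
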