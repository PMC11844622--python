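"""Motion detection: a U-net over k-space with line-structured outputs.

The detector sees a two-channel representation of the corrupted spectrum
(log-magnitude and normalised phase) and predicts, per pixel, whether the
underlying k-space line is motion-corrupted.  Because corruption is
line-structured, the raw 2-D prediction is collapsed by a *spatial
averaging module*: each phase-encoding line receives the mean prediction
across the frequency-encoding direction, which suppresses pixel-level
uncertainty in the low-SNR periphery of k-space.  The outermost PE lines
at each edge are additionally excluded from the mask and the losses.

Training minimises Dice + binary cross-entropy between the averaged,
peripherally excluded prediction and the ground-truth line mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kspace import KSpaceSlice
from .motion import LineMask
from .nn.engine import Tensor
from .nn.unet import UNet

PERIPHERAL_FRAC = 0.05   # PE lines zeroed at each k-space edge
BCE_CLIP = 1e-7          # probability clipping before logarithms
DICE_EPS = 1e-6

__all__ = [
    "DetectionConfig", "PredictedMask", "Detector",
    "spatial_average", "peripheral_exclusion_mask",
    "dice_loss", "bce_loss", "seg_loss",
    "PERIPHERAL_FRAC", "BCE_CLIP", "DICE_EPS",
]


@dataclass(frozen=True)
class DetectionConfig:
    depth: int = 2
    base_width: int = 8
    threshold: float = 0.5
    peripheral_frac: float = PERIPHERAL_FRAC
    log_magnitude_only: bool = False
    init_seed: int = 0


@dataclass
class PredictedMask:
    """Raw 2-D prediction, its per-line average, and the binarised mask."""

    raw: np.ndarray           # (H, W) in [0, 1]
    averaged: LineMask        # soft per-line values, periphery zeroed
    binary: LineMask          # averaged > threshold
    threshold: float = 0.5


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def spatial_average(raw):
    """Per-PE-line mean of a 2-D prediction map along the frequency axis.

    Accepts an (H, W) array (returns a soft :class:`LineMask`) or a
    ``Tensor`` with spatial axes last (returns a tensor with the frequency
    axis reduced to length 1, broadcastable back to 2-D).  Applying the
    module twice equals applying it once.
    """
    if isinstance(raw, Tensor):
        return raw.mean(axis=-1, keepdims=True)
    arr = np.asarray(raw, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D map, got shape {arr.shape}")
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError("prediction map must lie in [0, 1]")
    return LineMask(arr.mean(axis=1), binary=False)


def peripheral_exclusion_mask(height: int,
                              frac: float = PERIPHERAL_FRAC) -> np.ndarray:
    """1 on interior PE lines, 0 on the excluded outermost lines."""
    keep = np.ones(height)
    n_edge = int(round(frac * height))
    if n_edge > 0:
        keep[:n_edge] = 0.0
        keep[-n_edge:] = 0.0
    return keep


def dice_loss(mp, mgt, eps: float = DICE_EPS):
    """Soft Dice loss ``1 - (2 <Mp, MGT> + eps) / (sum Mp + sum MGT + eps)``."""
    mp_t, mgt_t = _as_tensor(mp), _as_tensor(mgt)
    if mp_t.shape != mgt_t.shape:
        raise ValueError(f"shape mismatch: {mp_t.shape} vs {mgt_t.shape}")
    num = (mp_t * mgt_t).sum() * 2.0 + eps
    den = mp_t.sum() + mgt_t.sum() + eps
    out = 1.0 - num / den
    return out if isinstance(mp, Tensor) else float(out.data)


def bce_loss(mp, mgt, clip: float = BCE_CLIP):
    """Binary cross-entropy, mean over elements, probabilities clipped.

    The mean (rather than summed) reduction keeps the Dice/BCE balance
    independent of mask size.
    """
    mp_t, mgt_t = _as_tensor(mp), _as_tensor(mgt)
    if mp_t.shape != mgt_t.shape:
        raise ValueError(f"shape mismatch: {mp_t.shape} vs {mgt_t.shape}")
    p = mp_t.clamp(clip, 1.0 - clip)
    out = -(mgt_t * p.log() + (1.0 - mgt_t) * (1.0 - p).log()).mean()
    return out if isinstance(mp, Tensor) else float(out.data)


def seg_loss(mp, mgt):
    """Combined segmentation loss: Dice + BCE."""
    d = dice_loss(mp, mgt)
    b = bce_loss(mp, mgt)
    return d + b


def kspace_channels(ks: KSpaceSlice | np.ndarray,
                    log_magnitude_only: bool = False) -> np.ndarray:
    """Detector input channels from a corrupted spectrum.

    Channel 0: per-sample standardised ``log(1 + |k|)``; channel 1 (unless
    disabled): phase divided by pi.  Shape (C, H, W).
    """
    coeffs = ks.coeffs if isinstance(ks, KSpaceSlice) else np.asarray(ks)
    logmag = np.log1p(np.abs(coeffs))
    std = logmag.std()
    logmag = (logmag - logmag.mean()) / (std if std > 0 else 1.0)
    if log_magnitude_only:
        return logmag[None]
    phase = np.angle(coeffs) / np.pi
    return np.stack([logmag, phase])


class Detector:
    """U-net motion detector with sigmoid head and spatial averaging."""

    def __init__(self, config: DetectionConfig = DetectionConfig()):
        self.config = config
        rng = np.random.default_rng(config.init_seed)
        c_in = 1 if config.log_magnitude_only else 2
        self.net = UNet(c_in, 1, config.depth, config.base_width, rng)

    # ---------------------------------------------------------------- train
    def forward_soft(self, batch: np.ndarray) -> Tensor:
        """Averaged, peripherally excluded soft mask for an (N,C,H,W) batch.

        Returns a tensor of shape (N, 1, H, 1); constant along the
        frequency axis by construction.
        """
        x = Tensor(batch)
        raw = self.net(x).sigmoid()
        avg = spatial_average(raw)                     # (N,1,H,1)
        keep = peripheral_exclusion_mask(batch.shape[-2],
                                         self.config.peripheral_frac)
        return avg * Tensor(keep[None, None, :, None])

    # ------------------------------------------------------------- inference
    def detect(self, ks: KSpaceSlice | np.ndarray) -> PredictedMask:
        """Predict the corruption mask of one corrupted spectrum."""
        channels = kspace_channels(ks, self.config.log_magnitude_only)
        h, w = channels.shape[-2:]
        self.net.check_shape(h, w)
        raw = self.net(Tensor(channels[None])).sigmoid().data[0, 0]
        avg = raw.mean(axis=1)
        keep = peripheral_exclusion_mask(h, self.config.peripheral_frac)
        avg = avg * keep
        binary = (avg > self.config.threshold).astype(np.float64)
        return PredictedMask(raw=raw,
                             averaged=LineMask(avg, binary=False),
                             binary=LineMask(binary, binary=True),
                             threshold=self.config.threshold)

    def loss(self, batch: np.ndarray, mgt: np.ndarray) -> Tensor:
        """Seg loss on the averaged mask vs (N, H) ground-truth lines.

        Peripheral lines are excluded from both prediction and target.
        """
        pred = self.forward_soft(batch)                # (N,1,H,1)
        keep = peripheral_exclusion_mask(batch.shape[-2],
                                         self.config.peripheral_frac)
        target = Tensor((mgt * keep[None, :])[:, None, :, None])
        return dice_loss(pred, target) + bce_loss(pred, target)
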