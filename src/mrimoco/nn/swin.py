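"""Windowed self-attention (Swin-style) blocks and the restoration net.

The correction network is a U-net whose attention stages are Swin
Transformer blocks: multi-head self-attention inside non-overlapping
windows, alternating between plain and cyclically shifted window grids so
information propagates across window boundaries, each followed by a
two-layer MLP with pre-norm residual connections.  At the scale this
package trains (windows covering a large fraction of the feature map) the
cyclic shift is applied without the cross-boundary attention mask of the
full-scale architecture.

The restoration net is residual: it predicts a correction added to its
input, with the final projection zero-initialised so the untrained network
is the identity.
"""

from __future__ import annotations

import numpy as np

from .engine import Tensor
from .layers import Conv2d, LayerNorm, Linear, Module, concat, upsample2x
from .unet import ConvBlock

__all__ = ["WindowAttention", "SwinBlock", "SwinUNet"]


class WindowAttention(Module):
    """Multi-head self-attention over (B, T, C) token windows."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator):
        if dim % n_heads:
            raise ValueError(f"dim {dim} not divisible by n_heads {n_heads}")
        self.n_heads = n_heads
        self.d_head = dim // n_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        b, t, c = x.shape
        h, d = self.n_heads, self.d_head
        qkv = self.qkv(x).reshape(b, t, 3, h, d).transpose((2, 0, 3, 1, 4))
        q, k, v = qkv[0], qkv[1], qkv[2]          # each (b, h, t, d)
        attn = (q @ k.transpose((0, 1, 3, 2))) * (d ** -0.5)
        attn = attn.softmax(axis=-1)
        out = (attn @ v).transpose((0, 2, 1, 3)).reshape(b, t, c)
        return self.proj(out)


class SwinBlock(Module):
    """Pre-norm windowed MSA + MLP on an NCHW feature map."""

    def __init__(self, dim: int, window: int, n_heads: int,
                 rng: np.random.Generator, shift: bool = False,
                 mlp_ratio: float = 2.0):
        self.window = window
        self.shift = window // 2 if shift else 0
        self.norm1 = LayerNorm(dim)
        self.attn = WindowAttention(dim, n_heads, rng)
        self.norm2 = LayerNorm(dim)
        hidden = int(dim * mlp_ratio)
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        n, c, hh, ww = x.shape
        w = self.window
        if hh % w or ww % w:
            raise ValueError(f"feature map {hh}x{ww} not divisible by window {w}")
        t = x
        if self.shift:
            t = t.roll((-self.shift, -self.shift), axis=(2, 3))
        # NCHW -> (n*windows, w*w, c) tokens
        t = (t.reshape(n, c, hh // w, w, ww // w, w)
              .transpose((0, 2, 4, 3, 5, 1))
              .reshape(n * (hh // w) * (ww // w), w * w, c))
        t = t + self.attn(self.norm1(t))
        t = t + self.fc2(self.fc1(self.norm2(t)).leaky_relu())
        t = (t.reshape(n, hh // w, ww // w, w, w, c)
              .transpose((0, 5, 1, 3, 2, 4))
              .reshape(n, c, hh, ww))
        if self.shift:
            t = t.roll((self.shift, self.shift), axis=(2, 3))
        return t


class SwinUNet(Module):
    """Residual restoration U-net with Swin blocks in place of attention.

    Convolutional encoder/decoder with stride-2 downsampling and skip
    connections; pairs of (plain, shifted) Swin blocks refine the
    bottleneck and each decoder stage.  Output = input + correction,
    clamped to [0, 1]; the correction head is zero-initialised.
    """

    def __init__(self, rng: np.random.Generator, c_in: int = 1,
                 depth: int = 2, base_width: int = 16, window: int = 8,
                 n_heads: int = 2, blocks_per_stage: int = 2):
        self.depth = depth
        widths = [base_width * 2 ** i for i in range(depth + 1)]
        self.enc = [ConvBlock(c_in if i == 0 else widths[i - 1], widths[i], rng)
                    for i in range(depth)]
        self.down = [Conv2d(widths[i], widths[i], 3, rng, stride=2)
                     for i in range(depth)]
        self.bottleneck = ConvBlock(widths[depth - 1] if depth else c_in,
                                    widths[depth], rng)
        self.bot_swin = [SwinBlock(widths[depth], window, n_heads, rng,
                                   shift=bool(j % 2))
                         for j in range(blocks_per_stage)]
        self.upconv = [Conv2d(widths[i + 1], widths[i], 3, rng)
                       for i in range(depth)]
        self.dec = [ConvBlock(widths[i] * 2, widths[i], rng)
                    for i in range(depth)]
        self.dec_swin = [[SwinBlock(widths[i], window, n_heads, rng,
                                    shift=bool(j % 2))
                          for j in range(blocks_per_stage)]
                         for i in range(depth)]
        self.head = Conv2d(widths[0], c_in, 1, rng, zero_init=True)
        self.window = window

    def check_shape(self, h: int, w: int) -> None:
        f = 2 ** self.depth
        coarse = self.window * f
        if h % coarse or w % coarse:
            raise ValueError(
                f"input {h}x{w} must be divisible by window*2^depth={coarse}; "
                f"pad to {int(np.ceil(h / coarse)) * coarse}"
                f"x{int(np.ceil(w / coarse)) * coarse}")

    def forward(self, x: Tensor) -> Tensor:
        self.check_shape(x.shape[-2], x.shape[-1])
        inp = x
        skips = []
        for enc, down in zip(self.enc, self.down):
            x = enc(x)
            skips.append(x)
            x = down(x).leaky_relu()
        x = self.bottleneck(x)
        for blk in self.bot_swin:
            x = blk(x)
        for i in reversed(range(self.depth)):
            x = self.upconv[i](upsample2x(x)).leaky_relu()
            x = self.dec[i](concat([skips[i], x], axis=1))
            for blk in self.dec_swin[i]:
                x = blk(x)
        return (inp + self.head(x)).clamp(0.0, 1.0)
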