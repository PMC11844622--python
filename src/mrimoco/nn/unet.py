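"""A compact U-net over the autodiff engine.

Encoder/decoder with stride-2 convolution downsampling, nearest-neighbour
upsampling and skip connections.  Sized for CPU-scale experiments; depth
and base width are the two knobs that matter.
"""

from __future__ import annotations

import numpy as np

from .layers import Conv2d, Module, concat, upsample2x

__all__ = ["ConvBlock", "UNet"]


class ConvBlock(Module):
    """Two 3x3 convolutions with leaky-ReLU activations."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.c1 = Conv2d(c_in, c_out, 3, rng)
        self.c2 = Conv2d(c_out, c_out, 3, rng)

    def forward(self, x):
        return self.c2(self.c1(x).leaky_relu()).leaky_relu()


class UNet(Module):
    """U-net returning raw (pre-activation) maps with ``c_out`` channels.

    Input height and width must be divisible by ``2**depth``.
    """

    def __init__(self, c_in: int, c_out: int, depth: int, base_width: int,
                 rng: np.random.Generator):
        self.depth = depth
        widths = [base_width * 2 ** i for i in range(depth + 1)]
        self.enc = [ConvBlock(c_in if i == 0 else widths[i - 1], widths[i], rng)
                    for i in range(depth)]
        self.down = [Conv2d(widths[i], widths[i], 3, rng, stride=2)
                     for i in range(depth)]
        self.bottleneck = ConvBlock(widths[depth - 1] if depth else c_in,
                                    widths[depth], rng)
        self.upconv = [Conv2d(widths[i + 1], widths[i], 3, rng)
                       for i in range(depth)]
        self.dec = [ConvBlock(widths[i] * 2, widths[i], rng)
                    for i in range(depth)]
        self.head = Conv2d(widths[0] if depth else widths[depth], c_out, 1, rng)

    def check_shape(self, h: int, w: int) -> None:
        f = 2 ** self.depth
        if h % f or w % f:
            raise ValueError(
                f"input {h}x{w} not divisible by 2^depth={f}; "
                f"pad to {int(np.ceil(h / f)) * f}x{int(np.ceil(w / f)) * f}")

    def forward(self, x):
        self.check_shape(x.shape[-2], x.shape[-1])
        skips = []
        for enc, down in zip(self.enc, self.down):
            x = enc(x)
            skips.append(x)
            x = down(x).leaky_relu()
        x = self.bottleneck(x)
        for i in reversed(range(self.depth)):
            x = self.upconv[i](upsample2x(x)).leaky_relu()
            x = self.dec[i](concat([skips[i], x], axis=1))
        return self.head(x)
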