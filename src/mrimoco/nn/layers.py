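"""Layers, parameter containers and the Adam optimizer.

Everything is built on :mod:`mrimoco.nn.engine`.  Modules own named
parameters; ``state_dict``/``load_state_dict`` round-trip through plain
dicts of arrays so checkpoints serialize to NPZ without any framework.
"""

from __future__ import annotations

import numpy as np

from .engine import Tensor, concat, conv2d

__all__ = [
    "Module", "Conv2d", "Linear", "LayerNorm", "Adam",
    "upsample2x", "concat",
]


class Module:
    """Base class: children discovered by attribute scan, like the big frameworks."""

    def parameters(self) -> list[Tensor]:
        return list(self.named_parameters().values())

    def _children(self, value, key: str):
        if isinstance(value, Tensor) and value.requires_grad:
            yield key, value
        elif isinstance(value, Module):
            for k, p in value.named_parameters(f"{key}.").items():
                yield k, p
        elif isinstance(value, (list, tuple)):
            for i, item in enumerate(value):
                yield from self._children(item, f"{key}.{i}")

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, v in self.__dict__.items():
            for k, p in self._children(v, f"{prefix}{name}"):
                out[k] = p
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None, zero_init: bool = False):
        fan_in = c_in * k * k
        scale = 0.0 if zero_init else np.sqrt(2.0 / fan_in)
        self.w = Tensor(rng.standard_normal((c_out, c_in, k, k)) * scale,
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = stride
        self.padding = k // 2 if padding is None else padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, padding=self.padding)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = Tensor(rng.standard_normal((d_in, d_out)) * np.sqrt(1.0 / d_in),
                        requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class LayerNorm(Module):
    """Normalises the last axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.g = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.g + self.beta


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling of an NCHW tensor."""
    n, c, h, w = x.shape
    y = x.reshape(n, c, h, 1, w, 1)
    y = y * Tensor(np.ones((1, 1, 1, 2, 1, 2)))
    return y.reshape(n, c, 2 * h, 2 * w)


class Adam:
    """Adam with the usual bias correction; betas default to (0.9, 0.999)."""

    def __init__(self, params: list[Tensor], lr: float = 2e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
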