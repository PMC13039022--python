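"""Layers and the Adam optimizer on top of :mod:`hepaseg.autograd`.

Parameter creation order is deterministic for a given module graph, so two
networks built from the same seeded ``numpy.random.Generator`` and the same
layer sequence receive bit-identical initial weights.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class; collects parameters from attributes recursively."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in vars(self).values():
            for p in _collect(value):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {str(i): p.data for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"checkpoint has {len(state)} arrays, model has {len(params)}"
            )
        for i, p in enumerate(params):
            arr = np.asarray(state[str(i)], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i}: shape {arr.shape} != {p.data.shape}")
            p.data = arr.copy()


def _collect(value):
    if isinstance(value, Tensor):
        if value.requires_grad:
            yield value
    elif isinstance(value, Module):
        yield from value.parameters()
    elif isinstance(value, (list, tuple)):
        for v in value:
            yield from _collect(v)


def he_init(rng: np.random.Generator, shape, fan_in: int, gain: float = 2.0):
    std = float(np.sqrt(gain / fan_in))
    return Tensor(rng.normal(0.0, std, size=shape).astype(np.float32),
                  requires_grad=True)


class Conv3d(Module):
    """Same-padded stride-1 3D convolution."""

    def __init__(self, rng, in_ch: int, out_ch: int, kernel: int = 3,
                 dilation: int = 1, weight_scale: float | None = None):
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.dilation = dilation
        fan_in = in_ch * kernel ** 3
        self.weight = he_init(rng, (out_ch, in_ch, kernel, kernel, kernel), fan_in)
        if weight_scale is not None:
            self.weight.data *= np.float32(weight_scale / np.sqrt(2.0 / fan_in))
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} channels, got {x.shape[1]}")
        return ag.conv3d(x, self.weight, self.bias, dilation=self.dilation)


class ConvTranspose3d(Module):
    """Up-convolution with kernel == stride (non-overlapping taps)."""

    def __init__(self, rng, in_ch: int, out_ch: int, factors=(2, 2, 2)):
        self.in_ch = in_ch
        self.factors = tuple(int(f) for f in factors)
        fan_in = in_ch
        self.weight = he_init(rng, (in_ch, out_ch) + self.factors, fan_in)
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv_transpose3d(x, self.weight, self.bias, factors=self.factors)


class InstanceNorm3d(Module):
    """Per-(batch, channel) normalization over spatial dims; affine."""

    eps = 1e-5

    def __init__(self, channels: int):
        self.gamma = Tensor(np.ones((1, channels, 1, 1, 1), dtype=np.float32),
                            requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1, 1), dtype=np.float32),
                           requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ag.instance_norm(x, self.gamma, self.beta, self.eps)


class Linear(Module):
    def __init__(self, rng, in_dim: int, out_dim: int, scale: float | None = None):
        std = scale if scale is not None else float(1.0 / np.sqrt(in_dim))
        self.weight = Tensor(
            rng.normal(0.0, std, size=(out_dim, in_dim)).astype(np.float32),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        # x: (L, in_dim) -> (L, out_dim)
        return x @ self.weight.T + self.bias


class Adam:
    """Adam with decoupled-style L2 (weight decay added to the gradient)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 1e-5):
        self.params = list(params)
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mh = self.m[i] / bc1
            vh = self.v[i] / bc2
            p.data = (p.data - self.lr * mh / (np.sqrt(vh) + self.eps)).astype(
                np.float32)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
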