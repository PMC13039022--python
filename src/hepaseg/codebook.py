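"""Vector-quantization bottleneck: nearest-prototype assignment with a
straight-through estimator and a two-term quantization loss.

Sites are the flattened (batch, depth, height, width) positions of a
rank-5 feature map; channels form the vector axis.  Ties in the nearest-
prototype assignment break toward the lowest index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .nn import Module


def pairwise_sq_dist(z_flat: np.ndarray, codebook: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances ‖z_n‖² + ‖e_k‖² − 2 z_nᵀe_k, shape (N, K).

    Tiny negative values from cancellation are clamped to 0.
    """
    z_flat = np.asarray(z_flat)
    codebook = np.asarray(codebook)
    if z_flat.ndim != 2 or codebook.ndim != 2 or z_flat.shape[1] != codebook.shape[1]:
        raise ValueError(
            f"dimension mismatch: Z {z_flat.shape} vs codebook {codebook.shape}")
    d = ((z_flat ** 2).sum(axis=1, keepdims=True)
         + (codebook ** 2).sum(axis=1)[None, :]
         - 2.0 * z_flat @ codebook.T)
    return np.maximum(d, 0.0)


def assign_codes(dist: np.ndarray) -> np.ndarray:
    """Per-site argmin over prototypes; numpy argmin already returns the
    first (lowest) index on ties."""
    return np.argmin(dist, axis=1)


@dataclass
class QuantizationResult:
    z_q: Tensor            # quantized features, same shape as the input
    indices: np.ndarray    # (N,) assigned prototype indices
    z_flat: Tensor         # (N, C) flattened encoder features (graph node)
    z_q_flat: Tensor       # (N, C) quantized flat features (graph node)


class VQCodebook(Module):
    """K learnable C-dimensional prototypes.

    ``init='data'`` (default) re-seeds the prototypes from the first feature
    map that reaches :meth:`quantize`: prototypes start uniform(−1/K, 1/K)
    and are replaced by K sites sampled from the features plus a small
    jitter.  With pure uniform init (``init='uniform'``) the gradient-only
    codebook update reliably collapses onto a single prototype within a
    few dozen steps, because only the winning code ever receives gradient.
    """

    def __init__(self, rng: np.random.Generator, num_codes: int = 64,
                 dim: int = 64, init: str = "data"):
        if num_codes < 1 or dim < 1:
            raise ValueError("num_codes and dim must be >= 1")
        if init not in ("data", "uniform"):
            raise ValueError(f"unknown codebook init {init!r}")
        self.num_codes = num_codes
        self.dim = dim
        self.init = init
        self._needs_data_init = init == "data"
        self._init_rng = np.random.default_rng(rng.integers(2 ** 63))
        self.embed = Tensor(
            rng.uniform(-1.0 / num_codes, 1.0 / num_codes,
                        size=(num_codes, dim)).astype(np.float32),
            requires_grad=True)

    def _data_init(self, z_flat: np.ndarray) -> None:
        rng = self._init_rng
        n = z_flat.shape[0]
        idx = rng.choice(n, size=self.num_codes, replace=n < self.num_codes)
        jitter = rng.normal(0.0, 1e-3, size=(self.num_codes, self.dim))
        self.embed.data = (z_flat[idx] + jitter).astype(np.float32)
        self._needs_data_init = False

    # -- flatten helpers -------------------------------------------------
    @staticmethod
    def flatten_sites(z: Tensor) -> Tensor:
        """(B, C, D, H, W) -> (N, C), N = B·D·H·W row-major over (b,z,y,x)."""
        b, c, d, h, w = z.shape
        return z.transpose((0, 2, 3, 4, 1)).reshape(b * d * h * w, c)

    @staticmethod
    def unflatten_sites(z_flat: Tensor, shape) -> Tensor:
        b, c, d, h, w = shape
        return z_flat.reshape((b, d, h, w, c)).transpose((0, 4, 1, 2, 3))

    # -- quantization ----------------------------------------------------
    def quantize(self, z: Tensor) -> QuantizationResult:
        if z.shape[1] != self.dim:
            raise ValueError(
                f"expected {self.dim} channels, got {z.shape[1]}")
        z_flat = self.flatten_sites(z)
        if self._needs_data_init:
            self._data_init(z_flat.data)
        dist = pairwise_sq_dist(z_flat.data, self.embed.data)
        indices = assign_codes(dist)
        z_q_flat = _gather_rows(self.embed, indices)
        z_q = self.unflatten_sites(z_q_flat, z.shape)
        return QuantizationResult(z_q=z_q, indices=indices,
                                  z_flat=z_flat, z_q_flat=z_q_flat)


def _gather_rows(embed: Tensor, indices: np.ndarray) -> Tensor:
    """Differentiable row gather: rows of the codebook selected per site."""
    out = Tensor(embed.data[indices])

    def backward(g):
        acc = np.zeros_like(embed.data)
        np.add.at(acc, indices, g)
        embed._accum(acc)

    if embed.requires_grad:
        out._parents = (embed,)
        out._backward = backward
        out.requires_grad = True
    return out


def straight_through(z: Tensor, z_q: Tensor) -> Tensor:
    """Z̃ = Z + stop-grad(Ẑ − Z): forward value exactly Ẑ, gradients flow
    to Z unchanged (implemented as a primitive so the value is bitwise Ẑ,
    which z + (Ẑ − Z) would not give in float32)."""
    if z.shape != z_q.shape:
        raise ValueError("shape mismatch in straight-through estimator")
    out = Tensor(z_q.data)

    def backward(g):
        z._accum(g)

    if z.requires_grad or z._parents:
        out._parents = (z,)
        out._backward = backward
        out.requires_grad = z.requires_grad
    return out


def vq_loss(z: Tensor, z_q: Tensor, lam: float = 0.25) -> Tensor:
    """Commitment term (encoder side, Ẑ detached) + λ · codebook-update term
    (codebook side, Z detached); value (1+λ)·mean‖Ẑ−Z‖²."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    commit = ((z_q.detach() - z) ** 2).mean()
    update = ((z_q - z.detach()) ** 2).mean()
    return commit + lam * update


def codebook_perplexity(indices: np.ndarray, num_codes: int) -> float:
    """exp(entropy) of the empirical code-usage distribution, in [1, K]."""
    indices = np.asarray(indices)
    if indices.size == 0:
        raise ValueError("empty index list")
    counts = np.bincount(indices, minlength=num_codes).astype(np.float64)
    p = counts / counts.sum()
    nz = p[p > 0]
    return float(np.exp(-(nz * np.log(nz)).sum()))
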