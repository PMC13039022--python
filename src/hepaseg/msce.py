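"""Three-branch multi-scale context block used at every encoder level.

Branch 1: 1×1×1 reduce → 3×3×3 conv              (receptive field 3)
Branch 2: 1×1×1 reduce → 3×3×3 conv, dilation 2  (receptive field 5)
Branch 3: global average pool → 1×1×1 conv → broadcast (global)

Branch outputs are concatenated on the channel axis and fused by a 1×1×1
convolution.  Every convolution is followed by instance norm + ReLU;
``linear_mode=True`` disables both so the block is exactly linear, which
the impulse-response tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .nn import Conv3d, InstanceNorm3d, Module


@dataclass(frozen=True)
class MSCEConfig:
    in_channels: int
    out_channels: int
    dilation: int = 2
    branch_channels: int | None = None  # default: out_channels // 2 (min 4)

    def resolved_branch_channels(self) -> int:
        if self.branch_channels is not None:
            return self.branch_channels
        return max(4, self.out_channels // 2)


class MSCEBlock(Module):
    def __init__(self, rng: np.random.Generator, cfg: MSCEConfig):
        self.cfg = cfg
        bc = cfg.resolved_branch_channels()
        self.reduce1 = Conv3d(rng, cfg.in_channels, bc, kernel=1)
        self.conv1 = Conv3d(rng, bc, bc, kernel=3)
        self.reduce2 = Conv3d(rng, cfg.in_channels, bc, kernel=1)
        self.conv2 = Conv3d(rng, bc, bc, kernel=3, dilation=cfg.dilation)
        self.pool_proj = Conv3d(rng, cfg.in_channels, bc, kernel=1)
        self.fuse = Conv3d(rng, 3 * bc, cfg.out_channels, kernel=1)
        self.norms = [InstanceNorm3d(bc) for _ in range(4)]
        self.fuse_norm = InstanceNorm3d(cfg.out_channels)
        self.linear_mode = False

    def _act(self, x: Tensor, norm: InstanceNorm3d) -> Tensor:
        if self.linear_mode:
            return x
        return ag.relu(norm(x))

    def branches(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} channels, got {x.shape[1]}")
        b1 = self._act(self.conv1(self._act(self.reduce1(x), self.norms[0])),
                       self.norms[1])
        b2 = self._act(self.conv2(self._act(self.reduce2(x), self.norms[2])),
                       self.norms[3])
        # no instance norm on the pooled branch: it is spatially constant,
        # and normalizing a constant map would zero it out
        pooled = x.mean(axis=(2, 3, 4), keepdims=True)
        b3 = self.pool_proj(pooled)
        if not self.linear_mode:
            b3 = ag.relu(b3)
        b3 = ag.broadcast_spatial(b3, x.shape[2:])
        return b1, b2, b3

    def __call__(self, x: Tensor) -> Tensor:
        b1, b2, b3 = self.branches(x)
        fused = self.fuse(ag.concat([b1, b2, b3], axis=1))
        return self._act(fused, self.fuse_norm)


def msce_forward(x: Tensor, block: MSCEBlock) -> Tensor:
    return block(x)
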