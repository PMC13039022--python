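"""Full segmentation network: multi-scale context encoder levels with
average-pool downsampling, a vector-quantized + state-space bottleneck,
and a transposed-convolution decoder with aligned skip connections.

Two sigmoid heads are produced: ``liver`` covers the whole organ region
(labels 1 ∪ 2, including tumor tissue) and ``tumor`` covers label 2 only,
so the containment penalty T(x) ≤ L(x) is anatomically meaningful.

Disabling the codebook and/or the state-space module via ``NetConfig``
turns the model into a plain U-Net built from the same blocks; parameter
initialization order is arranged so that the reduced model is bit-identical
to :class:`ReferenceUNet3D` constructed from the same seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .codebook import VQCodebook, codebook_perplexity, straight_through
from .msce import MSCEBlock, MSCEConfig
from .nn import Conv3d, ConvTranspose3d, InstanceNorm3d, Module
from .ssm import SSMParams, global_repr_forward


@dataclass(frozen=True)
class NetConfig:
    levels: int = 4
    channels_per_level: tuple[int, ...] = (16, 32, 48, 64)
    pool_factors: tuple[tuple[int, int, int], ...] = (
        (2, 2, 2), (2, 2, 2), (2, 2, 2), (1, 2, 2))
    dilation: int = 2
    branch_channels: int | None = None
    codebook_k: int = 64
    codebook_init: str = "data"
    ssm_state_size: int = 16
    ssm_bidirectional: bool = False
    use_codebook: bool = True
    use_ssm: bool = True
    lambda_vq: float = 0.25
    head_init_scale: float = 1.0

    def validate(self) -> None:
        if len(self.channels_per_level) != self.levels:
            raise ValueError("channels_per_level length must equal levels")
        if len(self.pool_factors) != self.levels:
            raise ValueError("pool_factors length must equal levels")
        if any(f < 1 for fac in self.pool_factors for f in fac):
            raise ValueError("pool factors must be positive integers")

    @property
    def bottleneck_dim(self) -> int:
        return self.channels_per_level[-1]

    def cumulative_factors(self) -> tuple[int, int, int]:
        cum = [1, 1, 1]
        for fac in self.pool_factors:
            for i in range(3):
                cum[i] *= fac[i]
        return tuple(cum)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "NetConfig":
        d = json.loads(s)
        d["channels_per_level"] = tuple(d["channels_per_level"])
        d["pool_factors"] = tuple(tuple(f) for f in d["pool_factors"])
        return cls(**d)


def align_skip(enc_feat: Tensor, dec_feat: Tensor) -> tuple[Tensor, Tensor]:
    """Bring the encoder feature to the decoder's spatial dims: centered
    crop when larger, symmetric zero-pad when smaller; any odd remainder
    goes to the trailing side."""
    target = dec_feat.shape[2:]
    source = enc_feat.shape[2:]
    crops, pads = [], []
    for s, t in zip(source, target):
        if s > t:
            lo = (s - t) // 2
            crops.append((lo, s - t - lo))
            pads.append((0, 0))
        elif s < t:
            lo = (t - s) // 2
            pads.append((lo, t - s - lo))
            crops.append((0, 0))
        else:
            crops.append((0, 0))
            pads.append((0, 0))
    out = enc_feat
    if any(c != (0, 0) for c in crops):
        out = ag.crop_spatial(out, crops)
    if any(p != (0, 0) for p in pads):
        out = ag.pad_spatial(out, pads)
    return out, dec_feat


class _DecoderLevel(Module):
    def __init__(self, rng, in_ch: int, out_ch: int, factors):
        self.up = ConvTranspose3d(rng, in_ch, out_ch, factors=factors)
        self.reduce = Conv3d(rng, 2 * out_ch, out_ch, kernel=1)
        self.conv = Conv3d(rng, out_ch, out_ch, kernel=3)
        self.norm1 = InstanceNorm3d(out_ch)
        self.norm2 = InstanceNorm3d(out_ch)

    def __call__(self, x: Tensor, skip: Tensor) -> Tensor:
        x = self.up(x)
        skip, x = align_skip(skip, x)
        x = ag.relu(self.norm1(self.reduce(ag.concat([skip, x], axis=1))))
        return ag.relu(self.norm2(self.conv(x)))


class _Backbone(Module):
    """Encoder levels, decoder levels and heads shared by the full network
    and the plain-U-Net reference; construction order fixes the RNG stream."""

    def __init__(self, rng: np.random.Generator, cfg: NetConfig):
        cfg.validate()
        self.cfg = cfg
        ch = cfg.channels_per_level
        self.encoders = []
        in_ch = 1
        for lvl in range(cfg.levels):
            mcfg = MSCEConfig(in_ch, ch[lvl], dilation=cfg.dilation,
                              branch_channels=cfg.branch_channels)
            self.encoders.append(MSCEBlock(rng, mcfg))
            in_ch = ch[lvl]
        self.decoders = []
        cur = ch[-1]
        for lvl in range(cfg.levels - 1, -1, -1):
            self.decoders.append(
                _DecoderLevel(rng, cur, ch[lvl], cfg.pool_factors[lvl]))
            cur = ch[lvl]
        self.liver_head = Conv3d(rng, ch[0], 1, kernel=1,
                                 weight_scale=cfg.head_init_scale)
        self.tumor_head = Conv3d(rng, ch[0], 1, kernel=1,
                                 weight_scale=cfg.head_init_scale)

    # -- shared plumbing -------------------------------------------------
    def pad_input(self, x: Tensor) -> tuple[Tensor, tuple]:
        cum = self.cfg.cumulative_factors()
        spatial = x.shape[2:]
        pads = []
        for s, c in zip(spatial, cum):
            rem = (-s) % c
            pads.append((rem // 2, rem - rem // 2))
        if any(p != (0, 0) for p in pads):
            x = ag.pad_spatial(x, pads)
        return x, tuple(pads)

    def encode(self, x: Tensor) -> tuple[Tensor, list[Tensor]]:
        skips = []
        for lvl, enc in enumerate(self.encoders):
            x = enc(x)
            skips.append(x)
            x = ag.avg_pool3d(x, self.cfg.pool_factors[lvl])
        return x, skips

    def decode(self, x: Tensor, skips: list[Tensor]) -> Tensor:
        for dec, skip in zip(self.decoders, reversed(skips)):
            x = dec(x, skip)
        return x

    def heads(self, x: Tensor, pads) -> tuple[Tensor, Tensor]:
        liver = ag.sigmoid(self.liver_head(x))
        tumor = ag.sigmoid(self.tumor_head(x))
        if any(p != (0, 0) for p in pads):
            liver = ag.crop_spatial(liver, pads)
            tumor = ag.crop_spatial(tumor, pads)
        return liver, tumor


class SegNet3D(Module):
    """Encoder → (codebook →) (state-space →) decoder → two sigmoid heads."""

    def __init__(self, cfg: NetConfig, seed: int = 0):
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        ch = cfg.channels_per_level
        # encoder first, then the optional bottleneck modules, then the
        # decoder: skipping the bottleneck leaves the encoder/decoder RNG
        # stream identical to ReferenceUNet3D's
        self.backbone = _Backbone(rng, cfg)
        self.vq = (VQCodebook(rng, cfg.codebook_k, ch[-1],
                              init=cfg.codebook_init)
                   if cfg.use_codebook else None)
        self.ssm = (SSMParams(rng, cfg.ssm_state_size, ch[-1],
                              bidirectional=cfg.ssm_bidirectional)
                    if cfg.use_ssm else None)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor, dict]:
        if x.ndim != 5 or x.shape[1] != 1:
            raise ValueError(
                f"expected (B, 1, D, H, W) input, got shape {tuple(x.shape)}")
        bb = self.backbone
        x, pads = bb.pad_input(x)
        z, skips = bb.encode(x)

        vq_aux: dict = {"z": None, "z_q": None, "indices": None,
                        "perplexity": None}
        if self.vq is not None:
            qr = self.vq.quantize(z)
            vq_aux.update(z=qr.z_flat, z_q=qr.z_q_flat, indices=qr.indices,
                          perplexity=codebook_perplexity(
                              qr.indices, self.vq.num_codes))
            z = straight_through(z, qr.z_q)
        if self.ssm is not None:
            z = global_repr_forward(z, self.ssm)

        out = bb.decode(z, skips)
        liver, tumor = bb.heads(out, pads)
        return liver, tumor, vq_aux

    __call__ = forward


class ReferenceUNet3D(Module):
    """Independently composed plain U-Net over the same backbone layers;
    used to check that disabling codebook + SSM is a pure config switch."""

    def __init__(self, cfg: NetConfig, seed: int = 0):
        cfg = dataclasses.replace(cfg, use_codebook=False, use_ssm=False)
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.backbone = _Backbone(rng, cfg)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        bb = self.backbone
        x, pads = bb.pad_input(x)
        skips = []
        for lvl in range(self.cfg.levels):
            x = bb.encoders[lvl](x)
            skips.append(x)
            x = ag.avg_pool3d(x, self.cfg.pool_factors[lvl])
        for i, lvl in enumerate(range(self.cfg.levels - 1, -1, -1)):
            x = bb.decoders[i](x, skips[lvl])
        return bb.heads(x, pads)

    __call__ = forward


def save_checkpoint(net: SegNet3D, path, extra: dict | None = None) -> None:
    arrays = net.state_dict()
    arrays["__config__"] = np.frombuffer(
        net.cfg.to_json().encode(), dtype=np.uint8)
    if extra:
        arrays["__extra__"] = np.frombuffer(
            json.dumps(extra).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[SegNet3D, dict]:
    with np.load(path) as zf:
        cfg = NetConfig.from_json(bytes(zf["__config__"]).decode())
        extra = (json.loads(bytes(zf["__extra__"]).decode())
                 if "__extra__" in zf else {})
        net = SegNet3D(cfg, seed=0)
        state = {k: zf[k] for k in zf.files if not k.startswith("__")}
    net.load_state_dict(state)
    if net.vq is not None:
        net.vq._needs_data_init = False  # prototypes come from the checkpoint
    return net, extra
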