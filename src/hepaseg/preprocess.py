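"""CT preprocessing chain: HU clipping, anisotropy-aware resampling,
liver-slab sampling along z, and min-max normalization.

The chain is applied in that literal order.  Resampling uses cubic spline
interpolation for images and nearest-neighbor for masks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import LabelMask, Volume3D


class NoLiverError(ValueError):
    """Raised when a mask contains no liver/tumor voxels."""


@dataclass(frozen=True)
class PreprocessConfig:
    hu_lo: float = -200.0
    hu_hi: float = 200.0
    in_plane_factor: float = 0.5
    target_z_spacing_mm: float = 1.0
    slab_slices: int = 48
    seed: int = 0

    def validate(self) -> None:
        if not self.hu_lo < self.hu_hi:
            raise ValueError("hu_lo must be < hu_hi")
        if not 0.0 < self.in_plane_factor <= 1.0:
            raise ValueError("in_plane_factor must be in (0, 1]")
        if self.target_z_spacing_mm <= 0:
            raise ValueError("target_z_spacing_mm must be positive")
        if self.slab_slices < 1:
            raise ValueError("slab_slices must be >= 1")


def clip_hu(vol: Volume3D, lo: float, hi: float) -> Volume3D:
    if not lo < hi:
        raise ValueError("lo must be < hi")
    return Volume3D(np.clip(vol.data, lo, hi), vol.spacing, vol.affine.copy(),
                    dict(vol.meta))


def resample(vol: Volume3D, mask: LabelMask,
             cfg: PreprocessConfig) -> tuple[Volume3D, LabelMask]:
    """Scale the in-plane grid by ``in_plane_factor`` and bring z spacing to
    ``target_z_spacing_mm``; cubic spline for the image, nearest for labels."""
    cfg.validate()
    if vol.shape != mask.shape:
        raise ValueError(f"volume {vol.shape} and mask {mask.shape} differ")
    if any(s <= 0 for s in vol.spacing):
        raise ValueError(f"degenerate spacing {vol.spacing}")
    sz = vol.spacing[0] / cfg.target_z_spacing_mm
    factors = (sz, cfg.in_plane_factor, cfg.in_plane_factor)
    if np.allclose(factors, 1.0):
        return (Volume3D(vol.data.copy(), vol.spacing, vol.affine.copy()),
                LabelMask(mask.data.copy(), mask.spacing, mask.affine.copy()))
    img = ndimage.zoom(vol.data, factors, order=3, mode="nearest")
    lab = ndimage.zoom(mask.data, factors, order=0, mode="nearest")
    new_spacing = tuple(s * o / n
                        for s, o, n in zip(vol.spacing, vol.shape, img.shape))
    aff = vol.affine.copy()
    # affine columns are ordered (x, y, z); array axes are (z, y, x)
    for col, ax in ((0, 2), (1, 1), (2, 0)):
        aff[:3, col] *= new_spacing[ax] / vol.spacing[ax]
    return (Volume3D(img, new_spacing, aff),
            LabelMask(lab, new_spacing, aff.copy()))


def sample_liver_slab(vol: Volume3D, mask: LabelMask, slab_slices: int,
                      seed: int) -> tuple[Volume3D, LabelMask]:
    """Draw ``slab_slices`` consecutive axial slices whose union contains at
    least one liver voxel; window start is uniform over valid starts.

    Volumes shorter than the slab are zero-padded symmetrically and the
    padding is recorded in ``meta['z_padding']``.
    """
    liver_per_slice = (mask.data >= 1).any(axis=(1, 2))
    if not liver_per_slice.any():
        raise NoLiverError("no liver present in the mask")
    depth = vol.shape[0]
    rng = np.random.default_rng(seed)

    if depth <= slab_slices:
        pad = slab_slices - depth
        before, after = pad // 2, pad - pad // 2
        spec = ((before, after), (0, 0), (0, 0))
        img = np.pad(vol.data, spec)
        lab = np.pad(mask.data, spec)
        meta = {"z_padding": (before, after), "z_start": 0}
        return (Volume3D(img, vol.spacing, vol.affine.copy(), meta),
                LabelMask(lab, mask.spacing, mask.affine.copy(), dict(meta)))

    liver_idx = np.flatnonzero(liver_per_slice)
    lo = max(0, liver_idx[0] - slab_slices + 1)
    hi = min(depth - slab_slices, liver_idx[-1])
    starts = np.arange(lo, hi + 1)
    # every start in [lo, hi] yields a window intersecting the liver range
    start = int(rng.choice(starts))
    sl = slice(start, start + slab_slices)
    meta = {"z_padding": (0, 0), "z_start": start}
    return (Volume3D(vol.data[sl].copy(), vol.spacing, vol.affine.copy(), meta),
            LabelMask(mask.data[sl].copy(), mask.spacing, mask.affine.copy(),
                      dict(meta)))


def minmax_normalize(vol: Volume3D) -> Volume3D:
    lo, hi = float(vol.data.min()), float(vol.data.max())
    if hi <= lo:
        warnings.warn("constant volume: min-max normalization returns zeros")
        return Volume3D(np.zeros_like(vol.data), vol.spacing, vol.affine.copy(),
                        dict(vol.meta))
    out = (vol.data - lo) / (hi - lo)
    return Volume3D(out, vol.spacing, vol.affine.copy(), dict(vol.meta))


def run_chain(vol: Volume3D, mask: LabelMask,
              cfg: PreprocessConfig) -> tuple[Volume3D, LabelMask]:
    """clip → resample → slab-sample → normalize (normalization is applied
    to the slab actually fed to the network)."""
    cfg.validate()
    vol = clip_hu(vol, cfg.hu_lo, cfg.hu_hi)
    vol, mask = resample(vol, mask, cfg)
    vol, mask = sample_liver_slab(vol, mask, cfg.slab_slices, cfg.seed)
    vol = minmax_normalize(vol)
    return vol, mask
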