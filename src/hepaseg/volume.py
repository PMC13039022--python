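"""Core volumetric data types and NIfTI I/O.

Arrays are ordered (z, y, x): the first axis is axial slice position.
NIfTI stores (x, y, z), so axes are reversed on read and write; the affine
is carried through unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

BACKGROUND, LIVER, TUMOR = 0, 1, 2


@dataclass
class Volume3D:
    """A scalar 3D intensity grid with physical spacing in mm."""

    data: np.ndarray                     # (z, y, x), float32
    spacing: tuple[float, float, float]  # (sz, sy, sx) mm
    affine: np.ndarray | None = None     # 4x4 voxel->world map (xyz order)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.affine is None:
            self.affine = default_affine(self.spacing)

    @property
    def shape(self):
        return self.data.shape


@dataclass
class LabelMask:
    """Integer labels {0 background, 1 liver, 2 tumor} aligned to a Volume3D."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.affine is None:
            self.affine = default_affine(self.spacing)

    @property
    def shape(self):
        return self.data.shape

    def liver_region(self) -> np.ndarray:
        """Whole-organ region: labels {1} ∪ {2}."""
        return self.data >= LIVER

    def tumor_region(self) -> np.ndarray:
        return self.data == TUMOR


def default_affine(spacing_zyx) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing_zyx[2], spacing_zyx[1], spacing_zyx[0]
    return aff


def _spacing_from_affine(affine: np.ndarray):
    sx, sy, sz = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    return (float(sz), float(sy), float(sx))


def read_volume(path) -> Volume3D:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float32).transpose(2, 1, 0)
    return Volume3D(data, _spacing_from_affine(img.affine), affine=img.affine)


def read_mask(path) -> LabelMask:
    img = nib.load(str(path))
    data = np.rint(np.asanyarray(img.dataobj)).astype(np.uint8).transpose(2, 1, 0)
    return LabelMask(data, _spacing_from_affine(img.affine), affine=img.affine)


def write_volume(vol: Volume3D, path) -> None:
    img = nib.Nifti1Image(vol.data.transpose(2, 1, 0).astype(np.float32),
                          vol.affine)
    nib.save(img, str(path))


def write_mask(mask: LabelMask, path) -> None:
    img = nib.Nifti1Image(mask.data.transpose(2, 1, 0).astype(np.uint8),
                          mask.affine)
    nib.save(img, str(path))
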