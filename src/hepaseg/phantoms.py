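"""Seedable synthetic CT phantoms: an ellipsoidal liver with spherical
hypodense lesions, optionally one distractor lesion outside the organ.

Shapes are analytic (ellipsoid/spheres) so voxel counts can be checked
against closed-form volumes.  One ``numpy.random.Generator`` stream drives
both lesion placement and intensity noise, so a config + seed pair fully
determines the output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .volume import LabelMask, Volume3D, write_mask, write_volume

MAX_PLACEMENT_ATTEMPTS = 500


class PlacementError(RuntimeError):
    """Raised when lesions cannot be placed without overlap."""


@dataclass(frozen=True)
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (48, 64, 64)          # (z, y, x) voxels
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)  # (z, y, x)
    liver_semiaxes_mm: tuple[float, float, float] = (18.0, 24.0, 24.0)
    n_tumors: int = 2
    tumor_radius_range_mm: tuple[float, float] = (4.0, 8.0)
    distractor_outside_liver: bool = False
    intensity_means: tuple[float, float, float] = (-120.0, 90.0, 30.0)
    noise_sd: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if any(s <= 0 for s in self.liver_semiaxes_mm):
            raise ValueError("liver semi-axes must be strictly positive")
        rmin, rmax = self.tumor_radius_range_mm
        if rmin <= 0 or rmax < rmin:
            raise ValueError("tumor radius range must be positive and ordered")
        if rmax >= min(self.liver_semiaxes_mm):
            raise ValueError("tumor max radius must be < smallest liver semi-axis")
        if self.n_tumors < 0:
            raise ValueError("n_tumors must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        bg, liver, tumor = self.intensity_means
        if not tumor < liver:
            raise ValueError("tumor mean must be below liver mean (hypodense)")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "PhantomConfig":
        d = json.loads(s)
        for k in ("grid_shape", "spacing_mm", "liver_semiaxes_mm",
                  "tumor_radius_range_mm", "intensity_means"):
            d[k] = tuple(d[k])
        return cls(**d)


def _coords_mm(cfg: PhantomConfig):
    """Voxel-center coordinates (mm) relative to the grid center, per axis."""
    out = []
    for n, s in zip(cfg.grid_shape, cfg.spacing_mm):
        out.append((np.arange(n) - (n - 1) / 2.0) * s)
    return np.meshgrid(*out, indexing="ij", sparse=True)


def _ellipsoid_gauge(zc, yc, xc, semiaxes):
    az, ay, ax = semiaxes
    return np.sqrt((zc / az) ** 2 + (yc / ay) ** 2 + (xc / ax) ** 2)


def _sample_center_inside(rng, cfg: PhantomConfig, radius: float):
    """A point whose `radius`-ball provably stays inside the ellipsoid."""
    az, ay, ax = cfg.liver_semiaxes_mm
    amin = min(az, ay, ax)
    limit = 1.0 - radius / amin
    if limit <= 0:
        return None
    for _ in range(MAX_PLACEMENT_ATTEMPTS):
        p = rng.uniform(-1.0, 1.0, size=3) * (az, ay, ax)
        if np.sqrt(((p / (az, ay, ax)) ** 2).sum()) <= limit:
            return p
    return None


def _sample_center_outside(rng, cfg: PhantomConfig, radius: float):
    """A point whose `radius`-ball provably avoids the ellipsoid but stays
    inside the grid."""
    az, ay, ax = cfg.liver_semiaxes_mm
    amin = min(az, ay, ax)
    half = [(n - 1) / 2.0 * s - radius - s
            for n, s in zip(cfg.grid_shape, cfg.spacing_mm)]
    if any(h <= 0 for h in half):
        return None
    for _ in range(MAX_PLACEMENT_ATTEMPTS):
        p = rng.uniform(-1.0, 1.0, size=3) * half
        if np.sqrt(((p / (az, ay, ax)) ** 2).sum()) >= 1.0 + radius / amin:
            return p
    return None


def generate_phantom(cfg: PhantomConfig) -> tuple[Volume3D, LabelMask]:
    """Generate one phantom volume + label mask from a validated config."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    zc, yc, xc = _coords_mm(cfg)

    labels = np.zeros(cfg.grid_shape, dtype=np.uint8)
    labels[_ellipsoid_gauge(zc, yc, xc, cfg.liver_semiaxes_mm) <= 1.0] = 1

    placed: list[tuple[np.ndarray, float]] = []  # (center, radius)
    rmin, rmax = cfg.tumor_radius_range_mm
    for _ in range(cfg.n_tumors):
        for _ in range(MAX_PLACEMENT_ATTEMPTS):
            r = float(rng.uniform(rmin, rmax))
            c = _sample_center_inside(rng, cfg, r)
            if c is None:
                continue
            if all(np.linalg.norm(c - pc) > r + pr for pc, pr in placed):
                placed.append((c, r))
                break
        else:
            raise PlacementError(
                f"could not place {cfg.n_tumors} non-overlapping tumors "
                f"after {MAX_PLACEMENT_ATTEMPTS} attempts")

    if cfg.distractor_outside_liver:
        for _ in range(MAX_PLACEMENT_ATTEMPTS):
            r = float(rng.uniform(rmin, rmax))
            c = _sample_center_outside(rng, cfg, r)
            if c is not None:
                placed.append((c, r))
                break
        else:
            raise PlacementError("could not place the extra-hepatic distractor")

    for c, r in placed:
        d = np.sqrt((zc - c[0]) ** 2 + (yc - c[1]) ** 2 + (xc - c[2]) ** 2)
        labels[d <= r] = 2

    means = np.asarray(cfg.intensity_means, dtype=np.float32)
    data = means[labels]
    if cfg.noise_sd > 0:
        data = data + rng.normal(0.0, cfg.noise_sd,
                                 size=cfg.grid_shape).astype(np.float32)

    vol = Volume3D(data, cfg.spacing_mm)
    mask = LabelMask(labels, cfg.spacing_mm)
    return vol, mask


def phantom_batch(cfg_list: list[PhantomConfig], out_dir) -> pd.DataFrame:
    """Write image/label NIfTI pairs plus a CSV manifest; returns the manifest."""
    if not cfg_list:
        raise ValueError("cfg_list must be non-empty")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, cfg in enumerate(cfg_list):
        vol, mask = generate_phantom(cfg)
        img_path = out_dir / f"phantom_{i:03d}_img.nii.gz"
        lab_path = out_dir / f"phantom_{i:03d}_lab.nii.gz"
        try:
            write_volume(vol, img_path)
            write_mask(mask, lab_path)
        except OSError as e:
            raise OSError(f"failed writing phantom files under {out_dir}: {e}") from e
        rows.append({"image": str(img_path), "label": str(lab_path),
                     "seed": cfg.seed, "config": cfg.to_json()})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def read_manifest(path) -> list[PhantomConfig]:
    df = pd.read_csv(path)
    return [PhantomConfig.from_json(s) for s in df["config"]]
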