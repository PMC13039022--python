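"""Segmentation metrics: Dice, VOE, RVD, spacing-aware average symmetric
surface distance and 95th-percentile Hausdorff distance, plus tumor-size
stratification by maximum per-axis component extent.

Conventions (documented because the printed formulas leave them open):
- VOE is reported as 1 − Dice; a strict Jaccard variant (1 − |∩|/|∪|) is
  available via ``jaccard_voe=True``.
- RVD is (|P| − |G|)/|P|; flags switch the denominator to |G| and/or take
  the absolute value.
- Surfaces are mask voxels with a 6-neighbour outside the mask (array
  borders count as outside); distances use the Euclidean distance
  transform with physical spacing.
- Both-empty Dice is 1.0 with a flag; surface distances of an empty mask
  are NaN sentinels with a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

SIZE_BIN_EDGES = (10.0, 20.0, 30.0, 50.0)
SIZE_BIN_NAMES = ("small (<10)", "small-medium (10-20)", "medium (20-30)",
                  "large (30-50)", "very large (>=50)")

_STRUCT6 = ndimage.generate_binary_structure(3, 1)   # 6-connectivity
_STRUCT26 = ndimage.generate_binary_structure(3, 3)  # 26-connectivity


@dataclass
class MetricReport:
    dice: float
    voe: float
    rvd: float
    asd_mm: float
    hd95_mm: float
    both_empty: bool = False
    pred_empty: bool = False
    gt_empty: bool = False
    distances_defined: bool = True


@dataclass
class SizeStrata:
    bin_names: tuple = SIZE_BIN_NAMES
    counts: list = field(default_factory=lambda: [0] * 5)
    dice: list = field(default_factory=lambda: [[] for _ in range(5)])
    empty: bool = False

    def mean_dice(self) -> list:
        return [float(np.mean(d)) if d else float("nan") for d in self.dice]


def _check(p, g):
    p = np.asarray(p).astype(bool)
    g = np.asarray(g).astype(bool)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    return p, g


def dice(pred, gt) -> float:
    """2|P∩G| / (|P|+|G|); both-empty defined as 1.0."""
    p, g = _check(pred, gt)
    ps, gs = int(p.sum()), int(g.sum())
    if ps + gs == 0:
        return 1.0
    return 2.0 * int((p & g).sum()) / (ps + gs)


def voe(pred, gt, jaccard_voe: bool = False) -> float:
    p, g = _check(pred, gt)
    if jaccard_voe:
        union = int((p | g).sum())
        if union == 0:
            return 0.0
        return 1.0 - int((p & g).sum()) / union
    return 1.0 - dice(p, g)


def rvd(pred, gt, absolute: bool = False, gt_denominator: bool = False) -> float:
    p, g = _check(pred, gt)
    ps, gs = int(p.sum()), int(g.sum())
    denom = gs if gt_denominator else ps
    if denom == 0:
        raise ZeroDivisionError("RVD undefined: denominator mask is empty")
    val = (ps - gs) / denom
    return abs(val) if absolute else val


def surface_voxels(mask) -> np.ndarray:
    """Boolean map of mask voxels with at least one 6-neighbour outside the
    mask; voxels on the array border always qualify."""
    m = np.asarray(mask).astype(bool)
    if not m.any():
        raise ValueError("surface of an empty mask is undefined")
    interior = ndimage.binary_erosion(m, structure=_STRUCT6, border_value=0)
    return m & ~interior


def _directed_distances(src_surface, dst_surface, spacing) -> np.ndarray:
    """Distance (mm) from every voxel of src_surface to the nearest voxel
    of dst_surface, via the Euclidean distance transform of ~dst."""
    dt = ndimage.distance_transform_edt(~dst_surface, sampling=spacing)
    return dt[src_surface]


def asd(pred, gt, spacing=(1.0, 1.0, 1.0)) -> float:
    """Average symmetric surface distance in mm."""
    p, g = _check(pred, gt)
    if not p.any() or not g.any():
        raise ValueError("surface distance undefined for an empty mask")
    sp, sg = surface_voxels(p), surface_voxels(g)
    d_pg = _directed_distances(sp, sg, spacing)
    d_gp = _directed_distances(sg, sp, spacing)
    return float((d_pg.sum() + d_gp.sum()) / (d_pg.size + d_gp.size))


def hd95(pred, gt, spacing=(1.0, 1.0, 1.0)) -> float:
    """95th percentile (linear interpolation) of the pooled directed
    surface distances, in mm."""
    p, g = _check(pred, gt)
    if not p.any() or not g.any():
        raise ValueError("surface distance undefined for an empty mask")
    sp, sg = surface_voxels(p), surface_voxels(g)
    pooled = np.concatenate([_directed_distances(sp, sg, spacing),
                             _directed_distances(sg, sp, spacing)])
    return float(np.percentile(pooled, 95, method="linear"))


def evaluate_masks(pred, gt, spacing=(1.0, 1.0, 1.0),
                   rvd_absolute: bool = False) -> MetricReport:
    """All five metrics with the empty-mask conventions applied."""
    p, g = _check(pred, gt)
    ps, gs = bool(p.any()), bool(g.any())
    d = dice(p, g)
    v = voe(p, g)
    if ps:
        r = rvd(p, g, absolute=rvd_absolute)
    else:
        r = float("nan")
    if ps and gs:
        a, h = asd(p, g, spacing), hd95(p, g, spacing)
        defined = True
    else:
        a = h = float("nan")
        defined = False
    return MetricReport(dice=d, voe=v, rvd=r, asd_mm=a, hd95_mm=h,
                        both_empty=not ps and not gs, pred_empty=not ps,
                        gt_empty=not gs, distances_defined=defined)


def _component_max_extent(component_mask) -> int:
    """Maximum per-axis extent of a component, in voxels."""
    idx = np.argwhere(component_mask)
    return int((idx.max(axis=0) - idx.min(axis=0) + 1).max())


def size_bin(extent_voxels: float) -> int:
    """Half-open bins: <10, [10,20), [20,30), [30,50), >=50."""
    return int(np.searchsorted(SIZE_BIN_EDGES, extent_voxels, side="right"))


def stratify_by_size(pred, gt, spacing=(1.0, 1.0, 1.0), margin: int = 5) -> SizeStrata:
    """Bin 26-connected ground-truth tumor components by maximum voxel
    extent; per-component Dice is computed against the prediction inside
    the component's bounding box dilated by ``margin`` voxels."""
    p, g = _check(pred, gt)
    strata = SizeStrata()
    labeled, n = ndimage.label(g, structure=_STRUCT26)
    if n == 0:
        strata.empty = True
        return strata
    objects = ndimage.find_objects(labeled)
    for comp_id, sl in enumerate(objects, start=1):
        comp = labeled == comp_id
        b = size_bin(_component_max_extent(comp))
        grown = tuple(
            slice(max(0, s.start - margin), min(dim, s.stop + margin))
            for s, dim in zip(sl, g.shape))
        strata.counts[b] += 1
        strata.dice[b].append(dice(p[grown], comp[grown]))
    return strata
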