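"""Hybrid training objective: segmentation (Dice + BCE per head),
vector-quantization loss, and the anatomical containment penalty

    L_contain = (1/N) Σ_x max(0, T(x) − L(x)),

which is zero exactly when the predicted tumor probability never exceeds
the predicted liver probability.  Total: L_seg + α·L_VQ + β·L_contain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor

_EPS = 1e-7
DICE_SMOOTH = 1.0


@dataclass(frozen=True)
class LossWeights:
    alpha: float = 0.4      # VQ loss weight
    beta: float = 0.6       # containment loss weight
    lambda_vq: float = 0.25  # commitment weight inside the VQ loss

    def validate(self) -> None:
        if self.alpha < 0 or self.beta < 0 or self.lambda_vq < 0:
            raise ValueError("loss weights must be non-negative")


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def containment_loss(tumor_prob, liver_prob) -> Tensor:
    """Mean positive part of T − L over all voxels (differentiable)."""
    t, l = _wrap(tumor_prob), _wrap(liver_prob)
    if t.shape != l.shape:
        raise ValueError(f"shape mismatch: {t.shape} vs {l.shape}")
    return ag.relu(t - l).mean()


def soft_dice_loss(prob: Tensor, target: Tensor) -> Tensor:
    """1 − (2·Σpg + ε) / (Σp + Σg + ε) with ε = 1."""
    inter = (prob * target).sum()
    denom = prob.sum() + target.sum()
    return 1.0 - (2.0 * inter + DICE_SMOOTH) / (denom + DICE_SMOOTH)


def bce_loss(prob: Tensor, target: Tensor) -> Tensor:
    p = ag.clip(prob, _EPS, 1.0 - _EPS)
    return -(target * ag.log(p) + (1.0 - target) * ag.log(1.0 - p)).mean()


def segmentation_loss(liver_prob, tumor_prob, liver_gt, tumor_gt) -> Tensor:
    """Mean over the two heads of (soft-Dice + BCE)/2."""
    liver_prob, tumor_prob = _wrap(liver_prob), _wrap(tumor_prob)
    liver_gt, tumor_gt = _wrap(liver_gt), _wrap(tumor_gt)
    if liver_prob.shape != liver_gt.shape or tumor_prob.shape != tumor_gt.shape:
        raise ValueError("prediction/target shape mismatch")
    liver_term = (soft_dice_loss(liver_prob, liver_gt)
                  + bce_loss(liver_prob, liver_gt)) * 0.5
    tumor_term = (soft_dice_loss(tumor_prob, tumor_gt)
                  + bce_loss(tumor_prob, tumor_gt)) * 0.5
    return (liver_term + tumor_term) * 0.5


def hybrid_loss(seg, vq, contain, weights: LossWeights) -> Tensor:
    weights.validate()
    return _wrap(seg) + weights.alpha * _wrap(vq) + weights.beta * _wrap(contain)
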