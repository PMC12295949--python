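"""Segmentation objectives: soft Dice, binary cross-entropy, and their
weighted hybrid.

Tumors occupy a tiny fraction of an abdominal CT slice, so plain pixel-wise
cross-entropy is dominated by background; the Dice term scores overlap
independently of target size, while the BCE term keeps per-pixel gradients
smooth and stabilizes early training.  The hybrid objective is
``alpha * L_Dice + beta * L_BCE``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor


@dataclass
class LossConfig:
    alpha: float = 1.0              # Dice weight
    beta: float = 1.0               # BCE weight
    smooth: float = 1e-5            # soft-Dice stabilizer (empty targets)
    clamp_eps: float = 1e-7         # probability clamp before logs

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0 or self.alpha + self.beta <= 0:
            raise ValueError(
                f"loss weights must be >= 0 with alpha + beta > 0, "
                f"got alpha={self.alpha}, beta={self.beta}")
        if self.smooth <= 0:
            raise ValueError("smooth must be positive")
        if not 0 < self.clamp_eps < 0.5:
            raise ValueError("clamp_eps must lie in (0, 0.5)")


def _check(pred, target):
    pred = pred if isinstance(pred, Tensor) else Tensor(pred)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")
    return pred, target


def dice_loss(pred, target, smooth: float = 1e-5) -> Tensor:
    """Soft Dice loss, ``1 - (2*sum(p*t)+s) / (sum(p)+sum(t)+s)``, computed
    over all voxels of the batch at once."""
    pred, target = _check(pred, target)
    intersection = (pred * target).sum()
    return 1.0 - (2.0 * intersection + smooth) / (pred.sum() + target.sum() + smooth)


def bce_loss(pred, target, clamp_eps: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy; probabilities are clamped to
    [eps, 1-eps] before the logs."""
    pred, target = _check(pred, target)
    p = pred.clamp(clamp_eps, 1.0 - clamp_eps)
    return -(p.log() * target + (1.0 - p).log() * (1.0 - target)).mean()


def hybrid_loss(pred, target, config: LossConfig | None = None) -> Tensor:
    """``alpha * dice_loss + beta * bce_loss`` (differentiable in pred)."""
    cfg = config if config is not None else LossConfig()
    return (cfg.alpha * dice_loss(pred, target, cfg.smooth)
            + cfg.beta * bce_loss(pred, target, cfg.clamp_eps))
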