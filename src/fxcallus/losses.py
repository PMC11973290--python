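"""Composite training objective for the segmentation network.

The total loss sums, over the M deeply-supervised decoder stages, an L1 loss
for the noise branch, an L1 loss for the texture branch, and a focal+Dice
edge loss, plus a weighted BCE+Dice segmentation loss::

    L_total = sum_j L_noise^j + sum_j L_texture^j + sum_j L_edge^j + delta * L_seg
    L_edge  = alpha * L_focal + (1 - alpha) * L_dice
    L_seg   = lambda_bce * L_bce + lambda_dice * L_dice

All losses consume probabilities (not logits); predictions are clamped to
[1e-7, 1 - 1e-7] before any logarithm. The L1 map losses are mean-normalized
per map so stages of different resolution contribute on a common scale.
"""

from __future__ import annotations

from dataclasses import dataclass

from .nn.tensor import Tensor, as_tensor

__all__ = ["LossWeights", "dice_loss", "focal_loss", "bce_loss", "l1_map_loss", "total_loss"]

_EPS_DICE = 1e-6
_EPS_PROB = 1e-7


@dataclass(frozen=True)
class LossWeights:
    """Weights of the composite objective.

    ``alpha`` balances focal vs Dice inside the edge loss; ``delta`` scales the
    segmentation term against the branch terms; ``lambda_bce``/``lambda_dice``
    weight the two segmentation components (both default to 1); ``focal_gamma``
    is the focal-loss focusing exponent.
    """

    alpha: float = 0.5
    delta: float = 1.0
    lambda_bce: float = 1.0
    lambda_dice: float = 1.0
    focal_gamma: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.delta < 0 or self.lambda_bce < 0 or self.lambda_dice < 0 or self.focal_gamma < 0:
            raise ValueError("delta, lambdas and focal_gamma must be non-negative")


def _check_shapes(pred: Tensor, target: Tensor) -> None:
    if pred.shape != target.shape:
        raise ValueError(f"prediction shape {pred.shape} does not match target shape {target.shape}")


def dice_loss(pred, target, eps: float = _EPS_DICE) -> Tensor:
    """Soft Dice loss 1 - (2 sum(p t) + eps) / (sum p + sum t + eps)."""
    pred, target = as_tensor(pred), as_tensor(target)
    _check_shapes(pred, target)
    inter = (pred * target).sum()
    denom = pred.sum() + target.sum() + eps
    return 1.0 - (2.0 * inter + eps) / denom


def focal_loss(pred, target, gamma: float = 2.0, balance: float = 1.0) -> Tensor:
    """Mean focal loss -balance * (1 - p_t)^gamma * log(p_t); gamma=0 gives BCE."""
    pred, target = as_tensor(pred), as_tensor(target)
    _check_shapes(pred, target)
    p = pred.clip(_EPS_PROB, 1.0 - _EPS_PROB)
    pt = p * target + (1.0 - p) * (1.0 - target)
    if gamma == 0:
        weight = 1.0
        loss = -(pt.log()) * balance
    else:
        weight = (1.0 - pt) ** gamma
        loss = -(weight * pt.log()) * balance
    return loss.mean()


def bce_loss(pred, target) -> Tensor:
    """Mean binary cross-entropy on clamped probabilities."""
    return focal_loss(pred, target, gamma=0.0, balance=1.0)


def l1_map_loss(y, m) -> Tensor:
    """Mean absolute difference between a predicted and a reference scalar map."""
    y, m = as_tensor(y), as_tensor(m)
    _check_shapes(y, m)
    return (y - m).abs().mean()


def total_loss(outputs, targets, w: LossWeights = LossWeights()) -> tuple[Tensor, dict[str, float]]:
    """Composite loss plus its per-term breakdown.

    ``outputs`` carries the segmentation foreground probability and M per-stage
    (edge_prob, noise, texture) triples; ``targets`` carries the ROI mask and
    the matching M-deep target pyramid (see :class:`fxcallus.segnet.ForwardOutput`
    and :class:`fxcallus.segnet.TargetPyramid`). Disabled branches (None in the
    triple) contribute nothing. The returned breakdown sums to the total.
    """
    if len(outputs.aux) != len(targets.aux):
        raise ValueError(
            f"decoder emitted {len(outputs.aux)} stage triples but target pyramid has {len(targets.aux)}"
        )
    breakdown: dict[str, float] = {}
    total = Tensor(0.0)
    for j, (out_stage, tgt_stage) in enumerate(zip(outputs.aux, targets.aux), start=1):
        edge_p, y_n, y_t = out_stage
        edge_gt, m_n, m_t = tgt_stage
        if edge_p is not None:
            focal = focal_loss(edge_p, edge_gt, gamma=w.focal_gamma)
            dice = dice_loss(edge_p, edge_gt)
            term = w.alpha * focal + (1.0 - w.alpha) * dice
            breakdown[f"edge_{j}"] = term.item()
            total = total + term
        if y_n is not None:
            term = l1_map_loss(y_n, m_n)
            breakdown[f"noise_{j}"] = term.item()
            total = total + term
        if y_t is not None:
            term = l1_map_loss(y_t, m_t)
            breakdown[f"texture_{j}"] = term.item()
            total = total + term
    seg_p = outputs.seg_prob
    seg_term = w.lambda_bce * bce_loss(seg_p, targets.roi) + w.lambda_dice * dice_loss(seg_p, targets.roi)
    breakdown["seg"] = w.delta * seg_term.item()
    total = total + w.delta * seg_term
    breakdown["total"] = total.item()
    return total, breakdown
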