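"""Soft segmentation losses and the masked combined objective.

The supervised term compares the prediction with the fused soft label; the
consistency term compares the network's output on a flipped image with the
flipped output on the original image (self-ensembling, no labels needed).
Both terms are per-pixel cross-entropies (soft Dice and soft focal variants
are available for the supervised term), combined as

    L = lambda1 * < mask_GT  . CE(p, p_hat) >
      + lambda2 * < mask_CR  . CE(f(flip(x)), flip(f(x))) > ,

with lambda1 = 1 - lambda2 and the masks from the uncertainty module.
All reductions are means over pixels, which keeps the learning-rate scale
independent of image size.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .fusion import SoftLabel
from .uncertainty import MaskPair

LOG_FLOOR = 1e-8  # clamp for log arguments
DICE_SMOOTH = 1e-5


class FlipTransform(str, Enum):
    """Involutive spatial flips used for consistency regularization."""

    HORIZONTAL = "horizontal"
    VERTICAL = "vertical"
    BOTH = "both"


def apply_flip(arr: np.ndarray, flip: FlipTransform, axes: tuple[int, int] = (0, 1)) -> np.ndarray:
    """Flip a (H, W, ...) array spatially; applying twice is the identity."""
    flip = FlipTransform(flip)
    ax_v, ax_h = axes
    if flip is FlipTransform.HORIZONTAL:
        return np.flip(arr, axis=ax_h)
    if flip is FlipTransform.VERTICAL:
        return np.flip(arr, axis=ax_v)
    return np.flip(np.flip(arr, axis=ax_h), axis=ax_v)


@dataclass(frozen=True)
class LossWeights:
    """Convex weights of the supervised and consistency terms."""

    lambda2: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda2 <= 1.0:
            raise ValueError("lambda2 must be in [0, 1]")

    @property
    def lambda1(self) -> float:
        return 1.0 - self.lambda2


@dataclass
class Prediction:
    """Network output: per-pixel softmax probabilities, shape (H, W, C)."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 3:
            raise ValueError("probs must be (H, W, C)")
        if not np.allclose(self.probs.sum(axis=-1), 1.0, atol=1e-5):
            raise ValueError("prediction channels must sum to 1 per pixel")

    def hard_mask(self) -> np.ndarray:
        return np.argmax(self.probs, axis=-1)


def _as_probs(x) -> np.ndarray:
    return np.asarray(getattr(x, "probs", x), dtype=np.float64)


def _check_shapes(target: np.ndarray, pred: np.ndarray) -> None:
    if target.shape != pred.shape:
        raise ValueError(f"shape mismatch: target {target.shape} vs pred {pred.shape}")


def _weighted_mean(per_pixel: np.ndarray, pixel_weights: np.ndarray | None) -> float:
    if pixel_weights is None:
        return float(per_pixel.mean())
    pixel_weights = np.asarray(pixel_weights, dtype=np.float64)
    if pixel_weights.shape != per_pixel.shape:
        raise ValueError("pixel_weights shape must match the spatial shape")
    if (pixel_weights < 0).any():
        raise ValueError("pixel_weights must be nonnegative")
    return float((pixel_weights * per_pixel).mean())


def cross_entropy_map(target, pred) -> np.ndarray:
    """Per-pixel -sum_c t_c log p_c with the log clamped at LOG_FLOOR."""
    t, p = _as_probs(target), _as_probs(pred)
    _check_shapes(t, p)
    return -(t * np.log(np.maximum(p, LOG_FLOOR))).sum(axis=-1)


def soft_cross_entropy(target, pred, pixel_weights: np.ndarray | None = None) -> float:
    """Weighted mean over pixels of the soft cross-entropy."""
    return _weighted_mean(cross_entropy_map(target, pred), pixel_weights)


def soft_dice(target, pred, smooth: float = DICE_SMOOTH) -> float:
    """1 - mean_c (2 sum t*p + s) / (sum t + sum p + s)."""
    t, p = _as_probs(target), _as_probs(pred)
    _check_shapes(t, p)
    axes = tuple(range(t.ndim - 1))
    inter = (t * p).sum(axis=axes)
    denom = t.sum(axis=axes) + p.sum(axis=axes)
    dice = (2.0 * inter + smooth) / (denom + smooth)
    return float(1.0 - dice.mean())


def soft_focal(target, pred, gamma: float = 2.0, pixel_weights: np.ndarray | None = None) -> float:
    """Focal-modulated soft cross-entropy: -sum t (1-p)^gamma log p.

    gamma = 0 recovers the plain soft cross-entropy.
    """
    if gamma < 0:
        raise ValueError("gamma must be nonnegative")
    t, p = _as_probs(target), _as_probs(pred)
    _check_shapes(t, p)
    per_pixel = -(t * (1.0 - p) ** gamma * np.log(np.maximum(p, LOG_FLOOR))).sum(axis=-1)
    return _weighted_mean(per_pixel, pixel_weights)


def consistency_loss(
    pred_of_flipped, flipped_pred, pixel_weights: np.ndarray | None = None
) -> float:
    """Cross-entropy between the two branches of the flip-consistency pair.

    ``pred_of_flipped`` — the network applied to the flipped image — plays
    the target; ``flipped_pred`` — the flipped prediction on the original
    image — plays the prediction.  For a flip-equivariant network the two
    coincide and the loss sits at its minimum, the target's own entropy.
    """
    return soft_cross_entropy(pred_of_flipped, flipped_pred, pixel_weights)


_SUPERVISED = {
    "ce": lambda t, p, w: soft_cross_entropy(t, p, w),
    "dice": lambda t, p, w: soft_dice(t, p),
    "focal": lambda t, p, w: soft_focal(t, p, pixel_weights=w),
}


@dataclass
class LossComponents:
    """Total objective with its two logged components."""

    total: float
    supervised: float
    consistency: float


def total_loss(
    target,
    pred,
    pred_of_flipped,
    flipped_pred,
    masks: MaskPair,
    weights: LossWeights,
    supervised: str = "ce",
    consistency: str = "ce",
) -> LossComponents:
    """Masked combined objective.

    The supervised term is masked by gt_mask (confident pixels only); the
    consistency term is weighted by cr_mask (everywhere, doubled on
    uncertain pixels).  Returns the weighted total together with the two
    unweighted-by-lambda components for logging.
    """
    if supervised not in _SUPERVISED or consistency not in _SUPERVISED:
        raise ValueError("loss kind must be one of 'ce', 'dice', 'focal'")
    sup = _SUPERVISED[supervised](target, pred, masks.gt_mask)
    if consistency == "dice":
        cons = soft_dice(pred_of_flipped, flipped_pred)
    else:
        w = masks.cr_mask
        cons = _SUPERVISED[consistency](pred_of_flipped, flipped_pred, w)
    total = weights.lambda1 * sup + weights.lambda2 * cons
    return LossComponents(total=total, supervised=sup, consistency=cons)
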