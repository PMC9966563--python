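"""Pixelwise annotation uncertainty and the asymmetric loss masks.

Rater disagreement is quantified per pixel as the *interclass variance* of
the soft label,

    Var(p) = (1/C) * sum_c (p_c - 1/C)^2 ,

which is maximal (at (C-1)/C^2) where the soft label is one-hot — full
rater agreement — and zero where it is uniform — maximal disagreement.
Note the inverse relation to entropy: LOW variance means HIGH uncertainty.

Thresholding the variance at mu partitions the image into a confidently
annotated region, where the supervised loss applies, and an uncertain
region, where supervision is withheld and only consistency regularization
acts (with double weight, so the two loss masks satisfy
cr_mask - 1 = 1 - gt_mask pointwise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .fusion import SoftLabel


@dataclass
class VarianceMap:
    """Per-pixel interclass variance, values in [0, (C-1)/C^2]."""

    var: np.ndarray
    num_classes: int

    @property
    def max_attainable(self) -> float:
        c = self.num_classes
        return (c - 1) / c**2


@dataclass
class MaskPair:
    """The asymmetric loss masks derived from a variance threshold mu.

    gt_mask is 1 where variance >= mu (confident pixels, supervised loss
    active); cr_mask is 1 everywhere plus 1 where variance < mu (the
    additive reading of the all-ones offset), so consistency regularization
    acts everywhere and with double weight on uncertain pixels.
    """

    gt_mask: np.ndarray  # {0, 1}
    cr_mask: np.ndarray  # {1, 2}
    mu: float

    @property
    def unsupervised_proportion(self) -> float:
        """Fraction of pixels whose supervision is withheld (var < mu)."""
        return float(1.0 - self.gt_mask.mean())


def interclass_variance(label: SoftLabel) -> VarianceMap:
    """Var[i,j] = (1/C) * sum_c (p[i,j,c] - 1/C)^2."""
    p = label.probs
    c = label.num_classes
    var = ((p - 1.0 / c) ** 2).sum(axis=-1) / c
    return VarianceMap(var=var, num_classes=c)


def make_masks(var: VarianceMap, mu: float, mode: str = "additive") -> MaskPair:
    """Threshold a variance map into the supervised/consistency mask pair.

    ``mode='additive'`` (default) gives cr_mask = 1 + 1[var < mu] in {1, 2};
    ``mode='replace'`` gives cr_mask = max(1, 1[var < mu]), i.e. all ones.
    """
    if mu < 0:
        raise ValueError("mu must be non-negative")
    if mu > var.max_attainable:
        warnings.warn(
            f"mu={mu} exceeds the attainable variance ceiling "
            f"{var.max_attainable:.4g}; every pixel will be unsupervised",
            stacklevel=2,
        )
    confident = (var.var >= mu).astype(np.float64)
    if mode == "additive":
        cr = 1.0 + (1.0 - confident)
    elif mode == "replace":
        cr = np.ones_like(confident)
    else:
        raise ValueError("mode must be 'additive' or 'replace'")
    return MaskPair(gt_mask=confident, cr_mask=cr, mu=mu)
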