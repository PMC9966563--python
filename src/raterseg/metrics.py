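"""Segmentation evaluation: Dice, IoU, multithreshold soft scores, and the
variance-vs-error diagnostic.

Hard metrics follow the standard confusion-count definitions
DSC = 2TP / (2TP + FP + FN) and IoU = TP / (TP + FP + FN), computed
one-vs-rest per class.  The soft variants binarize a probability map and a
soft reference at several thresholds (default 0.1, 0.3, 0.5, 0.7, 0.9) and
average the scores across thresholds, which rewards predictions whose
probability levels track the reference's inter-rater agreement levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_THRESHOLDS: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9)


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred_mask: np.ndarray, ref_mask: np.ndarray, class_id: int) -> ConfusionCounts:
    """Exact pixel counts for the one-vs-rest binarization of ``class_id``."""
    pred_mask = np.asarray(pred_mask)
    ref_mask = np.asarray(ref_mask)
    if pred_mask.shape != ref_mask.shape:
        raise ValueError("pred and ref masks must share a shape")
    p = pred_mask == class_id
    r = ref_mask == class_id
    return ConfusionCounts(
        tp=int(np.sum(p & r)),
        fp=int(np.sum(p & ~r)),
        fn=int(np.sum(~p & r)),
        tn=int(np.sum(~p & ~r)),
    )


def dsc(counts: ConfusionCounts) -> float:
    """Dice similarity coefficient; an empty-vs-empty class scores 1."""
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        return 1.0
    return 2.0 * counts.tp / denom


def miou(counts: ConfusionCounts) -> float:
    """Intersection over union; an empty-vs-empty class scores 1."""
    denom = counts.tp + counts.fp + counts.fn
    if denom == 0:
        return 1.0
    return counts.tp / denom


@dataclass
class MetricsReport:
    """Per-class and aggregate overlap scores for one prediction."""

    per_class_dsc: dict[int, float]
    per_class_iou: dict[int, float]
    mean_dsc: float
    mean_iou: float
    soft_dsc: float | None = None
    soft_iou: float | None = None
    thresholds: tuple[float, ...] = field(default=DEFAULT_THRESHOLDS)

    def to_dict(self) -> dict:
        out = {
            "mean_dsc": self.mean_dsc,
            "mean_iou": self.mean_iou,
        }
        for c, v in self.per_class_dsc.items():
            out[f"dsc_class_{c}"] = v
        for c, v in self.per_class_iou.items():
            out[f"iou_class_{c}"] = v
        if self.soft_dsc is not None:
            out["soft_dsc"] = self.soft_dsc
            out["soft_iou"] = self.soft_iou
        return out


def evaluate_masks(
    pred_mask: np.ndarray,
    ref_mask: np.ndarray,
    num_classes: int,
    include_background: bool = False,
) -> MetricsReport:
    """Hard DSC/IoU per class and their means.

    The background class (index 0) is excluded from the means by default,
    matching the usual per-structure reporting convention.
    """
    start = 0 if include_background else 1
    classes = list(range(start, num_classes))
    if not classes:
        raise ValueError("no classes to evaluate")
    d, i = {}, {}
    for c in classes:
        counts = confusion(pred_mask, ref_mask, c)
        d[c] = dsc(counts)
        i[c] = miou(counts)
    return MetricsReport(
        per_class_dsc=d,
        per_class_iou=i,
        mean_dsc=float(np.mean(list(d.values()))),
        mean_iou=float(np.mean(list(i.values()))),
    )


def soft_multithreshold(
    pred,
    soft_ref,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    class_id: int = 1,
) -> tuple[float, float]:
    """Multithreshold soft DSC/IoU for one foreground class.

    Both the predicted probability map and the soft reference are binarized
    at each threshold; DSC and IoU are computed on each pair of binary masks
    and averaged over thresholds.
    """
    if len(thresholds) == 0:
        raise ValueError("thresholds must be non-empty")
    t = np.asarray(thresholds, dtype=float)
    if (t <= 0).any() or (t >= 1).any() or (np.diff(t) <= 0).any():
        raise ValueError("thresholds must be strictly ascending in (0, 1)")
    p = np.asarray(getattr(pred, "probs", pred))
    r = np.asarray(getattr(soft_ref, "probs", soft_ref))
    if p.ndim == 3:
        p = p[..., class_id]
    if r.ndim == 3:
        r = r[..., class_id]
    if p.shape != r.shape:
        raise ValueError("pred and reference shapes must match")
    ds, ious = [], []
    for thr in t:
        counts = confusion((p >= thr).astype(int), (r >= thr).astype(int), 1)
        ds.append(dsc(counts))
        ious.append(miou(counts))
    return float(np.mean(ds)), float(np.mean(ious))


def variance_error_profile(
    var: np.ndarray,
    per_pixel_loss: np.ndarray,
    error: np.ndarray,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Bin pixels by interclass variance; report mean loss and error rate
    per bin.

    Reproduces the diagnostic relating rater-disagreement variance to where
    the model's loss and mispredictions concentrate.  Bins are equal-width
    over [var.min(), var.max()]; empty bins are dropped.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    var = np.asarray(var).ravel()
    loss = np.asarray(per_pixel_loss).ravel()
    err = np.asarray(error).ravel().astype(float)
    if not (var.shape == loss.shape == err.shape):
        raise ValueError("var, loss and error must share a shape")
    edges = np.linspace(var.min(), var.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(var, edges) - 1, 0, n_bins - 1)
    df = pd.DataFrame({"bin": idx, "var": var, "loss": loss, "error": err})
    out = (
        df.groupby("bin")
        .agg(
            var_mean=("var", "mean"),
            loss_mean=("loss", "mean"),
            error_rate=("error", "mean"),
            n_pixels=("var", "size"),
        )
        .reset_index()
    )
    out["bin_left"] = edges[out["bin"].to_numpy()]
    out["bin_right"] = edges[out["bin"].to_numpy() + 1]
    return out
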