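"""Segmentation quality metrics: pixel accuracy, mean IoU, Dice, confusion.

With p_ij the number of pixels of true class i predicted as class j:

    PA       = trace / total
    IoU_i    = p_ii / (FP_i + FN_i + p_ii)         averaged over classes
    Dice_i   = 2 p_ii / (FP_i + 2 p_ii + FN_i)     averaged over classes

where FP_i / FN_i are the class's off-diagonal column / row sums.  The
identity Dice = 2·IoU / (1 + IoU) holds per class.  A class absent from
both the reference and the prediction contributes 1 to the averages
(vacuously perfect); absent from only one side, 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MetricsReport", "confusion_matrix", "compute_metrics", "evaluate_masks"]


@dataclass
class MetricsReport:
    confusion: np.ndarray
    pa: float
    mean_iou: float
    dice: float
    n_classes: int = 2
    param_count: int | None = None
    param_bytes: int | None = None

    def to_dict(self) -> dict:
        d = {
            "confusion": self.confusion.astype(int).tolist(),
            "pa": float(self.pa),
            "mean_iou": float(self.mean_iou),
            "dice": float(self.dice),
            "n_classes": int(self.n_classes),
        }
        if self.param_count is not None:
            d["param_count"] = int(self.param_count)
            d["param_bytes"] = int(self.param_bytes)
        return d


def confusion_matrix(true_mask, pred_mask, n_classes: int = 2) -> np.ndarray:
    """Count matrix with rows = true class, columns = predicted class."""
    t = np.asarray(true_mask).ravel()
    p = np.asarray(pred_mask).ravel()
    if t.shape != p.shape:
        raise ValueError(f"mask shapes differ: {np.shape(true_mask)} vs {np.shape(pred_mask)}")
    t = t.astype(np.int64)
    p = p.astype(np.int64)
    if t.size and (t.min() < 0 or t.max() >= n_classes or p.min() < 0 or p.max() >= n_classes):
        raise ValueError(f"mask values outside [0, {n_classes})")
    return np.bincount(t * n_classes + p, minlength=n_classes * n_classes).reshape(
        n_classes, n_classes)


def compute_metrics(confusion: np.ndarray) -> MetricsReport:
    """Pixel accuracy, mean IoU and mean Dice from a confusion matrix."""
    c = np.asarray(confusion, dtype=np.float64)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(c < 0):
        raise ValueError("confusion matrix entries must be non-negative")
    n = c.shape[0]
    total = c.sum()
    tp = np.diag(c)
    fp = c.sum(axis=0) - tp  # predicted i but true j != i
    fn = c.sum(axis=1) - tp  # true i but predicted j != i
    pa = float(tp.sum() / total) if total > 0 else 1.0

    ious = np.empty(n)
    dices = np.empty(n)
    for i in range(n):
        denom_iou = tp[i] + fp[i] + fn[i]
        if denom_iou == 0:
            # class absent from reference and prediction alike
            ious[i] = dices[i] = 1.0
        else:
            ious[i] = tp[i] / denom_iou
            dices[i] = 2 * tp[i] / (fp[i] + 2 * tp[i] + fn[i])
    return MetricsReport(confusion=np.asarray(confusion), pa=pa,
                         mean_iou=float(ious.mean()), dice=float(dices.mean()),
                         n_classes=n)


def evaluate_masks(true_masks, pred_masks, n_classes: int = 2) -> MetricsReport:
    """Aggregate confusion over a collection of mask pairs, then score."""
    c = np.zeros((n_classes, n_classes), dtype=np.int64)
    for t, p in zip(true_masks, pred_masks):
        c += confusion_matrix(t, p, n_classes)
    return compute_metrics(c)
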