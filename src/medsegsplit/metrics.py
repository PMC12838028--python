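"""Soft Dice training loss and IoU (Jaccard) evaluation.

Conventions:

* The Soft Dice loss uses the squared-denominator form
  ``1 - mean_c (2*sum(p*g) + s) / (sum(p^2) + sum(g^2) + s)`` with
  ``s = 1`` by default; sums run over batch and pixels, classes are
  averaged with equal weight and the background class participates in the
  loss.
* Reported IoU excludes the background class for the 5-class task (the
  mean runs over the four foreground structures) and reports the foreground
  class only for binary tasks; a flag re-includes background.
* Empty-union convention: a class absent from both prediction and ground
  truth scores IoU 1.0, keeping per-sample averages defined on small
  images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

TASK_NUM_CLASSES = {"multiclass5": 5, "binary_lesion": 2, "binary_polyp": 2}


def one_hot(mask: np.ndarray, num_classes: int) -> np.ndarray:
    """(..., H, W) integer labels -> (..., C, H, W) one-hot float array."""
    if mask.min() < 0 or mask.max() >= num_classes:
        raise ValueError("mask labels outside [0, num_classes)")
    eye = np.eye(num_classes, dtype=np.float64)
    oh = eye[mask]  # (..., H, W, C)
    return np.moveaxis(oh, -1, -3)


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def soft_dice_loss(probs: np.ndarray, onehot_gt: np.ndarray, smooth: float = 1.0) -> float:
    """Soft Dice loss on class probabilities; scalar in [0, 1]."""
    if probs.shape != onehot_gt.shape:
        raise ValueError(f"shape mismatch: {probs.shape} vs {onehot_gt.shape}")
    axes = (0, 2, 3) if probs.ndim == 4 else tuple(i for i in range(probs.ndim) if i != 0)
    inter = (probs * onehot_gt).sum(axis=axes)
    denom = (probs**2).sum(axis=axes) + (onehot_gt**2).sum(axis=axes)
    dice = (2.0 * inter + smooth) / (denom + smooth)
    return float(1.0 - dice.mean())


def soft_dice_loss_grad(
    probs: np.ndarray, onehot_gt: np.ndarray, smooth: float = 1.0
) -> np.ndarray:
    """Gradient of :func:`soft_dice_loss` w.r.t. the probabilities."""
    axes = (0, 2, 3)
    inter = (probs * onehot_gt).sum(axis=axes, keepdims=True)
    denom = (probs**2).sum(axis=axes, keepdims=True) + (onehot_gt**2).sum(
        axis=axes, keepdims=True
    )
    num_classes = probs.shape[1]
    d_dice = (2.0 * onehot_gt * (denom + smooth) - (2.0 * inter + smooth) * 2.0 * probs) / (
        denom + smooth
    ) ** 2
    return -d_dice / num_classes


def soft_dice_with_logits(
    logits: np.ndarray, onehot_gt: np.ndarray, smooth: float = 1.0
) -> tuple[float, np.ndarray]:
    """Softmax + Soft Dice; returns (loss, gradient w.r.t. logits)."""
    p = softmax(logits, axis=1)
    loss = soft_dice_loss(p, onehot_gt, smooth)
    gp = soft_dice_loss_grad(p, onehot_gt, smooth)
    gz = p * (gp - (p * gp).sum(axis=1, keepdims=True))
    return loss, gz.astype(logits.dtype)


@dataclass
class ConfusionCounts:
    """Per-class pixel overlap bookkeeping for one prediction/GT pair."""

    intersection: np.ndarray  # |pred=c AND gt=c|
    prediction: np.ndarray  # |pred=c|
    ground_truth: np.ndarray  # |gt=c|

    @property
    def union(self) -> np.ndarray:
        return self.prediction + self.ground_truth - self.intersection

    @classmethod
    def from_masks(
        cls, pred_mask: np.ndarray, gt_mask: np.ndarray, num_classes: int
    ) -> "ConfusionCounts":
        if pred_mask.shape != gt_mask.shape:
            raise ValueError("prediction and ground-truth masks must share a shape")
        classes = np.arange(num_classes)
        p = pred_mask.ravel()[:, None] == classes
        g = gt_mask.ravel()[:, None] == classes
        return cls(
            intersection=(p & g).sum(axis=0),
            prediction=p.sum(axis=0),
            ground_truth=g.sum(axis=0),
        )


def iou_per_class(pred_mask: np.ndarray, gt_mask: np.ndarray, class_id: int) -> float:
    """Jaccard index for one class; 1.0 if the class is absent from both."""
    if pred_mask.shape != gt_mask.shape:
        raise ValueError("prediction and ground-truth masks must share a shape")
    p = pred_mask == class_id
    g = gt_mask == class_id
    union = np.logical_or(p, g).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(p, g).sum() / union)


def _sample_iou(pred, gt, task_kind: str, include_background: bool) -> float:
    if task_kind == "multiclass5":
        classes = range(0, 5) if include_background else range(1, 5)
    elif task_kind in ("binary_lesion", "binary_polyp"):
        classes = range(0, 2) if include_background else (1,)
    else:
        raise ValueError(f"unknown task kind: {task_kind!r}")
    return float(np.mean([iou_per_class(pred, gt, c) for c in classes]))


def average_iou(
    pairs,
    task_kind: str,
    include_background: bool = False,
) -> float:
    """Mean per-sample IoU over (prediction, ground-truth) mask pairs.

    For the 5-class task each sample's score is the mean IoU over the four
    foreground structures; for binary tasks it is the foreground-class IoU.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("average_iou needs at least one mask pair")
    return float(
        np.mean([_sample_iou(p, g, task_kind, include_background) for p, g in pairs])
    )
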