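"""Classification metrics and explanation-quality (IoU / mIoU) scoring.

Classification side: per-class binary confusion at a threshold, accuracy,
precision, recall, F1, one-vs-rest AUC, and unweighted macro averages.
Classes for which a metric is undefined (no positives, single label value)
are reported as NaN and excluded from the macro with a warning.

Explanation side: class-activation maps are binarized at a cutoff on the
normalized display (default 0.5, always reported alongside the score) and
compared with expert ROI masks by intersection-over-union; the mean over
classes is the mIoU. When both masks are empty the IoU is defined as 1.0
(a correctly absent finding) but such classes are excluded from aggregates
by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "ClassMetrics",
    "IoUReport",
    "classification_metrics",
    "macro_auc",
    "binarize_cam",
    "compute_iou",
    "compute_miou",
]


@dataclass
class ClassMetrics:
    per_class: pd.DataFrame  # rows: classes; cols: tp fp fn tn accuracy precision recall f1 auc
    macro: dict[str, float]
    threshold: float

    def __repr__(self) -> str:
        m = ", ".join(f"{k}={v:.3f}" for k, v in self.macro.items())
        return f"ClassMetrics(n_classes={len(self.per_class)}, threshold={self.threshold}, macro: {m})"


@dataclass
class IoUReport:
    per_class_iou: np.ndarray
    miou: float
    threshold: float
    included: np.ndarray  # bool mask of classes entering the mean

    @property
    def n_classes(self) -> int:
        return len(self.per_class_iou)


def macro_auc(probs: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Unweighted mean one-vs-rest AUC; per-class NaN where undefined."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    per_class = np.full(labels.shape[1], np.nan)
    for k in range(labels.shape[1]):
        yk = labels[:, k]
        if yk.min() == yk.max():
            warnings.warn(f"AUC undefined for class {k}: only one label value present",
                          stacklevel=2)
            continue
        per_class[k] = roc_auc_score(yk, probs[:, k])
    if np.all(np.isnan(per_class)):
        return float("nan"), per_class
    return float(np.nanmean(per_class)), per_class


def classification_metrics(probs: np.ndarray, labels: np.ndarray,
                           threshold: float = 0.5) -> ClassMetrics:
    """Per-class and macro classification metrics at a decision threshold.

    AUC is computed from the continuous probabilities (rank statistic); all
    other metrics from the binary confusion at the threshold.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    if probs.shape != labels.shape:
        raise ValueError(f"probs shape {probs.shape} != labels shape {labels.shape}")
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")

    pred = probs >= threshold
    rows = []
    _, auc_per_class = macro_auc(probs, labels)
    for k in range(labels.shape[1]):
        y, p = labels[:, k].astype(bool), pred[:, k]
        tp = int(np.sum(y & p)); fp = int(np.sum(~y & p))
        fn = int(np.sum(y & ~p)); tn = int(np.sum(~y & ~p))
        n = tp + fp + fn + tn
        # zero-division convention: no positive predictions -> precision 0
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else np.nan
        if tp + fn == 0:
            warnings.warn(f"recall undefined for class {k}: no positive labels",
                          stacklevel=2)
        denom = precision + recall
        f1 = 2 * precision * recall / denom if denom else 0.0
        rows.append({"tp": tp, "fp": fp, "fn": fn, "tn": tn,
                     "accuracy": (tp + tn) / n,
                     "precision": precision, "recall": recall, "f1": f1,
                     "auc": auc_per_class[k]})
    per_class = pd.DataFrame(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        macro = {m: float(np.nanmean(per_class[m].to_numpy(dtype=float)))
                 for m in ("accuracy", "precision", "recall", "f1", "auc")}
    return ClassMetrics(per_class=per_class, macro=macro, threshold=threshold)


def binarize_cam(display: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binary saliency mask: pixel set iff normalized display >= threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"CAM binarization threshold must be in (0, 1), got {threshold}")
    return np.asarray(display) >= threshold


def compute_iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks; both-empty gives 1.0."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.sum(a | b)
    if union == 0:
        return 1.0
    return float(np.sum(a & b) / union)


def compute_miou(cam_masks: np.ndarray, roi_masks: np.ndarray,
                 threshold: float = 0.5, include_empty: bool = False) -> IoUReport:
    """Per-class IoU between saliency and expert ROI masks, and their mean.

    ``cam_masks`` and ``roi_masks`` are (n_classes, H, W) boolean stacks.
    Classes whose ROI mask is empty are excluded from the mean by default
    (with a warning), since no expert finding exists to overlap.
    """
    cam_masks = np.asarray(cam_masks, dtype=bool)
    roi_masks = np.asarray(roi_masks, dtype=bool)
    if cam_masks.shape != roi_masks.shape:
        raise ValueError(f"mask stacks differ: {cam_masks.shape} vs {roi_masks.shape}")
    if cam_masks.ndim != 3 or cam_masks.shape[0] == 0:
        raise ValueError(f"expected nonempty (n_classes, H, W) stacks, got {cam_masks.shape}")

    n = cam_masks.shape[0]
    ious = np.array([compute_iou(cam_masks[k], roi_masks[k]) for k in range(n)])
    included = np.ones(n, dtype=bool)
    if not include_empty:
        empty = ~roi_masks.any(axis=(1, 2))
        if empty.any():
            warnings.warn(
                f"classes {np.flatnonzero(empty).tolist()} have no ROI and are "
                "excluded from mIoU", stacklevel=2)
        included = ~empty
    if not included.any():
        return IoUReport(per_class_iou=ious, miou=float("nan"),
                         threshold=threshold, included=included)
    return IoUReport(per_class_iou=ious, miou=float(np.mean(ious[included])),
                     threshold=threshold, included=included)
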