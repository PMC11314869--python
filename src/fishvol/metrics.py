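"""Detection and regression evaluation metrics.

Detection metrics follow the standard instance-segmentation benchmark
definitions: predictions are greedily matched to ground-truth instances in
descending confidence order, a match requiring mask IoU at or above a
threshold; precision = TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic
mean, and AP the area under the precision-recall curve with the precision
envelope made monotonically non-increasing (the continuous form, not
11-point interpolation).  mAP averages AP over classes; mAP@0.5:0.95
additionally averages IoU thresholds 0.50, 0.55, ..., 0.95.

Regression diagnostics for predicted-vs-true mass: R^2, RMSE, and NRMSE
(RMSE divided by the mean true value, making errors comparable across size
classes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "DetectionCounts",
    "RegressionReport",
    "mask_iou",
    "detection_counts",
    "precision_recall_f1",
    "average_precision",
    "mean_average_precision",
    "match_detections",
    "regression_metrics",
]


@dataclass(frozen=True)
class DetectionCounts:
    TP: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class RegressionReport:
    r2: float
    rmse: float
    nrmse: float
    n: int


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def match_detections(pred_masks: Sequence[np.ndarray],
                     confidences: Sequence[float],
                     truth_masks: Sequence[np.ndarray],
                     iou_threshold: float = 0.5) -> list[bool]:
    """Greedy confidence-ordered matching; returns is_TP per prediction.

    Each truth instance can absorb at most one prediction; a prediction is
    a true positive when its best IoU against a still-unmatched truth
    reaches the threshold.
    """
    if not 0 < iou_threshold < 1:
        raise ValueError("iou_threshold must lie in (0, 1)")
    order = np.argsort(-np.asarray(confidences, dtype=float), kind="stable")
    taken = [False] * len(truth_masks)
    is_tp = [False] * len(pred_masks)
    for idx in order:
        best_iou, best_j = 0.0, -1
        for j, tm in enumerate(truth_masks):
            if taken[j]:
                continue
            iou = mask_iou(pred_masks[idx], tm)
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0 and best_iou >= iou_threshold:
            taken[best_j] = True
            is_tp[idx] = True
    return is_tp


def detection_counts(pred_masks: Sequence[np.ndarray],
                     truth_masks: Sequence[np.ndarray],
                     iou_threshold: float = 0.5,
                     confidences: Sequence[float] | None = None) -> DetectionCounts:
    """TP/FP/FN totals from greedy matching (uniform confidence by default)."""
    if confidences is None:
        confidences = [1.0] * len(pred_masks)
    is_tp = match_detections(pred_masks, confidences, truth_masks, iou_threshold)
    tp = sum(is_tp)
    return DetectionCounts(TP=tp, FP=len(pred_masks) - tp, FN=len(truth_masks) - tp)


def precision_recall_f1(c: DetectionCounts) -> tuple[float, float, float]:
    """P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R); 0/0 -> 0."""
    p = c.TP / (c.TP + c.FP) if c.TP + c.FP > 0 else 0.0
    r = c.TP / (c.TP + c.FN) if c.TP + c.FN > 0 else 0.0
    f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return p, r, f1


def average_precision(ranked: Sequence[tuple[float, bool]], n_truth: int) -> float:
    """Area under the PR curve with the monotone precision envelope.

    ``ranked`` holds (confidence, is_TP) per detection; detections are
    sorted by descending confidence, cumulative precision/recall computed,
    precision replaced by its running maximum from the right, and the
    recall axis integrated exactly.
    """
    if n_truth < 1:
        raise ValueError("AP undefined with no ground-truth instances")
    if not ranked:
        return 0.0
    order = np.argsort(-np.asarray([c for c, _ in ranked], dtype=float), kind="stable")
    tps = np.asarray([bool(ranked[i][1]) for i in order])
    cum_tp = np.cumsum(tps)
    cum_fp = np.cumsum(~tps)
    recall = cum_tp / n_truth
    precision = cum_tp / (cum_tp + cum_fp)
    # envelope: precision at recall r is the max precision at recall >= r
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    prev_r = 0.0
    ap = 0.0
    for r, p in zip(recall, envelope):
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


def mean_average_precision(per_class_ap: dict[str, float]) -> float:
    """Unweighted mean of per-class average precisions."""
    if not per_class_ap:
        raise ValueError("no classes")
    return float(np.mean(list(per_class_ap.values())))


def regression_metrics(pred: Sequence[float], true: Sequence[float]) -> RegressionReport:
    """R^2, RMSE, and NRMSE (= RMSE / mean true) of predictions."""
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.shape != true.shape or pred.size < 2:
        raise ValueError("pred and true must be equal-length with n >= 2")
    resid = pred - true
    rmse = float(np.sqrt(np.mean(resid**2)))
    mean_true = float(true.mean())
    if mean_true == 0:
        raise ValueError("NRMSE undefined: mean of true values is zero")
    ss_tot = float(np.sum((true - mean_true) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined: true values are constant")
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return RegressionReport(r2=r2, rmse=rmse, nrmse=rmse / mean_true, n=pred.size)
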