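"""Pixelwise segmentation metrics over confusion counts.

Foreground (WBC, mask value 1) is the positive class.  Two accuracy-style
quantities are reported side by side: ``mean_metric`` is TP/(TP+TN),
implemented verbatim from the source definition, while ``pixel_accuracy``
is the standard (TP+TN)/total, used as the headline "mean accuracy"
aggregate.  Also provided: IoU (Jaccard), Dice similarity coefficient,
boundary F1 within a pixel tolerance, precision, recall, specificity, F1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_counts",
    "mean_metric",
    "pixel_accuracy",
    "iou",
    "dsc",
    "boundary_f1",
    "precision_recall_specificity_f1",
    "binarize",
    "evaluate_dataset",
    "DEFAULT_BOUNDARY_TOLERANCE",
]

DEFAULT_BOUNDARY_TOLERANCE = 2.0  # pixels at 224x224; scale with the diagonal

METRIC_COLUMNS = (
    "mean_metric",
    "pixel_accuracy",
    "iou",
    "dsc",
    "boundary_f1",
    "precision",
    "recall",
    "specificity",
    "f1",
)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _as_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.all(np.isin(arr, [0, 1])):
        raise ValueError(f"{name} must be a strict 0/1 array")
    return arr.astype(bool)


def confusion_counts(pred_mask: np.ndarray, gt_mask: np.ndarray) -> ConfusionCounts:
    """Exact pixel tallies; foreground = 1 is the positive class."""
    pred = _as_binary(pred_mask, "pred_mask")
    gt = _as_binary(gt_mask, "gt_mask")
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    return ConfusionCounts(
        tp=int(np.sum(pred & gt)),
        fp=int(np.sum(pred & ~gt)),
        fn=int(np.sum(~pred & gt)),
        tn=int(np.sum(~pred & ~gt)),
    )


def mean_metric(counts: ConfusionCounts) -> float:
    """TP / (TP + TN), as printed; NaN when tp + tn = 0."""
    den = counts.tp + counts.tn
    if den == 0:
        return math.nan
    return counts.tp / den


def pixel_accuracy(counts: ConfusionCounts) -> float:
    """(TP + TN) / total — the standard overall accuracy."""
    if counts.total == 0:
        raise ValueError("cannot compute accuracy of empty counts")
    return (counts.tp + counts.tn) / counts.total


def iou(counts: ConfusionCounts) -> float:
    """TP / (TP + FP + FN); both masks empty -> 1 by convention."""
    den = counts.tp + counts.fp + counts.fn
    if den == 0:
        return 1.0
    return counts.tp / den


def dsc(pred_mask: np.ndarray, gt_mask: np.ndarray) -> float:
    """Dice similarity 2|A∩B|/(|A|+|B|); both masks empty -> 1."""
    c = confusion_counts(pred_mask, gt_mask)
    den = 2 * c.tp + c.fp + c.fn
    if den == 0:
        return 1.0
    return 2 * c.tp / den


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels 4-adjacent to background (or the image border)."""
    structure = ndimage.generate_binary_structure(2, 1)  # 4-connectivity
    eroded = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~eroded


def boundary_f1(
    pred_mask: np.ndarray,
    gt_mask: np.ndarray,
    tolerance: float = DEFAULT_BOUNDARY_TOLERANCE,
) -> float:
    """F1 of boundary-pixel matching within a Euclidean pixel tolerance."""
    if tolerance < 0:
        raise ValueError("tolerance must be nonnegative")
    pred = _as_binary(pred_mask, "pred_mask")
    gt = _as_binary(gt_mask, "gt_mask")
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    pb = _boundary(pred)
    gb = _boundary(gt)
    if not pb.any() and not gb.any():
        return 1.0
    if not pb.any() or not gb.any():
        return 0.0
    dist_to_gt = ndimage.distance_transform_edt(~gb)
    dist_to_pred = ndimage.distance_transform_edt(~pb)
    precision = float(np.mean(dist_to_gt[pb] <= tolerance))
    recall = float(np.mean(dist_to_pred[gb] <= tolerance))
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def precision_recall_specificity_f1(
    counts: ConfusionCounts,
) -> tuple[float, float, float, float]:
    """(precision, recall, specificity, F1); NaN flags a zero denominator."""
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else math.nan
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else math.nan
    specificity = (
        counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else math.nan
    )
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f1 = math.nan
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, specificity, f1


def binarize(prob_map: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map into a strict 0/1 mask."""
    return (np.asarray(prob_map) > threshold).astype(np.uint8)


@dataclass
class MetricReport:
    """Per-sample metric rows plus unweighted dataset aggregates (unit scale)."""

    per_sample: pd.DataFrame
    aggregates: dict[str, float]

    def aggregates_percent(self, decimals: int = 2) -> dict[str, float]:
        """Ratio metrics as percentages (2 decimals); boundary F1 stays 0-1."""
        out = {}
        for k, v in self.aggregates.items():
            if k == "boundary_f1":
                out[k] = round(v, decimals)
            else:
                out[k] = round(100.0 * v, decimals)
        return out


def _sample_row(pred: np.ndarray, gt: np.ndarray, tolerance: float) -> dict:
    c = confusion_counts(pred, gt)
    p, r, s, f1 = precision_recall_specificity_f1(c)
    return {
        "mean_metric": mean_metric(c),
        "pixel_accuracy": pixel_accuracy(c),
        "iou": iou(c),
        "dsc": dsc(pred, gt),
        "boundary_f1": boundary_f1(pred, gt, tolerance),
        "precision": p,
        "recall": r,
        "specificity": s,
        "f1": f1,
    }


def evaluate_dataset(
    pairs: Iterable[tuple[np.ndarray, np.ndarray]],
    tolerance: float = DEFAULT_BOUNDARY_TOLERANCE,
    sample_ids: Sequence[str] | None = None,
) -> MetricReport:
    """Per-sample metrics and their unweighted means over the collection.

    NaN entries (undefined denominators) are excluded from the aggregates
    sample-by-sample, mirroring how missing values are flagged per row.
    """
    rows = []
    for i, (pred, gt) in enumerate(pairs):
        row = _sample_row(np.asarray(pred), np.asarray(gt), tolerance)
        row["sample_id"] = (
            sample_ids[i] if sample_ids is not None else f"sample_{i:05d}"
        )
        rows.append(row)
    if not rows:
        raise ValueError("cannot evaluate an empty collection")
    df = pd.DataFrame(rows).set_index("sample_id")
    aggregates = {col: float(df[col].mean(skipna=True)) for col in METRIC_COLUMNS}
    return MetricReport(per_sample=df, aggregates=aggregates)
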