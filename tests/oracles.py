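"""Independent brute-force oracles used only by the tests.

Everything here is written as plain Python loops over pixels, deliberately
avoiding the vectorized code paths of the package, so the two routes can be
compared against each other.
"""

from __future__ import annotations

import math

import numpy as np


def brute_confusion(pred, gt):
    tp = fp = fn = tn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            p, g = int(pred[i, j]), int(gt[i, j])
            if p == 1 and g == 1:
                tp += 1
            elif p == 1 and g == 0:
                fp += 1
            elif p == 0 and g == 1:
                fn += 1
            else:
                tn += 1
    return tp, fp, fn, tn


def brute_mean_metric(pred, gt):
    tp, fp, fn, tn = brute_confusion(pred, gt)
    return tp / (tp + tn) if tp + tn else math.nan


def brute_pixel_accuracy(pred, gt):
    tp, fp, fn, tn = brute_confusion(pred, gt)
    return (tp + tn) / (tp + fp + fn + tn)


def brute_iou(pred, gt):
    inter = union = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            if pred[i, j] and gt[i, j]:
                inter += 1
            if pred[i, j] or gt[i, j]:
                union += 1
    return inter / union if union else 1.0


def brute_dsc(pred, gt):
    inter = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            if pred[i, j] and gt[i, j]:
                inter += 1
    size = int(pred.sum()) + int(gt.sum())
    return 2 * inter / size if size else 1.0


def brute_prf(pred, gt):
    tp, fp, fn, tn = brute_confusion(pred, gt)
    precision = tp / (tp + fp) if tp + fp else math.nan
    recall = tp / (tp + fn) if tp + fn else math.nan
    specificity = tn / (tn + fp) if tn + fp else math.nan
    if (
        math.isnan(precision)
        or math.isnan(recall)
        or precision + recall == 0
    ):
        f1 = math.nan
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, specificity, f1


def brute_boundary_pixels(mask):
    """Foreground pixels with a 4-neighbour background pixel or on the border."""
    h, w = mask.shape
    out = []
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            edge = False
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                if ni < 0 or ni >= h or nj < 0 or nj >= w or not mask[ni, nj]:
                    edge = True
                    break
            if edge:
                out.append((i, j))
    return out


def brute_boundary_f1(pred, gt, tolerance):
    pb = brute_boundary_pixels(pred)
    gb = brute_boundary_pixels(gt)
    if not pb and not gb:
        return 1.0
    if not pb or not gb:
        return 0.0

    def frac_matched(src, ref):
        hit = 0
        for (i, j) in src:
            best = min(math.hypot(i - a, j - b) for (a, b) in ref)
            if best <= tolerance:
                hit += 1
        return hit / len(src)

    precision = frac_matched(pb, gb)
    recall = frac_matched(gb, pb)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def soft_dice_loss(pred, target, smooth=1.0):
    """Independent soft-Dice loss: 1 - (2 Σpt + 2s') / (Σp + Σt + 2s').

    With s' = smooth the denominator matches the Tversky denominator at
    alpha = beta = 0.5: Σpt + 0.5 Σp(1-t) + 0.5 Σ(1-p)t = (Σp + Σt)/2.
    """
    inter = float(np.sum(np.asarray(pred) * np.asarray(target)))
    total = float(np.sum(pred) + np.sum(target))
    return 1.0 - (2.0 * inter + 2.0 * smooth) / (total + 2.0 * smooth)


def point_in_ellipse(i, j, center, semi_major, eccentricity, rotation):
    semi_minor = semi_major * math.sqrt(max(1.0 - eccentricity**2, 0.0))
    dr, dc = i - center[0], j - center[1]
    u = dr * math.cos(rotation) + dc * math.sin(rotation)
    v = -dr * math.sin(rotation) + dc * math.cos(rotation)
    return (u / semi_major) ** 2 + (v / semi_minor) ** 2 <= 1.0
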