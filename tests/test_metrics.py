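"""Pixelwise metrics against hand arithmetic and brute-force enumeration."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from wbcseg.metrics import (
    ConfusionCounts,
    boundary_f1,
    confusion_counts,
    dsc,
    evaluate_dataset,
    iou,
    mean_metric,
    pixel_accuracy,
    precision_recall_specificity_f1,
)

from conftest import random_mask_pairs
from oracles import (
    brute_boundary_f1,
    brute_confusion,
    brute_dsc,
    brute_iou,
    brute_prf,
)


class TestConfusionCounts:
    def test_identical_masks_have_no_errors(self):
        m = (np.random.default_rng(0).random((8, 8)) > 0.5).astype(np.uint8)
        c = confusion_counts(m, m)
        assert c.fp == 0 and c.fn == 0

    def test_complement_masks_have_no_agreements(self):
        m = (np.random.default_rng(1).random((8, 8)) > 0.5).astype(np.uint8)
        c = confusion_counts(1 - m, m)
        assert c.tp == 0 and c.tn == 0

    def test_two_by_two_enumeration(self):
        pred = np.array([[1, 1], [0, 0]])
        gt = np.array([[1, 0], [0, 0]])
        c = confusion_counts(pred, gt)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 0, 2)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts(np.array([[2, 0]]), np.array([[1, 0]]))


class TestScalarMetrics:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            (ConfusionCounts(5, 0, 0, 5), 0.5),  # tp = tn
            (ConfusionCounts(3, 2, 1, 0), 1.0),  # tn = 0
            (ConfusionCounts(50, 0, 0, 25), 2 / 3),
        ],
    )
    def test_mean_metric_as_printed(self, counts, expected):
        assert mean_metric(counts) == pytest.approx(expected)

    def test_mean_metric_undefined_is_nan(self):
        assert math.isnan(mean_metric(ConfusionCounts(0, 3, 2, 0)))

    @pytest.mark.parametrize(
        "counts, expected",
        [
            (ConfusionCounts(4, 0, 0, 12), 1.0),
            (ConfusionCounts(0, 8, 8, 0), 0.0),
            (ConfusionCounts(1, 1, 0, 2), 0.75),
        ],
    )
    def test_pixel_accuracy(self, counts, expected):
        assert pixel_accuracy(counts) == pytest.approx(expected)

    def test_iou_arithmetic(self):
        assert iou(ConfusionCounts(50, 10, 15, 0)) == pytest.approx(50 / 75)
        assert iou(ConfusionCounts(7, 0, 0, 3)) == 1.0
        assert iou(ConfusionCounts(0, 4, 4, 2)) == 0.0
        assert iou(ConfusionCounts(0, 0, 0, 9)) == 1.0  # both empty

    def test_precision_recall_specificity_f1_arithmetic(self):
        p, r, s, f1 = precision_recall_specificity_f1(ConfusionCounts(1, 1, 0, 2))
        assert (p, r) == (0.5, 1.0)
        assert s == pytest.approx(2 / 3)
        assert f1 == pytest.approx(2 / 3)


class TestDice:
    def test_perfect_and_counts_case(self):
        m = np.ones((4, 4), dtype=np.uint8)
        assert dsc(m, m) == 1.0
        # counts (tp, fp, fn) = (50, 10, 15): dsc = 100/125
        pred = np.zeros(75, dtype=np.uint8)
        gt = np.zeros(75, dtype=np.uint8)
        pred[:60] = 1  # 50 tp + 10 fp
        gt[:50] = 1
        gt[60:75] = 1  # 15 fn
        assert dsc(pred.reshape(5, 15), gt.reshape(5, 15)) == pytest.approx(0.8)

    def test_dsc_iou_identity_on_random_pairs(self):
        for pred, gt in random_mask_pairs(100, 12, seed=3):
            j = iou(confusion_counts(pred, gt))
            d = dsc(pred, gt)
            assert d == pytest.approx(2 * j / (1 + j), abs=1e-12)
            assert d >= j
            if d == pytest.approx(j, abs=1e-12):
                assert j in (0.0, 1.0)

    def test_f1_equals_dsc_from_same_counts(self):
        for pred, gt in random_mask_pairs(50, 10, seed=4):
            c = confusion_counts(pred, gt)
            if c.tp + c.fp == 0 or c.tp + c.fn == 0:
                continue
            _, _, _, f1 = precision_recall_specificity_f1(c)
            if not math.isnan(f1):
                assert f1 == pytest.approx(dsc(pred, gt), abs=1e-12)


class TestBoundaryF1:
    def test_identical_masks_score_one(self):
        m = np.zeros((16, 16), dtype=np.uint8)
        m[4:10, 5:12] = 1
        assert boundary_f1(m, m, tolerance=0) == 1.0

    def test_empty_prediction_scores_zero(self):
        gt = np.zeros((16, 16), dtype=np.uint8)
        gt[4:8, 4:8] = 1
        assert boundary_f1(np.zeros_like(gt), gt, 2.0) == 0.0

    def test_one_pixel_shift_within_tolerance_two(self):
        gt = np.zeros((32, 32), dtype=np.uint8)
        gt[11:21, 11:21] = 1
        pred = np.zeros_like(gt)
        pred[11:21, 12:22] = 1  # shifted one pixel right
        assert boundary_f1(pred, gt, tolerance=2.0) == 1.0

    def test_matches_brute_force_on_small_pairs(self):
        for pred, gt in random_mask_pairs(20, 8, seed=5):
            assert boundary_f1(pred, gt, 1.5) == pytest.approx(
                brute_boundary_f1(pred, gt, 1.5), abs=1e-12
            )


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    pred=arrays(np.uint8, (9, 9), elements=st.integers(0, 1)),
    gt=arrays(np.uint8, (9, 9), elements=st.integers(0, 1)),
)
def test_metrics_agree_with_enumeration_oracle(pred, gt):
    tp, fp, fn, tn = brute_confusion(pred, gt)
    c = confusion_counts(pred, gt)
    assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)
    assert iou(c) == pytest.approx(brute_iou(pred, gt), abs=1e-12)
    assert dsc(pred, gt) == pytest.approx(brute_dsc(pred, gt), abs=1e-12)
    for mine, ref in zip(precision_recall_specificity_f1(c), brute_prf(pred, gt)):
        if math.isnan(ref):
            assert math.isnan(mine)
        else:
            assert mine == pytest.approx(ref, abs=1e-12)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    pred=arrays(np.uint8, (8, 8), elements=st.integers(0, 1)),
    gt=arrays(np.uint8, (8, 8), elements=st.integers(0, 1)),
)
def test_metrics_invariant_under_joint_horizontal_flip(pred, gt):
    c = confusion_counts(pred, gt)
    cf = confusion_counts(pred[:, ::-1], gt[:, ::-1])
    assert (c.tp, c.fp, c.fn, c.tn) == (cf.tp, cf.fp, cf.fn, cf.tn)
    assert boundary_f1(pred, gt, 2.0) == pytest.approx(
        boundary_f1(pred[:, ::-1], gt[:, ::-1], 2.0), abs=1e-12
    )


class TestEvaluateDataset:
    def test_perfect_pair_gives_all_hundreds(self):
        m = np.zeros((16, 16), dtype=np.uint8)
        m[3:9, 3:9] = 1
        report = evaluate_dataset([(m, m)])
        pct = report.aggregates_percent()
        for key in ("pixel_accuracy", "iou", "dsc", "precision", "recall"):
            assert pct[key] == 100.0
        assert pct["boundary_f1"] == 1.0

    def test_duplicated_pair_equals_single(self):
        pred, gt = random_mask_pairs(3, 10, seed=6)[2]
        single = evaluate_dataset([(pred, gt)])
        double = evaluate_dataset([(pred, gt), (pred, gt)])
        for k, v in single.aggregates.items():
            if math.isnan(v):
                assert math.isnan(double.aggregates[k])
            else:
                assert double.aggregates[k] == pytest.approx(v, abs=1e-12)

    def test_aggregate_is_unweighted_mean(self):
        m = np.zeros((8, 8), dtype=np.uint8)
        m[2:6, 2:6] = 1
        half = np.zeros_like(m)
        half[2:6, 2:4] = 1  # IoU vs m = 8/16 = 0.5
        report = evaluate_dataset([(m, m), (half, m)])
        assert report.aggregates["iou"] == pytest.approx(0.75)

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            evaluate_dataset([])
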