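"""IoU matching, detection metrics, regression metrics, full reports."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crownscope.crown_metrics import extract_crown_instances
from crownscope.errors import DimensionError, UndefinedMetricError
from crownscope.evaluation import (
    DetectionCounts,
    RegressionPairs,
    compute_iou,
    detection_metrics,
    evaluate_run,
    match_crowns,
    regression_metrics,
)


def instances_from(mask):
    return extract_crown_instances(np.where(mask, 255, 0).astype(np.uint8),
                                   1.0, min_crown_pixels=1, fit_ellipses=False)


def exhaustive_match(predicted, reference, threshold):
    """Best one-to-one assignment: max pair count, then max total IoU."""
    from crownscope.evaluation import _instance_iou

    ious = {}
    for i, p in enumerate(predicted):
        for j, r in enumerate(reference):
            v = _instance_iou(p, r)
            if v > threshold:
                ious[(i, j)] = v
    best = (0, 0.0)
    npred, nref = len(predicted), len(reference)
    for k in range(min(npred, nref), -1, -1):
        for ps in itertools.combinations(range(npred), k):
            for rs in itertools.permutations(range(nref), k):
                pairs = list(zip(ps, rs))
                if all(pair in ious for pair in pairs):
                    tot = sum(ious[pair] for pair in pairs)
                    if (k, tot) > best:
                        best = (k, tot)
        if best[0] == k and best[0] > 0:
            break
    return best[0]


class TestComputeIou:
    def test_identity_is_100(self):
        a = np.zeros((6, 6)); a[1:4, 1:4] = 1
        assert compute_iou(a, a) == 100.0

    def test_disjoint_is_0(self):
        a = np.zeros((6, 6)); b = np.zeros((6, 6))
        a[0, 0] = 1; b[5, 5] = 1
        assert compute_iou(a, b) == 0.0

    def test_shifted_square(self):
        a = np.zeros((10, 10)); b = np.zeros((10, 10))
        a[2:4, 2:4] = 1; b[2:4, 3:5] = 1
        assert compute_iou(a, b) == pytest.approx(100 * 2 / 6)

    def test_both_empty_undefined(self):
        with pytest.raises(UndefinedMetricError):
            compute_iou(np.zeros((3, 3)), np.zeros((3, 3)))

    def test_shape_mismatch(self):
        with pytest.raises(DimensionError):
            compute_iou(np.zeros((3, 3)), np.zeros((4, 4)))


class TestMatching:
    def test_perfect_match(self):
        mask = np.zeros((30, 30), bool); mask[5:15, 5:15] = True
        inst = instances_from(mask)
        counts = match_crowns(inst, instances_from(mask))
        assert (counts.tp, counts.fp, counts.fn) == (1, 0, 0)
        assert counts.matched_ious == [100.0]

    def test_below_threshold_not_accepted(self):
        a = np.zeros((30, 30), bool); b = np.zeros((30, 30), bool)
        a[0:10, 0:10] = True
        b[0:10, 6:16] = True  # IoU = 4/16 x 100 = 25% < 50%
        counts = match_crowns(instances_from(a), instances_from(b))
        assert (counts.tp, counts.fp, counts.fn) == (0, 1, 1)

    def test_exactly_50_percent_rejected(self):
        a = np.zeros((20, 20), bool); b = np.zeros((20, 20), bool)
        a[0:4, 0:4] = True       # 16 px
        b[0:4, 0:8] = True       # 32 px, intersection 16, union 32 -> 50.0%
        counts = match_crowns(instances_from(a), instances_from(b), 50.0)
        assert counts.tp == 0

    def test_one_to_one_constraint(self):
        # two predictions over one reference, both above a low threshold
        pred = np.zeros((30, 30), bool)
        pred[5:15, 5:10] = True
        pred[5:15, 11:16] = True
        ref = np.zeros((30, 30), bool)
        ref[5:15, 5:16] = True
        counts = match_crowns(instances_from(pred), instances_from(ref),
                              iou_threshold=30.0)
        assert (counts.tp, counts.fp, counts.fn) == (1, 1, 0)

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_exhaustive_assignment(self, seed):
        rng = np.random.default_rng(seed)
        def blobs(n):
            m = np.zeros((40, 40), bool)
            for _ in range(n):
                r, c = rng.integers(2, 30, 2)
                h, w = rng.integers(4, 10, 2)
                m[r:r + h, c:c + w] = True
            return instances_from(m)
        pred = blobs(rng.integers(1, 5))
        ref = blobs(rng.integers(1, 5))
        counts = match_crowns(pred, ref, 50.0)
        assert counts.tp == exhaustive_match(pred, ref, 50.0)

    def test_empty_lists_allowed(self):
        counts = match_crowns([], [])
        assert (counts.tp, counts.fp, counts.fn) == (0, 0, 0)

    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_count_conservation(self, tp, extra_p, extra_r):
        counts = DetectionCounts(tp=tp, fp=extra_p, fn=extra_r,
                                 n_reference=tp + extra_r,
                                 n_predicted=tp + extra_p)
        assert counts.tp + counts.fp == counts.n_predicted
        assert counts.tp + counts.fn == counts.n_reference


class TestDetectionMetrics:
    def test_printed_count_example(self):
        from crownscope.evaluation import round_half_up

        m = detection_metrics(DetectionCounts(tp=189, fp=24, fn=46))
        assert round_half_up(m.precision) == 88.73
        assert round_half_up(m.recall) == 80.43
        assert round_half_up(m.f1) == 84.38

    def test_no_predictions_precision_undefined_recall_zero(self):
        with pytest.warns(UserWarning, match="precision undefined"):
            m = detection_metrics(DetectionCounts(tp=0, fp=0, fn=5))
        assert math.isnan(m.precision)
        assert m.recall == 0.0
        assert math.isnan(m.f1)

    def test_no_reference_recall_undefined(self):
        with pytest.warns(UserWarning, match="recall undefined"):
            m = detection_metrics(DetectionCounts(tp=0, fp=3, fn=0))
        assert math.isnan(m.recall)

    @given(st.integers(1, 500), st.integers(0, 500), st.integers(0, 500))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_f1_bounded_by_twice_min_side(self, tp, fp, fn):
        m = detection_metrics(DetectionCounts(tp=tp, fp=fp, fn=fn))
        assert m.f1 <= 2 * min(m.precision, m.recall) + 1e-9
        assert m.f1 == pytest.approx(
            2 * m.recall * m.precision / (m.precision + m.recall))


class TestRegressionMetrics:
    def test_perfect_agreement(self):
        m = regression_metrics(RegressionPairs([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
        assert (m.r2, m.rmse, m.rrmse) == (1.0, 0.0, 0.0)

    def test_hand_computed_example(self):
        pairs = RegressionPairs([1.0, 2.0, 3.0], [1.1, 1.9, 3.2])
        m = regression_metrics(pairs)
        assert m.rmse == pytest.approx(math.sqrt(0.06 / 3), rel=1e-6)
        assert m.rrmse == pytest.approx(100 * math.sqrt(0.06 / 3) / 2, rel=1e-6)
        ybar = (1.1 + 1.9 + 3.2) / 3
        denom = sum((y - ybar) ** 2 for y in (1.1, 1.9, 3.2))
        assert m.r2 == pytest.approx(1 - 0.06 / denom, rel=1e-6)

    def test_conventional_denominator_flag(self):
        pairs = RegressionPairs([1.0, 2.0, 3.0], [1.1, 1.9, 3.2])
        m = regression_metrics(pairs, conventional=True)
        assert m.r2 == pytest.approx(1 - 0.06 / 2.0, rel=1e-6)

    @given(st.floats(0.1, 50.0))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_scale_invariance(self, k):
        x = np.array([1.0, 2.0, 4.0, 5.5])
        y = np.array([1.2, 1.8, 4.3, 5.0])
        m1 = regression_metrics(RegressionPairs(x, y))
        mk = regression_metrics(RegressionPairs(k * x, k * y))
        assert mk.r2 == pytest.approx(m1.r2, rel=1e-9)
        assert mk.rrmse == pytest.approx(m1.rrmse, rel=1e-9)
        assert mk.rmse == pytest.approx(k * m1.rmse, rel=1e-9)

    def test_too_few_pairs(self):
        with pytest.raises(UndefinedMetricError):
            regression_metrics(RegressionPairs([1.0], [1.0]))

    def test_length_mismatch(self):
        with pytest.raises(DimensionError):
            RegressionPairs([1.0, 2.0], [1.0])


class TestEvaluateRun:
    def test_prediction_equals_reference(self, scene5):
        _, truth = scene5
        report = evaluate_run(truth.mask, truth.to_instances(),
                              resolution=truth.resolution)
        assert report.detection.precision == 100.0
        assert report.detection.recall == 100.0
        assert report.regression["cw_m"].r2 == pytest.approx(1.0, abs=5e-4)
        assert report.counts.tp + report.counts.fn == report.counts.n_reference

    def test_empty_prediction(self, scene5):
        _, truth = scene5
        refs = truth.to_instances()
        with pytest.warns(UserWarning):
            report = evaluate_run(np.zeros_like(truth.mask), refs,
                                  resolution=truth.resolution)
        assert report.counts.fn == report.counts.n_reference
        assert report.detection.recall == 0.0
        assert report.regression == {}

    def test_report_round_trips_to_json(self, scene5, tmp_path):
        _, truth = scene5
        report = evaluate_run(truth.mask, truth.to_instances(),
                              resolution=truth.resolution)
        report.to_json(tmp_path / "report.json")
        import json

        data = json.loads((tmp_path / "report.json").read_text())
        assert data["tp"] == report.counts.tp
        assert data["precision_percent"] == 100.0

    def test_external_reference_metrics_table(self, scene5):
        _, truth = scene5
        metrics = truth.metrics_table[["cw_mean_m", "cpa_m2", "height_m"]]
        report = evaluate_run(truth.mask, truth.to_instances(),
                              ref_metrics=metrics,
                              resolution=truth.resolution)
        assert report.regression["cpa_m2"].rmse < 0.01
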