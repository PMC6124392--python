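"""Evaluation-protocol tests: IoU geometry, greedy matching, 11-point AP."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refinebank.core_io import Box, DatasetIndex, Detection, GroundTruthBox, ImageRecord
from refinebank.evaluation import (
    PRCurve,
    RECALL_LEVELS,
    average_precision,
    evaluate,
    interpolated_precision,
    iou,
    iou_sweep,
    match_detections,
    pr_curve,
    tp_fp_summary,
)

from conftest import make_detection, make_gt


def brute_force_ap(statuses, n_gt):
    """Independent oracle: enumerate P_interp at the 11 recall levels from
    first principles (no shared code with the implementation)."""
    if n_gt == 0:
        return 0.0
    points = []
    tp = 0
    for k, s in enumerate(statuses, start=1):
        tp += bool(s)
        points.append((tp / n_gt, tp / k))
    total = 0.0
    for r in [i / 10 for i in range(11)]:
        qualifying = [p for rec, p in points if rec >= r - 1e-12]
        total += max(qualifying) if qualifying else 0.0
    return total / 11.0


class TestIoU:
    def test_identical_boxes_give_one(self):
        assert iou(Box(0, 0, 10, 10), Box(0, 0, 10, 10)) == 1.0

    def test_disjoint_boxes_give_zero(self):
        assert iou(Box(0, 0, 10, 10), Box(20, 20, 30, 30)) == 0.0

    def test_half_overlap_hand_arithmetic(self):
        # inter 50, union 150
        assert iou(Box(0, 0, 10, 10), Box(5, 0, 15, 10)) == pytest.approx(1 / 3)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_symmetric_bounded_and_one_iff_identical(self, data):
        def box(d):
            # millipixel granularity: "IoU = 1 iff identical" needs exact
            # float arithmetic, which sub-denormal coordinate gaps break
            grid = st.floats(0, 50).map(lambda v: round(v, 3))
            side = st.floats(1, 50).map(lambda v: round(v, 3))
            x0, y0 = d.draw(grid), d.draw(grid)
            return Box(x0, y0, x0 + d.draw(side), y0 + d.draw(side))

        a, b = box(data), box(data)
        v = iou(a, b)
        assert v == iou(b, a)
        assert 0.0 <= v <= 1.0
        if v == 1.0:
            assert a == b


class TestMatching:
    def test_single_overlapping_detection_is_tp(self):
        gt = [make_gt("i", 0, 0, 10, 10, "canker")]
        det = [make_detection("i", 0, 0, 10, 8, "canker", 0.9)]  # IoU 0.8
        m = match_detections(det, gt, 0.5)
        assert (m.tp, m.fp, m.fn) == (1, 0, 0)

    def test_duplicate_detection_on_matched_gt_is_fp(self):
        gt = [make_gt("i", 0, 0, 10, 10, "canker")]
        det = [
            make_detection("i", 0, 0, 10, 10, "canker", 0.8),
            make_detection("i", 0, 0, 10, 9, "canker", 0.9),
        ]
        m = match_detections(det, gt, 0.5)
        # ranked by score: the 0.9 det matches first, the 0.8 is a duplicate
        assert m.statuses == [True, False]
        assert m.detections[0].score == 0.9
        assert m.fn == 0

    def test_class_mismatch_is_fp_plus_fn(self):
        gt = [make_gt("i", 0, 0, 10, 10, "canker")]
        det = [make_detection("i", 0, 0, 10, 9, "plague", 0.9)]  # IoU 0.9
        m = match_detections(det, gt, 0.5)
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)

    def test_empty_ground_truth_all_fp(self):
        det = [make_detection("i", 0, 0, 10, 10, "canker", 0.9)]
        m = match_detections(det, [], 0.5)
        assert (m.tp, m.fp, m.fn) == (0, 1, 0)

    def test_threshold_boundary_geq_vs_strict(self):
        gt = [make_gt("i", 0, 0, 10, 10, "canker")]
        det = [make_detection("i", 0, 0, 10, 5, "canker", 0.9)]  # IoU exactly 0.5
        assert match_detections(det, gt, 0.5).tp == 1
        assert match_detections(det, gt, 0.5, strict=True).tp == 0

    def test_detections_in_other_images_do_not_match(self):
        gt = [make_gt("i", 0, 0, 10, 10, "canker")]
        det = [make_detection("j", 0, 0, 10, 10, "canker", 0.9)]
        m = match_detections(det, gt, 0.5)
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_count_identities_hold_for_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        gts, dets = [], []
        for g in range(rng.integers(0, 6)):
            x0, y0 = rng.uniform(0, 80, 2)
            gts.append(make_gt("i", x0, y0, x0 + rng.uniform(5, 20), y0 + rng.uniform(5, 20), "c"))
        for d in range(rng.integers(0, 8)):
            x0, y0 = rng.uniform(0, 80, 2)
            dets.append(
                make_detection("i", x0, y0, x0 + rng.uniform(5, 20), y0 + rng.uniform(5, 20),
                               "c", float(rng.random()))
            )
        m = match_detections(dets, gts, 0.5)
        assert m.tp + m.fp == len(dets)
        assert m.tp + m.fn == len(gts)


class TestPRCurveAndAP:
    def _match(self, statuses, n_gt):
        dets = [make_detection("i", 0, 0, 10, 10, "c", 1 - 0.01 * k)
                for k in range(len(statuses))]
        from refinebank.evaluation import MatchResult
        return MatchResult(dets, list(statuses), n_gt - sum(statuses), 0.5)

    def test_hand_computed_curve_points(self):
        curve = pr_curve(self._match([True, False, True, False], 2))
        expected = [(0.5, 1.0), (0.5, 0.5), (1.0, 2 / 3), (1.0, 0.5)]
        assert curve.points() == pytest.approx(expected)

    def test_all_tp_ends_at_perfect_point(self):
        curve = pr_curve(self._match([True] * 5, 5))
        assert curve.points()[-1] == (1.0, 1.0)

    def test_no_ground_truth_gives_empty_curve(self):
        assert len(pr_curve(self._match([], 0))) == 0

    def test_interpolated_precision_hand_values(self):
        curve = pr_curve(self._match([True, False, True, False], 2))
        assert interpolated_precision(curve, 0.3) == 1.0
        assert interpolated_precision(curve, 0.8) == pytest.approx(2 / 3)
        assert interpolated_precision(PRCurve(np.empty(0), np.empty(0)), 0.5) == 0.0

    def test_perfect_detector_ap_is_one(self):
        assert average_precision(pr_curve(self._match([True] * 4, 4))) == 1.0

    def test_zero_tp_ap_is_zero(self):
        assert average_precision(pr_curve(self._match([False] * 4, 2))) == 0.0

    def test_hand_derived_ap_value(self):
        ap = average_precision(pr_curve(self._match([True, False, True, False], 2)))
        assert ap == pytest.approx(28 / 33)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_ap_equals_brute_force_oracle(self, data):
        statuses = data.draw(st.lists(st.booleans(), max_size=12))
        extra_gt = data.draw(st.integers(0, 5))
        n_gt = sum(statuses) + extra_gt
        ap = average_precision(pr_curve(self._match(statuses, n_gt)))
        assert ap == pytest.approx(brute_force_ap(statuses, n_gt), abs=1e-12)


class TestEvaluateAndSweep:
    def test_single_class_perfect_detections(self, single_image_index):
        dets = [
            make_detection("img0", 10, 10, 40, 40, "canker", 0.9),
            make_detection("img0", 60, 60, 90, 90, "plague", 0.8),
        ]
        report = evaluate(dets, single_image_index, 0.5)
        assert report.per_class == {"canker": 1.0, "plague": 1.0}
        assert report.mean_ap == 1.0

    def test_unknown_detection_class_raises(self, single_image_index):
        dets = [make_detection("img0", 0, 0, 5, 5, "rust", 0.9)]
        with pytest.raises(ValueError, match="unknown class"):
            evaluate(dets, single_image_index, 0.5, class_set=["canker", "plague"])

    def test_zero_gt_classes_excluded_from_mean(self, single_image_index):
        dets = [make_detection("img0", 10, 10, 40, 40, "canker", 0.9)]
        report = evaluate(dets, single_image_index, 0.5,
                          class_set=["canker", "plague", "miner"])
        assert "miner" in report.excluded_classes
        assert set(report.per_class) == {"canker", "plague"}

    def test_gt_as_detections_constant_across_thresholds(self, single_image_index):
        dets = [
            make_detection("img0", 10, 10, 40, 40, "canker", 1.0),
            make_detection("img0", 60, 60, 90, 90, "plague", 1.0),
        ]
        table = iou_sweep(dets, single_image_index)
        assert (table["fp"] == 0).all()
        assert (table.groupby("class")["tp"].nunique() == 1).all()

    def test_iou_054_detection_flips_at_06(self, single_image_index):
        # IoU with the canker GT = 630 / (900 + 900 - 630) = 0.538
        dets = [make_detection("img0", 10, 19, 40, 49, "canker", 0.9)]
        table = iou_sweep(dets, single_image_index, thresholds=[0.5, 0.6])
        canker = table[table["class"] == "canker"].set_index("iou")
        assert canker.loc[0.5, "tp"] == 1
        assert canker.loc[0.6, "tp"] == 0


class TestTpFpSummary:
    def test_single_tp_no_fp_shares(self):
        s = tp_fp_summary({"canker": (1, 0)})
        assert (s.tp_share, s.fp_share) == (100.0, 0.0)

    def test_empty_total_is_not_applicable(self):
        s = tp_fp_summary({"canker": (0, 0)})
        assert s.tp_share is None and s.fp_share is None

    def test_per_class_totals(self):
        s = tp_fp_summary({"a": (8, 2), "b": (1, 1)})
        assert s.per_class.set_index("class").loc["a", "total"] == 10
        assert s.total == 12
        assert s.tp_share == 75.0
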