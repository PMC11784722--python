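"""Metric correctness: matching, AP against brute-force oracles, F1, strata."""

import numpy as np
import pytest

from imcyolo.evalkit import (
    EvalCounts, GroundTruthBox, average_precision, average_precision_staircase,
    evaluate, f1_best, map50_95, map_at, match_detections, mean_ap,
    precision_recall, pr_curve_export, size_stratified_map,
)
from imcyolo.head import Detection


def det(x1, y1, x2, y2, score, cid=0):
    return Detection((float(x1), float(y1), float(x2), float(y2)), score, cid)


def gt(x1, y1, x2, y2, cid=0):
    return GroundTruthBox((float(x1), float(y1), float(x2), float(y2)), cid)


def staircase_oracle(flags, n_gt):
    """Threshold-by-threshold loop: P-R points, monotone envelope, exact
    rectangle integration.  Deliberately naive."""
    pts = [(0.0, 1.0)]
    tp = fp = 0
    for f in flags:
        tp, fp = tp + bool(f), fp + (not f)
        pts.append((tp / n_gt, tp / (tp + fp)))
    # monotone envelope from the right
    env = []
    best = 0.0
    for r, p in reversed(pts):
        best = max(best, p)
        env.append((r, best))
    env.reverse()
    area = 0.0
    for (r0, _), (r1, p1) in zip(env, env[1:]):
        area += (r1 - r0) * p1
    return area


def f1_sweep_oracle(dets_per_image, gts_per_image, iou_thresh=0.5):
    scores = sorted({d.score for dets in dets_per_image for d in dets})
    best = 0.0
    for thr in scores:
        tp = fp = fn = 0
        for dets, gts in zip(dets_per_image, gts_per_image):
            kept = [d for d in dets if d.score >= thr]
            c, _ = match_detections(kept, gts, iou_thresh)
            tp, fp, fn = tp + c.TP, fp + c.FP, fn + c.FN
        if 2 * tp + fp + fn:
            best = max(best, 2 * tp / (2 * tp + fp + fn))
    return best


class TestMatching:
    def test_perfect_single_match(self):
        counts, flags = match_detections([det(0, 0, 10, 10, 0.9)],
                                         [gt(0, 0, 10, 10)], 0.5)
        assert (counts.TP, counts.FP, counts.FN) == (1, 0, 0)
        assert flags == [True]

    def test_second_detection_on_same_box_is_false_positive(self):
        counts, flags = match_detections(
            [det(0, 0, 10, 10, 0.9), det(0, 0, 10, 10, 0.8)],
            [gt(0, 0, 10, 10)], 0.5)
        assert (counts.TP, counts.FP) == (1, 1)
        assert flags == [True, False]

    def test_low_overlap_rejected_at_half_iou(self):
        counts, _ = match_detections([det(0, 0, 2, 2, 0.9)], [gt(1, 1, 3, 3)], 0.5)
        assert (counts.TP, counts.FP, counts.FN) == (0, 1, 1)

    def test_equal_scores_keep_insertion_order(self):
        d1 = [det(0, 0, 10, 10, 0.5), det(0, 0, 9, 9, 0.5)]
        _, flags = match_detections(d1, [gt(0, 0, 10, 10)], 0.5)
        assert flags == [True, False]

    def test_class_mismatch_never_matches(self):
        counts, _ = match_detections([det(0, 0, 10, 10, 0.9, cid=1)],
                                     [gt(0, 0, 10, 10, cid=0)], 0.5)
        assert (counts.TP, counts.FP, counts.FN) == (0, 1, 1)


class TestPrecisionRecall:
    @pytest.mark.parametrize("tp,fp,fn,p,r", [
        (2, 1, 1, 2 / 3, 2 / 3),
        (3, 0, 0, 1.0, 1.0),
        (0, 4, 2, 0.0, 0.0),
        (0, 0, 0, 1.0, 0.0),
    ])
    def test_formulas_and_conventions(self, tp, fp, fn, p, r):
        got = precision_recall(EvalCounts(TP=tp, FP=fp, FN=fn))
        assert got == (pytest.approx(p), pytest.approx(r))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            EvalCounts(TP=-1)


class TestAveragePrecision:
    def test_all_true_positives_give_unit_ap(self):
        flags = np.array([True, True, True])
        assert average_precision(flags, 3) == pytest.approx(1.0)
        assert average_precision_staircase(flags, 3) == pytest.approx(1.0)

    def test_no_true_positives_give_zero(self):
        flags = np.array([False, False])
        assert average_precision(flags, 2) == 0.0

    def test_tp_then_fp_still_unit_ap(self):
        # recall saturates at the first detection; trailing FP is past the curve
        flags = np.array([True, False])
        assert average_precision(flags, 1) == pytest.approx(1.0)

    def test_undefined_without_ground_truth(self):
        with pytest.raises(ValueError, match="ground truth"):
            average_precision(np.array([True]), 0)

    def test_staircase_matches_naive_oracle_on_random_instances(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 30))
            n_gt = int(rng.integers(1, 20))
            flags = rng.random(n) < 0.5
            flags = flags[: max(1, n)]
            capped = np.zeros(n, dtype=bool)
            capped[np.flatnonzero(flags)[:n_gt]] = True  # at most n_gt TPs
            fast = average_precision_staircase(capped, n_gt)
            slow = staircase_oracle(capped.tolist(), n_gt)
            assert abs(fast - slow) < 1e-6

    def test_interpolated_variant_close_to_exact_integral(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 40))
            n_gt = int(rng.integers(3, 25))
            capped = np.zeros(n, dtype=bool)
            hits = np.flatnonzero(rng.random(n) < 0.4)[:n_gt]
            capped[hits] = True
            a = average_precision(capped, n_gt)
            b = average_precision_staircase(capped, n_gt)
            assert abs(a - b) <= 0.02  # 101-point quantization only


class TestMeanAP:
    def test_single_class_map_equals_class_ap(self):
        dets = [[det(0, 0, 10, 10, 0.9)]]
        gts = [[gt(0, 0, 10, 10)]]
        m, per_class = map_at(dets, gts, 0.5)
        assert m == per_class[0] == pytest.approx(1.0)

    def test_perfect_detector_maxes_the_iou_sweep(self):
        dets = [[det(0, 0, 10, 10, 0.9), det(20, 20, 31, 29, 0.8)]]
        gts = [[gt(0, 0, 10, 10), gt(20, 20, 31, 29)]]
        m, _ = map50_95(dets, gts)
        assert m == pytest.approx(1.0)

    def test_shifted_boxes_pass_only_loose_thresholds(self):
        # IoU 32/48 = 2/3: perfect at 0.50-0.65, failing at 0.70+
        dets = [[det(2, 0, 12, 4, 0.9)]]
        gts = [[gt(0, 0, 10, 4)]]
        m, per_iou = map50_95(dets, gts)
        passing = [t for t, v in per_iou.items() if v == pytest.approx(1.0)]
        assert passing == [0.5, 0.55, 0.6, 0.65]
        assert m == pytest.approx(4 / 10)

    def test_map5095_never_exceeds_map50(self, rng):
        dets, gts = [], []
        for _ in range(6):
            img_gts = [gt(x, x, x + 10, x + 8) for x in rng.uniform(0, 80, 3)]
            img_dets = [det(g.box[0] + rng.uniform(-3, 3), g.box[1],
                            g.box[2] + rng.uniform(-3, 3), g.box[3],
                            rng.uniform(0.1, 1.0)) for g in img_gts]
            gts.append(img_gts)
            dets.append(img_dets)
        m5095, per_iou = map50_95(dets, gts)
        assert m5095 <= per_iou[0.5] + 1e-9

    def test_empty_class_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mean_ap({})


class TestF1Best:
    def test_known_counts_give_two_thirds(self):
        # best threshold keeps TP=2, FP=1 (highest-scored box is spurious),
        # FN=1 -> F1 = 4/6
        dets = [[det(100, 100, 105, 105, 0.9), det(0, 0, 10, 10, 0.8),
                 det(30, 30, 40, 40, 0.7)]]
        gts = [[gt(0, 0, 10, 10), gt(30, 30, 40, 40), gt(60, 60, 70, 70)]]
        f1, _ = f1_best(dets, gts)
        assert f1 == pytest.approx(2 * 2 / (2 * 2 + 1 + 1))  # TP=2 FP=1 FN=1

    def test_perfect_detector_reaches_one(self):
        dets = [[det(0, 0, 10, 10, 0.9)]]
        gts = [[gt(0, 0, 10, 10)]]
        assert f1_best(dets, gts)[0] == pytest.approx(1.0)

    def test_sweep_maximality_against_oracle(self, rng):
        for _ in range(30):
            gts, dets = [], []
            for _ in range(3):
                img_gts = [gt(x, x, x + 10, x + 10) for x in rng.uniform(0, 100, 4)]
                img_dets = []
                for g in img_gts:
                    if rng.random() < 0.7:
                        j = rng.uniform(-4, 4)
                        img_dets.append(det(g.box[0] + j, g.box[1] + j,
                                            g.box[2] + j, g.box[3] + j,
                                            float(rng.uniform(0.05, 1.0))))
                for _ in range(int(rng.integers(0, 3))):
                    x = rng.uniform(150, 300)
                    img_dets.append(det(x, x, x + 8, x + 8, float(rng.uniform(0.05, 1.0))))
                gts.append(img_gts)
                dets.append(img_dets)
            fast, _ = f1_best(dets, gts)
            assert fast == pytest.approx(f1_sweep_oracle(dets, gts), abs=1e-9)

    def test_requires_ground_truth(self):
        with pytest.raises(ValueError, match="ground truth"):
            f1_best([[det(0, 0, 5, 5, 0.5)]], [[]])


class TestSizeStrata:
    def test_perfect_small_and_missed_large(self):
        gts = [[gt(0, 0, 10, 10), gt(50, 50, 250, 250)]]
        dets = [[det(0, 0, 10, 10, 0.9)]]
        strata = size_stratified_map(dets, gts)
        assert strata["small"] == pytest.approx(1.0)
        assert strata["large"] == pytest.approx(0.0)
        assert strata["medium"] is None

    def test_all_tiny_targets_leave_other_strata_missing(self):
        gts = [[gt(0, 0, 5, 5)]]
        dets = [[det(0, 0, 5, 5, 0.9)]]
        strata = size_stratified_map(dets, gts)
        assert strata["medium"] is None and strata["large"] is None

    def test_strata_partition_ground_truth(self):
        boxes = [gt(0, 0, 10, 10), gt(0, 0, 50, 50), gt(0, 0, 200, 200)]
        lo, hi = 32.0 ** 2, 96.0 ** 2
        small = [g for g in boxes if g.area < lo]
        medium = [g for g in boxes if lo <= g.area < hi]
        large = [g for g in boxes if g.area >= hi]
        assert len(small) + len(medium) + len(large) == len(boxes)

    def test_literal_area_unit_moves_the_cuts(self):
        gts = [[gt(0, 0, 10, 10)]]  # area 100 px^2
        dets = [[det(0, 0, 10, 10, 0.9)]]
        side = size_stratified_map(dets, gts, area_unit="side")
        literal = size_stratified_map(dets, gts, area_unit="px2")
        assert side["small"] == pytest.approx(1.0)
        assert literal["small"] is None  # 100 > 96 -> large under px2 reading
        assert literal["large"] == pytest.approx(1.0)


class TestPRCurve:
    def test_perfect_detector_curve_and_area(self, tmp_path):
        dets = [[det(0, 0, 10, 10, 0.9)]]
        gts = [[gt(0, 0, 10, 10)]]
        csv_path = tmp_path / "pr.csv"
        points, ap = pr_curve_export(dets, gts, csv_path=csv_path)
        assert points[0] == (0.0, 1.0)
        assert points[-1][1] == pytest.approx(1.0)
        header = csv_path.read_text().splitlines()[0]
        assert header == "recall,precision"

    def test_area_equals_ap_and_recall_monotone(self, rng):
        gts = [[gt(x, x, x + 10, x + 10) for x in rng.uniform(0, 100, 5)]]
        dets = [[det(g.box[0] + rng.uniform(-3, 3), g.box[1], g.box[2],
                     g.box[3], float(rng.uniform(0.1, 1))) for g in gts[0][:4]]]
        points, ap = pr_curve_export(dets, gts)
        recalls = [r for r, _ in points]
        precisions = [p for _, p in points]
        assert recalls == sorted(recalls)
        assert np.mean(precisions) == pytest.approx(ap, abs=1e-9)


class TestFullReport:
    def test_report_fields_consistent(self):
        gts = [[gt(0, 0, 10, 10), gt(30, 30, 42, 40)]]
        dets = [[det(0, 0, 10, 10, 0.9), det(30, 30, 42, 40, 0.6),
                 det(80, 80, 90, 90, 0.4)]]
        rep = evaluate(dets, gts, conf_thresh=0.5)
        assert rep.map50 == pytest.approx(1.0)
        assert rep.map50_95 <= rep.map50
        assert rep.precision == pytest.approx(1.0)
        assert rep.recall == pytest.approx(1.0)
        assert rep.n_classes == 1
        assert 0 <= rep.f1_best <= 1
        d = rep.to_dict()
        assert set(d) >= {"mAP50", "mAP50_95", "F1best", "size_strata"}
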