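"""Detection evaluation: matching, precision/recall, AP, mAP, F1best.

Definitions follow the standard single-stage-detector conventions:
P = TP/(TP+FP), R = TP/(TP+FN), AP is the area under the interpolated
precision-recall curve (101-point grid with a monotone-max precision
envelope), mAP averages AP over classes, mAP50:95 additionally averages
over IoU thresholds 0.50:0.05:0.95, and F1best = max over confidence
thresholds of 2TP/(2TP+FP+FN).  Ground truth can be stratified by pixel
area into small/medium/large using the 32^2 / 96^2 side-length convention
(a literal-area reading is available via ``area_unit="px2"``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .head import box_iou_xyxy

__all__ = [
    "GroundTruthBox", "EvalCounts", "MetricReport",
    "match_detections", "precision_recall", "average_precision",
    "average_precision_staircase", "mean_ap", "map_at", "map50_95",
    "f1_best", "size_stratified_map", "pr_curve_export", "evaluate",
]

IOU_GRID = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))
RECALL_GRID = np.linspace(0.0, 1.0, 101)


@dataclass(frozen=True)
class GroundTruthBox:
    box: tuple  # absolute pixel xyxy
    class_id: int = 0

    @property
    def area(self) -> float:
        x1, y1, x2, y2 = self.box
        return max(x2 - x1, 0.0) * max(y2 - y1, 0.0)


@dataclass
class EvalCounts:
    TP: int = 0
    FP: int = 0
    FN: int = 0
    TN: int = 0  # defined for completeness; unused by the box metrics

    def __post_init__(self):
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("counts must be nonnegative")


@dataclass
class MetricReport:
    precision: float
    recall: float
    ap_per_iou: dict
    map50: float
    map50_95: float
    f1_best: float
    f1_threshold: float
    n_classes: int
    pr_curve: list = field(default_factory=list)
    size_strata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "precision": self.precision, "recall": self.recall,
            "ap_per_iou": {str(k): v for k, v in self.ap_per_iou.items()},
            "mAP50": self.map50, "mAP50_95": self.map50_95,
            "F1best": self.f1_best, "F1best_threshold": self.f1_threshold,
            "n_classes": self.n_classes,
            "size_strata": self.size_strata,
        }


def _det_arrays(dets):
    boxes = np.array([d.box for d in dets], dtype=np.float64).reshape(-1, 4)
    scores = np.array([d.score for d in dets], dtype=np.float64)
    classes = np.array([d.class_id for d in dets], dtype=np.int64)
    return boxes, scores, classes


def match_detections(dets, gts, iou_thresh: float = 0.5):
    """Greedy one-to-one matching by descending score, best-IoU ground truth.

    Ties in score keep insertion order.  Returns ``(EvalCounts, flags)``
    where ``flags[i]`` says whether detection ``i`` (original order) is a
    true positive.
    """
    flags = [False] * len(dets)
    if not gts:
        counts = EvalCounts(TP=0, FP=len(dets), FN=0)
        return counts, flags
    gt_boxes = np.array([g.box for g in gts], dtype=np.float64)
    gt_cls = np.array([g.class_id for g in gts])
    taken = np.zeros(len(gts), dtype=bool)
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].score, i))
    for i in order:
        d = dets[i]
        cand = np.flatnonzero(~taken & (gt_cls == d.class_id))
        if cand.size == 0:
            continue
        ious = box_iou_xyxy(np.array([d.box]), gt_boxes[cand])[0]
        j = int(np.argmax(ious))
        if ious[j] >= iou_thresh:
            taken[cand[j]] = True
            flags[i] = True
    tp = sum(flags)
    return EvalCounts(TP=tp, FP=len(dets) - tp, FN=len(gts) - tp), flags


def precision_recall(counts: EvalCounts):
    """P and R per the standard formulas; P defaults to 1 with no detections."""
    p = counts.TP / (counts.TP + counts.FP) if (counts.TP + counts.FP) else 1.0
    r = counts.TP / (counts.TP + counts.FN) if (counts.TP + counts.FN) else 0.0
    return p, r


def _pooled_flags(dets_per_image, gts_per_image, iou_thresh, class_id=None):
    """Match per image, pool detections over the split sorted by score."""
    scores, flags = [], []
    n_gt = 0
    for dets, gts in zip(dets_per_image, gts_per_image):
        if class_id is not None:
            dets = [d for d in dets if d.class_id == class_id]
            gts = [g for g in gts if g.class_id == class_id]
        n_gt += len(gts)
        _, f = match_detections(dets, gts, iou_thresh)
        scores.extend(d.score for d in dets)
        flags.extend(f)
    order = np.lexsort((np.arange(len(scores)), -np.asarray(scores, dtype=np.float64)))
    return (np.asarray(scores)[order] if scores else np.zeros(0),
            np.asarray(flags, dtype=bool)[order] if flags else np.zeros(0, dtype=bool),
            n_gt)


def _pr_points(flags: np.ndarray, n_gt: int):
    tp = np.cumsum(flags)
    fp = np.cumsum(~flags)
    recall = tp / n_gt
    precision = tp / np.maximum(tp + fp, 1)
    return recall, precision


def _interp101(flags: np.ndarray, n_gt: int) -> np.ndarray:
    """Monotone-envelope precision sampled on the 101-point recall grid."""
    recall, precision = _pr_points(flags, n_gt)
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    idx = np.searchsorted(recall, RECALL_GRID, side="left")
    return np.where(idx < envelope.size, envelope[np.minimum(idx, envelope.size - 1)], 0.0)


def average_precision(flags: np.ndarray, n_gt: int) -> float:
    """AP via 101-point interpolation with a monotone precision envelope."""
    if n_gt <= 0:
        raise ValueError("average precision undefined without ground truth")
    if flags.size == 0:
        return 0.0
    return float(_interp101(flags, n_gt).mean())


def average_precision_staircase(flags: np.ndarray, n_gt: int) -> float:
    """All-points (continuous staircase) AP; the exact integral of the
    monotone envelope.  Kept as an independent cross-check of the
    interpolated implementation."""
    if n_gt <= 0:
        raise ValueError("average precision undefined without ground truth")
    if flags.size == 0:
        return 0.0
    recall, precision = _pr_points(flags, n_gt)
    recall = np.concatenate([[0.0], recall])
    precision = np.concatenate([[1.0], precision])
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    return float(np.sum(np.diff(recall) * envelope[1:]))


def map_at(dets_per_image, gts_per_image, iou_thresh: float,
           class_ids=None, method=average_precision):
    """Mean AP over classes at one IoU threshold (classes without ground
    truth are skipped, i.e. reported as missing rather than zero)."""
    if class_ids is None:
        class_ids = sorted({g.class_id for gts in gts_per_image for g in gts})
    if not class_ids:
        raise ValueError("no classes with ground truth")
    aps = {}
    for c in class_ids:
        _, flags, n_gt = _pooled_flags(dets_per_image, gts_per_image, iou_thresh, c)
        aps[c] = method(flags, n_gt) if n_gt else None
    present = [v for v in aps.values() if v is not None]
    if not present:
        raise ValueError("no class has ground truth in this split")
    return float(np.mean(present)), aps


def mean_ap(per_class_aps: dict) -> float:
    vals = [v for v in per_class_aps.values() if v is not None]
    if not vals:
        raise ValueError("empty class set")
    return float(np.mean(vals))


def map50_95(dets_per_image, gts_per_image, method=average_precision):
    per_iou = {}
    for t in IOU_GRID:
        per_iou[t], _ = map_at(dets_per_image, gts_per_image, t, method=method)
    return float(np.mean(list(per_iou.values()))), per_iou


def f1_best(dets_per_image, gts_per_image, iou_thresh: float = 0.5):
    """Max F1 over the confidence-threshold sweep; ties take the lowest
    threshold.  F1 = 2TP/(2TP+FP+FN)."""
    scores, flags, n_gt = _pooled_flags(dets_per_image, gts_per_image, iou_thresh)
    if n_gt == 0:
        raise ValueError("F1 undefined without ground truth")
    if scores.size == 0:
        return 0.0, 1.0
    tp = np.cumsum(flags)
    fp = np.cumsum(~flags)
    fn = n_gt - tp
    f1 = 2 * tp / np.maximum(2 * tp + fp + fn, 1)
    # thresholds: keeping all detections with score >= scores[i]
    best = -1.0
    best_thr = 1.0
    for i in range(len(scores) - 1, -1, -1):  # low thresholds first on ties
        if i < len(scores) - 1 and scores[i] == scores[i + 1]:
            continue  # same threshold keeps the later (complete) prefix
        if f1[i] > best + 1e-12:
            best, best_thr = float(f1[i]), float(scores[i])
    return best, best_thr


def size_stratified_map(dets_per_image, gts_per_image,
                        thresholds=(32.0, 96.0), area_unit: str = "side"):
    """mAP50:95 within small/medium/large ground-truth area strata.

    ``area_unit="side"`` reads the thresholds as side lengths (area cuts at
    32^2 and 96^2, the COCO convention); ``"px2"`` treats them as literal
    areas.  Detections overlapping out-of-stratum ground truth are ignored
    rather than counted as false positives; empty strata are reported as
    ``None``.
    """
    lo, hi = thresholds
    if area_unit == "side":
        lo, hi = lo * lo, hi * hi
    elif area_unit != "px2":
        raise ValueError("area_unit must be 'side' or 'px2'")
    bounds = {"small": (0.0, lo), "medium": (lo, hi), "large": (hi, np.inf)}
    out = {}
    for name, (a, b) in bounds.items():
        in_stratum = [[g for g in gts if a <= g.area < b] for gts in gts_per_image]
        if sum(len(g) for g in in_stratum) == 0:
            out[name] = None
            continue
        kept_dets = []
        for dets, gts, strat in zip(dets_per_image, gts_per_image, in_stratum):
            ignore = [g for g in gts if not (a <= g.area < b)]
            if ignore:
                ig_boxes = np.array([g.box for g in ignore])
                kept = []
                for d in dets:
                    ious = box_iou_xyxy(np.array([d.box]), ig_boxes)[0]
                    st_iou = 0.0
                    if strat:
                        st_iou = box_iou_xyxy(np.array([d.box]),
                                              np.array([g.box for g in strat]))[0].max()
                    # drop detections that sit on ignored ground truth
                    if ious.max() >= 0.5 and ious.max() > st_iou:
                        continue
                    kept.append(d)
                kept_dets.append(kept)
            else:
                kept_dets.append(list(dets))
        out[name], _ = map50_95(kept_dets, in_stratum)
    return out


def pr_curve_export(dets_per_image, gts_per_image, iou_thresh: float = 0.5,
                    csv_path=None, class_id=None):
    """Monotone-interpolated P-R curve points; area equals the AP value.

    Returns ``(points, ap)`` where ``points`` is a list of (recall,
    precision) pairs on the 101-point recall grid, prefixed with the (0, 1)
    anchor when the curve does not start there.
    """
    _, flags, n_gt = _pooled_flags(dets_per_image, gts_per_image, iou_thresh, class_id)
    ap = average_precision(flags, n_gt)
    interp = _interp101(flags, n_gt) if flags.size else np.zeros(101)
    points = list(zip(RECALL_GRID.tolist(), interp.tolist()))
    if csv_path is not None:
        with open(csv_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["recall", "precision"])
            writer.writerows(points)
    return points, ap


def evaluate(dets_per_image, gts_per_image, conf_thresh: float = 0.25,
             iou_thresh: float = 0.5) -> MetricReport:
    """Full report: P/R at ``conf_thresh``, AP grid, mAP, F1best, strata."""
    counts = EvalCounts()
    for dets, gts in zip(dets_per_image, gts_per_image):
        strong = [d for d in dets if d.score >= conf_thresh]
        c, _ = match_detections(strong, gts, iou_thresh)
        counts.TP += c.TP
        counts.FP += c.FP
        counts.FN += c.FN
    p, r = precision_recall(counts)
    m5095, per_iou = map50_95(dets_per_image, gts_per_image)
    f1, thr = f1_best(dets_per_image, gts_per_image, iou_thresh=0.5)
    points, _ = pr_curve_export(dets_per_image, gts_per_image, iou_thresh=0.5)
    classes = {g.class_id for gts in gts_per_image for g in gts}
    return MetricReport(
        precision=p, recall=r, ap_per_iou=per_iou,
        map50=per_iou[0.5], map50_95=m5095, f1_best=f1, f1_threshold=thr,
        n_classes=len(classes), pr_curve=points,
        size_strata=size_stratified_map(dets_per_image, gts_per_image),
    )
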