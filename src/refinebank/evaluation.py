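"""Detection evaluation: IoU, TP/FP matching, precision-recall and 11-point AP.

The evaluation protocol is the classic Pascal VOC one.  Detections are
ranked by descending confidence and matched greedily: a detection is a true
positive when its best-overlap *unmatched* same-class ground-truth box
reaches the IoU threshold, otherwise a false positive; each ground-truth
box can be claimed at most once, so duplicate hits on the same box are
false positives.  Average precision is the mean of the interpolated
precision P_interp(r) = max_{r' >= r} p(r') over the eleven recall levels
{0, 0.1, ..., 1.0}, and mAP averages AP over the classes that have at
least one ground-truth box.

True negatives are undefined for open-background detection (there is no
enumerable set of "correctly not detected" boxes); summaries report them
as not applicable rather than guessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import Box, DatasetIndex, Detection, GroundTruthBox

__all__ = [
    "iou",
    "MatchResult",
    "match_detections",
    "PRCurve",
    "pr_curve",
    "interpolated_precision",
    "average_precision",
    "APReport",
    "evaluate",
    "iou_sweep",
    "TpFpSummary",
    "tp_fp_summary",
    "micro_precision_recall",
]

RECALL_LEVELS = np.linspace(0.0, 1.0, 11)


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes; 0 when disjoint, 1 iff identical."""
    inter = a.intersection_area(b)
    if inter == 0.0:
        return 0.0
    union = a.area + b.area - inter
    return inter / union


@dataclass
class MatchResult:
    """TP/FP statuses of a ranked detection list against ground truth.

    ``detections`` are in descending-score order (ties keep input order);
    ``statuses[k]`` is True for TP.  ``fn_count`` counts ground-truth boxes
    left unmatched.  True negatives are not a meaningful count in detection
    and are exposed only as ``tn = None`` (not applicable).
    """

    detections: list[Detection]
    statuses: list[bool]
    fn_count: int
    iou_threshold: float
    matched_gt: list[GroundTruthBox | None] = field(default_factory=list)

    tn: None = None  # not applicable for open-background detection

    @property
    def tp(self) -> int:
        return sum(self.statuses)

    @property
    def fp(self) -> int:
        return len(self.statuses) - self.tp

    @property
    def fn(self) -> int:
        return self.fn_count

    @property
    def n_gt(self) -> int:
        return self.tp + self.fn_count

    def tp_detections(self) -> list[Detection]:
        return [d for d, s in zip(self.detections, self.statuses) if s]

    def fp_detections(self) -> list[Detection]:
        return [d for d, s in zip(self.detections, self.statuses) if not s]


def match_detections(
    detections: Sequence[Detection],
    ground_truths: Sequence[GroundTruthBox],
    iou_threshold: float,
    *,
    strict: bool = False,
) -> MatchResult:
    """Greedily assign TP/FP statuses at one IoU threshold.

    Detections are processed in descending score (score ties broken by
    input order); each is matched against the unmatched ground-truth boxes
    of the same image and class, taking the highest-IoU candidate (IoU ties
    broken by lowest ground-truth index).  ``strict`` switches the
    acceptance rule from ``IoU >= threshold`` to ``IoU > threshold``.

    Empty ground truth is not an error: every detection is then FP.
    """
    if not 0.0 < iou_threshold <= 1.0:
        raise ValueError(f"iou_threshold {iou_threshold} outside (0, 1]")

    order = sorted(range(len(detections)), key=lambda i: -detections[i].score)
    ranked = [detections[i] for i in order]

    # candidate GTs grouped by (image, class)
    groups: dict[tuple[str, str], list[int]] = {}
    for j, gt in enumerate(ground_truths):
        groups.setdefault((gt.image_id, gt.class_label), []).append(j)
    claimed = [False] * len(ground_truths)

    statuses: list[bool] = []
    matched: list[GroundTruthBox | None] = []
    for det in ranked:
        best_j = -1
        best_iou = -1.0
        for j in groups.get((det.image_id, det.class_label), ()):
            if claimed[j]:
                continue
            ov = iou(det.box, ground_truths[j].box)
            if ov > best_iou:  # strict >: IoU ties keep the lowest GT index
                best_iou = ov
                best_j = j
        hit = best_iou > iou_threshold if strict else best_iou >= iou_threshold
        if best_j >= 0 and hit:
            claimed[best_j] = True
            statuses.append(True)
            matched.append(ground_truths[best_j])
        else:
            statuses.append(False)
            matched.append(None)
    fn = claimed.count(False)
    return MatchResult(ranked, statuses, fn, iou_threshold, matched)


@dataclass
class PRCurve:
    """Ranked (recall, precision) points, one per detection rank."""

    recalls: np.ndarray
    precisions: np.ndarray

    def __post_init__(self) -> None:
        self.recalls = np.asarray(self.recalls, dtype=float)
        self.precisions = np.asarray(self.precisions, dtype=float)
        if self.recalls.shape != self.precisions.shape:
            raise ValueError("recall/precision length mismatch")
        if len(self.recalls) and np.any(np.diff(self.recalls) < 0):
            raise ValueError("recalls must be non-decreasing")

    def __len__(self) -> int:
        return len(self.recalls)

    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.recalls.tolist(), self.precisions.tolist()))


def pr_curve(match: MatchResult, n_gt: int | None = None) -> PRCurve:
    """Precision/recall at every rank of the score-ordered detection list.

    ``n_gt`` defaults to the ground-truth count recorded in the match
    (tp + fn).  With zero ground truth the curve is empty.
    """
    total_gt = match.n_gt if n_gt is None else n_gt
    if total_gt == 0:
        return PRCurve(np.empty(0), np.empty(0))
    tp_cum = np.cumsum(np.asarray(match.statuses, dtype=float))
    ranks = np.arange(1, len(match.statuses) + 1, dtype=float)
    return PRCurve(tp_cum / total_gt, tp_cum / ranks)


def interpolated_precision(curve: PRCurve, r: float) -> float:
    """Max precision over curve points with recall >= r; 0 if none qualify."""
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"recall level {r} outside [0, 1]")
    if len(curve) == 0:
        return 0.0
    mask = curve.recalls >= r - 1e-12
    if not mask.any():
        return 0.0
    return float(curve.precisions[mask].max())


def average_precision(curve: PRCurve) -> float:
    """11-point interpolated AP: mean of P_interp over recalls 0, 0.1, ..., 1."""
    if len(curve) == 0:
        return 0.0
    # suffix max of precision in recall order gives P_interp at each point
    interp = np.maximum.accumulate(curve.precisions[::-1])[::-1]
    total = 0.0
    for r in RECALL_LEVELS:
        mask = curve.recalls >= r - 1e-12
        total += float(interp[np.argmax(mask)]) if mask.any() else 0.0
    return total / len(RECALL_LEVELS)


@dataclass
class APReport:
    """Per-class and mean 11-point AP at one IoU threshold.

    Classes with zero ground-truth boxes cannot have a defined AP; they are
    excluded from the mean and listed in ``excluded_classes``.
    """

    per_class: dict[str, float]
    mean_ap: float
    iou_threshold: float
    excluded_classes: list[str] = field(default_factory=list)

    @classmethod
    def from_aps(cls, per_class: Mapping[str, float], iou_threshold: float = 0.5) -> "APReport":
        aps = dict(per_class)
        if not aps:
            return cls(aps, float("nan"), iou_threshold)
        return cls(aps, float(np.mean(list(aps.values()))), iou_threshold)


def evaluate(
    detections: Sequence[Detection],
    dataset_index: DatasetIndex,
    iou_threshold: float = 0.5,
    class_set: Sequence[str] | None = None,
) -> APReport:
    """Per-class AP (match -> curve -> AP, pooled over images) and mean AP."""
    gts = dataset_index.ground_truths()
    if class_set is None:
        class_set = sorted({g.class_label for g in gts}
                           | {d.class_label for d in detections})
    known = set(class_set)
    for det in detections:
        if det.class_label not in known:
            raise ValueError(f"detection has unknown class {det.class_label!r}")

    per_class: dict[str, float] = {}
    excluded: list[str] = []
    for label in class_set:
        cls_gts = [g for g in gts if g.class_label == label]
        cls_dets = [d for d in detections if d.class_label == label]
        if not cls_gts:
            excluded.append(label)
            continue
        match = match_detections(cls_dets, cls_gts, iou_threshold)
        per_class[label] = average_precision(pr_curve(match))
    mean_ap = float(np.mean(list(per_class.values()))) if per_class else float("nan")
    return APReport(per_class, mean_ap, iou_threshold, excluded)


def iou_sweep(
    detections: Sequence[Detection],
    dataset_index: DatasetIndex,
    thresholds: Sequence[float] | None = None,
    class_set: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-threshold, per-class tp/fp/fn/precision/recall/AP table.

    Default thresholds are 0.1 ... 0.9, the standard sensitivity sweep for
    detector stability under stricter localisation demands.
    """
    if thresholds is None:
        thresholds = np.round(np.arange(0.1, 0.95, 0.1), 2).tolist()
    gts = dataset_index.ground_truths()
    if class_set is None:
        class_set = sorted({g.class_label for g in gts})
    rows = []
    for thr in thresholds:
        for label in class_set:
            cls_gts = [g for g in gts if g.class_label == label]
            cls_dets = [d for d in detections if d.class_label == label]
            match = match_detections(cls_dets, cls_gts, thr)
            n_det = len(match.statuses)
            tp, fp, fn = match.tp, match.fp, match.fn
            precision = tp / n_det if n_det else float("nan")
            recall = tp / len(cls_gts) if cls_gts else float("nan")
            ap = average_precision(pr_curve(match)) if cls_gts else float("nan")
            rows.append(
                {
                    "class": label,
                    "iou": float(thr),
                    "tp": tp,
                    "fp": fp,
                    "fn": fn,
                    "precision": precision,
                    "recall": recall,
                    "ap": ap,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class TpFpSummary:
    """Per-class and global TP/FP counts with percentage shares of the total."""

    per_class: pd.DataFrame  # columns class, tp, fp, total
    tp: int
    fp: int
    total: int
    tp_share: float | None  # percent of total, rounded to 2 decimals
    fp_share: float | None


def tp_fp_summary(
    per_class_counts: Mapping[str, tuple[int, int]] | Mapping[str, MatchResult],
) -> TpFpSummary:
    """Summarise per-class TP/FP counts (or match results) into a table.

    Shares are percentages of the grand total, rounded to 2 decimals; with
    an empty total they are undefined and reported as ``None``.
    """
    rows = []
    for label, value in per_class_counts.items():
        if isinstance(value, MatchResult):
            tp, fp = value.tp, value.fp
        else:
            tp, fp = int(value[0]), int(value[1])
        if tp < 0 or fp < 0:
            raise ValueError("counts must be non-negative")
        rows.append({"class": label, "tp": tp, "fp": fp, "total": tp + fp})
    table = pd.DataFrame(rows, columns=["class", "tp", "fp", "total"])
    tp_total = int(table["tp"].sum()) if len(table) else 0
    fp_total = int(table["fp"].sum()) if len(table) else 0
    total = tp_total + fp_total
    if total == 0:
        return TpFpSummary(table, 0, 0, 0, None, None)
    return TpFpSummary(
        table,
        tp_total,
        fp_total,
        total,
        round(100.0 * tp_total / total, 2),
        round(100.0 * fp_total / total, 2),
    )


def micro_precision_recall(
    detections: Sequence[Detection],
    dataset_index: DatasetIndex,
    iou_threshold: float = 0.5,
    class_set: Sequence[str] | None = None,
) -> tuple[float, float, dict[str, MatchResult]]:
    """Global (micro-averaged) precision and recall over all classes.

    Returns ``(precision, recall, per_class_matches)``; precision is
    tp/(tp+fp) pooling every class, recall is tp/(tp+fn).
    """
    gts = dataset_index.ground_truths()
    if class_set is None:
        class_set = sorted({g.class_label for g in gts} | {d.class_label for d in detections})
    matches: dict[str, MatchResult] = {}
    tp = fp = fn = 0
    for label in class_set:
        cls_gts = [g for g in gts if g.class_label == label]
        cls_dets = [d for d in detections if d.class_label == label]
        m = match_detections(cls_dets, cls_gts, iou_threshold)
        matches[label] = m
        tp += m.tp
        fp += m.fp
        fn += m.fn
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    return precision, recall, matches
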