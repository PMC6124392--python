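"""Integration unit: combine primary detections with verifier verdicts.

A detection survives refinement iff its class verifier says True; nothing
is relabeled, re-scored or re-localised, and no detection is ever added.
The comparison report quantifies the intended effect — recall is set by
the primary detector (R = TP/(TP+FN)) and the filter bank's job is to
raise precision (P = TP/(TP+FP)) by deleting false positives — via
before/after AP, TP/FP summaries and the recall-retention ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core_io import DatasetIndex, Detection
from .evaluation import (
    APReport,
    TpFpSummary,
    evaluate,
    micro_precision_recall,
    tp_fp_summary,
)
from .filter_bank import VerifierDecision, verify

__all__ = ["RefinementReport", "refine", "compare", "ap_differences"]


@dataclass
class RefinementReport:
    """Before/after metrics of one refinement pass."""

    before_ap: APReport
    after_ap: APReport
    before_summary: TpFpSummary
    after_summary: TpFpSummary
    ap_delta: dict[str, float]
    mean_ap_delta: float
    before_precision: float
    after_precision: float
    before_recall: float
    after_recall: float
    kept_count: int
    dropped_count: int
    recall_retention: float  # after.tp / before.tp

    def to_dict(self) -> dict:
        return {
            "iou_threshold": self.before_ap.iou_threshold,
            "mean_ap_before": self.before_ap.mean_ap,
            "mean_ap_after": self.after_ap.mean_ap,
            "mean_ap_delta": self.mean_ap_delta,
            "ap_before": self.before_ap.per_class,
            "ap_after": self.after_ap.per_class,
            "ap_delta": self.ap_delta,
            "precision_before": self.before_precision,
            "precision_after": self.after_precision,
            "recall_before": self.before_recall,
            "recall_after": self.after_recall,
            "kept": self.kept_count,
            "dropped": self.dropped_count,
            "recall_retention": self.recall_retention,
            "tp_fp_before": {
                "tp": self.before_summary.tp,
                "fp": self.before_summary.fp,
                "tp_share": self.before_summary.tp_share,
                "fp_share": self.before_summary.fp_share,
            },
            "tp_fp_after": {
                "tp": self.after_summary.tp,
                "fp": self.after_summary.fp,
                "tp_share": self.after_summary.tp_share,
                "fp_share": self.after_summary.fp_share,
            },
        }


def refine(
    detections: Sequence[Detection],
    bank,
    dataset_index: DatasetIndex,
) -> tuple[list[Detection], list[VerifierDecision]]:
    """Keep detections whose verifier verdict is True.

    Order, boxes, labels and scores of survivors are preserved exactly;
    the verdict log is aligned with the *input* detections so rejected
    probabilities remain inspectable.
    """
    kept: list[Detection] = []
    log: list[VerifierDecision] = []
    image_cache: dict[str, np.ndarray] = {}
    for det in detections:
        if det.image_id not in image_cache:
            image_cache[det.image_id] = dataset_index[det.image_id].load()
        decision = verify(bank, det, image_cache[det.image_id])
        log.append(decision)
        if decision.verdict:
            kept.append(det)
    return kept, log


def compare(
    before_detections: Sequence[Detection],
    after_detections: Sequence[Detection],
    dataset_index: DatasetIndex,
    iou_threshold: float = 0.5,
    class_set: Sequence[str] | None = None,
) -> RefinementReport:
    """Evaluate both detection sets on the same dataset and threshold and
    report per-class AP deltas (after - before) plus precision/recall."""
    before_ap = evaluate(before_detections, dataset_index, iou_threshold, class_set)
    after_ap = evaluate(after_detections, dataset_index, iou_threshold, class_set)
    delta = ap_differences(before_ap, after_ap)

    p_before, r_before, m_before = micro_precision_recall(
        before_detections, dataset_index, iou_threshold, class_set
    )
    p_after, r_after, m_after = micro_precision_recall(
        after_detections, dataset_index, iou_threshold, class_set
    )
    before_summary = tp_fp_summary(m_before)
    after_summary = tp_fp_summary(m_after)
    tp_before = before_summary.tp
    retention = after_summary.tp / tp_before if tp_before else float("nan")
    return RefinementReport(
        before_ap=before_ap,
        after_ap=after_ap,
        before_summary=before_summary,
        after_summary=after_summary,
        ap_delta=delta,
        mean_ap_delta=after_ap.mean_ap - before_ap.mean_ap,
        before_precision=p_before,
        after_precision=p_after,
        before_recall=r_before,
        after_recall=r_after,
        kept_count=len(after_detections),
        dropped_count=len(before_detections) - len(after_detections),
        recall_retention=retention,
    )


def ap_differences(before: APReport, after: APReport) -> dict[str, float]:
    """Per-class AP difference (after - before) over the shared classes."""
    shared = set(before.per_class) & set(after.per_class)
    return {c: after.per_class[c] - before.per_class[c] for c in sorted(shared)}
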