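"""Published reference statistics of the tomato diseases-and-pests benchmark.

The real greenhouse image collection behind this package's problem setting
is not publicly distributable, but its published summary statistics are:
per-class annotation counts (heavily unbalanced, with a transverse
``background`` class of healthy tissue and scene clutter), the per-class
true-positive / false-positive counts produced by the Faster-R-CNN-style
primary detector at IoU 0.5, and the per-class average precisions of that
baseline detector and of the refinement-filter-bank system built on top of
it.

These numbers serve two roles here: they parameterise the synthetic scene
generator (class frequencies, the ~90/10 TP/FP regime of the primary
detector) and they are the inputs to the summary-arithmetic checks
(totals, percentage shares, mean APs and their differences).
"""

from __future__ import annotations

DISEASE_CLASSES: tuple[str, ...] = (
    "leaf_mold",
    "gray_mold",
    "canker",
    "plague",
    "miner",
    "low_temperature",
    "powdery_mildew",
    "whitefly",
    "nutritional_excess",
    "yellow_leaf_curl",
)

BACKGROUND_CLASS = "background"

#: Annotated bounding-box counts per class, after data augmentation,
#: including the transverse background class.  Total 49,662.
ANNOTATION_COUNTS: dict[str, int] = {
    "leaf_mold": 11922,
    "gray_mold": 2768,
    "canker": 2648,
    "plague": 2570,
    "miner": 5283,
    "low_temperature": 477,
    "powdery_mildew": 338,
    "whitefly": 404,
    "nutritional_excess": 426,
    "yellow_leaf_curl": 3927,
    "background": 18899,
}

#: Primary-detector outcome at IoU threshold 0.5: (true positives, false
#: positives) per disease class.  Pooled, 27,676 TP vs 3,087 FP, i.e. a
#: 89.97% / 10.03% split — the operating regime the detector simulator is
#: calibrated to reproduce.
PRIMARY_TP_FP: dict[str, tuple[int, int]] = {
    "leaf_mold": (11022, 900),
    "gray_mold": (1642, 1126),
    "canker": (2226, 422),
    "plague": (2246, 324),
    "miner": (5198, 85),
    "low_temperature": (426, 51),
    "powdery_mildew": (314, 24),
    "whitefly": (380, 24),
    "yellow_leaf_curl": (3819, 108),
    "nutritional_excess": (403, 23),
}

#: Published per-class 11-point AP of the baseline Faster-R-CNN (VGG-16)
#: detector and of the refined (filter-bank) system.
BASELINE_AP: dict[str, float] = {
    "leaf_mold": 0.9060,
    "gray_mold": 0.7968,
    "canker": 0.8569,
    "plague": 0.8762,
    "miner": 0.8046,
    "low_temperature": 0.7824,
    "powdery_mildew": 0.6556,
    "whitefly": 0.8301,
    "nutritional_excess": 0.8971,
    "yellow_leaf_curl": 0.8500,
}

REFINED_AP: dict[str, float] = {
    "leaf_mold": 0.9205,
    "gray_mold": 0.8910,
    "canker": 0.9376,
    "plague": 0.9710,
    "miner": 0.9947,
    "low_temperature": 0.9821,
    "powdery_mildew": 0.9963,
    "whitefly": 0.9929,
    "nutritional_excess": 0.9893,
    "yellow_leaf_curl": 0.9500,
}


def disease_class_frequencies() -> dict[str, float]:
    """Annotation-count shares renormalised over the 10 disease classes.

    This is the default class-frequency vector of the synthetic scene
    generator, reproducing the benchmark's unbalance regime (leaf mold
    dominates with ~39% of boxes; powdery mildew has ~1%).
    """
    counts = {c: ANNOTATION_COUNTS[c] for c in DISEASE_CLASSES}
    total = sum(counts.values())
    return {c: n / total for c, n in counts.items()}


#: Confusable class pairs observed in the primary detector's failure modes:
#: canker patches detected as plague, gray mold as canker, low temperature
#: as canker.  The scene generator gives these pairs near-identical
#: appearances and the detector simulator's default confusion matrix leaks
#: probability along them.
CONFUSABLE_PAIRS: tuple[tuple[str, str], ...] = (
    ("canker", "plague"),
    ("gray_mold", "canker"),
    ("low_temperature", "canker"),
)
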