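"""Primary diagnosis unit: a pluggable detector contract plus a simulator.

A real region-proposal detector (Faster R-CNN-style) is out of scope here;
instead :func:`simulate_detections` emulates its output statistics so the
refinement stages can be exercised end to end.  Per ground-truth box the
simulator drops a miss with probability ``miss_rate``, jitters the box
edges with Gaussian noise, draws the emitted label from a row-stochastic
confusion matrix (mislabeled emissions are exactly the cross-class false
positives a verifier must catch), and assigns a confidence from a
truncated-Gaussian score model.  Additionally a Poisson number of spurious
boxes per image with random geometry emulates background false alarms.

The default configuration is calibrated so that roughly 10% of emitted
boxes are false positives at IoU 0.5 — the operating point of the
benchmark's primary detector (89.97% TP / 10.03% FP).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Protocol, Sequence

import numpy as np

from . import benchmark_data as bd
from .core_io import Box, DatasetIndex, Detection

__all__ = [
    "ScoreModel",
    "DetectorConfig",
    "default_confusion",
    "calibrate_fp_rate",
    "default_detector_config",
    "simulate_detections",
    "Detector",
    "SimulatedDetector",
]


@dataclass(frozen=True)
class ScoreModel:
    """Truncated-Gaussian confidence models for true and spurious boxes."""

    mean_tp: float = 0.85
    mean_fp: float = 0.55
    sd: float = 0.1

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("score sd must be non-negative")
        for m in (self.mean_tp, self.mean_fp):
            if not 0.0 <= m <= 1.0:
                raise ValueError("score means must lie in [0, 1]")


@dataclass(frozen=True)
class DetectorConfig:
    """Parameters of the simulated primary detector.

    ``confusion`` maps true class -> {emitted class -> probability}; rows
    must sum to 1.  ``fp_rate`` is the Poisson mean of spurious boxes per
    image; spurious geometry is uniform-centred with log-uniform side
    lengths between ``fp_min_side`` and half the image side.
    """

    classes: tuple[str, ...]
    confusion: Mapping[str, Mapping[str, float]]
    loc_jitter_sd: float = 2.0
    miss_rate: float = 0.05
    fp_rate: float = 0.6
    score_model: ScoreModel = field(default_factory=ScoreModel)
    fp_min_side: float = 16.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loc_jitter_sd < 0:
            raise ValueError("loc_jitter_sd must be non-negative")
        if not 0.0 <= self.miss_rate <= 1.0:
            raise ValueError("miss_rate must be in [0, 1]")
        if self.fp_rate < 0:
            raise ValueError("fp_rate must be non-negative")
        for cls in self.classes:
            row = self.confusion.get(cls)
            if row is None:
                raise ValueError(f"confusion matrix lacks a row for {cls!r}")
            total = sum(row.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"confusion row {cls!r} sums to {total}, expected 1")
            unknown = set(row) - set(self.classes)
            if unknown:
                raise ValueError(f"confusion row {cls!r} names unknown classes {unknown}")

    def mislabel_probability(self, class_frequencies: Mapping[str, float]) -> float:
        """Frequency-weighted probability an emitted GT-derived box is mislabeled."""
        return sum(
            class_frequencies.get(c, 0.0) * (1.0 - self.confusion[c].get(c, 0.0))
            for c in self.classes
        )


def default_confusion(
    classes: Sequence[str] = bd.DISEASE_CLASSES,
    pairs: Sequence[tuple[str, str]] = bd.CONFUSABLE_PAIRS,
    leak: float = 0.05,
) -> dict[str, dict[str, float]]:
    """Near-identity confusion leaking ``leak`` along the confusable pairs."""
    conf = {c: {c: 1.0} for c in classes}
    for src, dst in pairs:
        conf[src] = {src: 1.0 - leak, dst: leak}
    return conf


def calibrate_fp_rate(
    confusion: Mapping[str, Mapping[str, float]],
    class_frequencies: Mapping[str, float],
    miss_rate: float,
    boxes_per_image: float,
    target_fp_share: float = 0.1003,
) -> float:
    """Solve the spurious-box Poisson mean so the expected overall FP share
    (mislabeled emissions + spurious boxes) hits ``target_fp_share``.

    With g = (1 - miss_rate) * boxes_per_image GT-derived emissions per
    image of which fraction m are mislabeled, the spurious rate s solves
    (m*g + s) / (g + s) = t, i.e. s = g*(t - m)/(1 - t).
    """
    if not 0.0 < target_fp_share < 1.0:
        raise ValueError("target_fp_share must be in (0, 1)")
    g = (1.0 - miss_rate) * boxes_per_image
    m = sum(
        class_frequencies.get(c, 0.0) * (1.0 - row.get(c, 0.0))
        for c, row in confusion.items()
    )
    s = g * (target_fp_share - m) / (1.0 - target_fp_share)
    if s < 0:
        raise ValueError(
            f"confusion alone already yields FP share {m:.4f} > target {target_fp_share}"
        )
    return s


def default_detector_config(
    classes: Sequence[str] = bd.DISEASE_CLASSES,
    class_frequencies: Mapping[str, float] | None = None,
    boxes_per_image: float = 6.0,
    target_fp_share: float = 0.1003,
    seed: int = 0,
    **overrides,
) -> DetectorConfig:
    """Config with confusable-pair leakage and the FP rate calibrated to the
    benchmark's ~10% false-positive share."""
    if class_frequencies is None:
        class_frequencies = bd.disease_class_frequencies()
    confusion = overrides.pop("confusion", default_confusion(classes))
    miss_rate = overrides.pop("miss_rate", 0.05)
    fp_rate = overrides.pop(
        "fp_rate",
        calibrate_fp_rate(confusion, class_frequencies, miss_rate, boxes_per_image,
                          target_fp_share),
    )
    return DetectorConfig(
        classes=tuple(classes),
        confusion=confusion,
        miss_rate=miss_rate,
        fp_rate=fp_rate,
        seed=seed,
        **overrides,
    )


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0:
        return float(np.clip(mean, 0.0, 1.0))
    for _ in range(100):
        v = rng.normal(mean, sd)
        if 0.0 <= v <= 1.0:
            return float(v)
    return float(np.clip(rng.normal(mean, sd), 0.0, 1.0))


def simulate_detections(
    dataset_index: DatasetIndex,
    config: DetectorConfig,
) -> list[Detection]:
    """Emit simulated detections for every image in the index.

    Deterministic given ``config.seed`` (a single global random stream,
    images visited in sorted image-id order).  Jittered boxes that
    degenerate (area <= 1 px^2 after clamping) are resampled up to 10
    times and then skipped with a warning.
    """
    rng = np.random.default_rng(config.seed)
    class_list = list(config.classes)
    detections: list[Detection] = []
    sm = config.score_model

    for image_id in dataset_index.image_ids:
        rec = dataset_index[image_id]
        w, h = float(rec.width), float(rec.height)
        for gt in rec.boxes:
            if rng.random() < config.miss_rate:
                continue
            box = None
            for _ in range(10):
                jit = rng.normal(0.0, config.loc_jitter_sd, size=4)
                x0 = gt.box.x_min + jit[0]
                y0 = gt.box.y_min + jit[1]
                x1 = gt.box.x_max + jit[2]
                y1 = gt.box.y_max + jit[3]
                x0, x1 = min(x0, x1), max(x0, x1)
                y0, y1 = min(y0, y1), max(y0, y1)
                x0, x1 = max(x0, 0.0), min(x1, w)
                y0, y1 = max(y0, 0.0), min(y1, h)
                if (x1 - x0) * (y1 - y0) > 1.0:
                    box = Box(x0, y0, x1, y1)
                    break
            if box is None:
                warnings.warn(f"degenerate jittered box for {image_id}, skipped")
                continue
            row = config.confusion[gt.class_label]
            emitted_labels = sorted(row)
            p = np.array([row[c] for c in emitted_labels])
            label = emitted_labels[rng.choice(len(emitted_labels), p=p)]
            score = _trunc_normal(rng, sm.mean_tp, sm.sd)
            detections.append(Detection(image_id, box, label, score))

        for _ in range(rng.poisson(config.fp_rate)):
            max_side = min(w, h) / 2.0
            sw = float(np.exp(rng.uniform(np.log(config.fp_min_side), np.log(max_side))))
            sh = float(np.exp(rng.uniform(np.log(config.fp_min_side), np.log(max_side))))
            cx = rng.uniform(0.0, w)
            cy = rng.uniform(0.0, h)
            x0 = max(cx - sw / 2.0, 0.0)
            y0 = max(cy - sh / 2.0, 0.0)
            x1 = min(cx + sw / 2.0, w)
            y1 = min(cy + sh / 2.0, h)
            if (x1 - x0) * (y1 - y0) <= 1.0:
                continue
            label = class_list[rng.choice(len(class_list))]
            score = _trunc_normal(rng, sm.mean_fp, sm.sd)
            detections.append(Detection(image_id, Box(x0, y0, x1, y1), label, score))

    return detections


class Detector(Protocol):
    """Contract for a pluggable primary detector.

    Implementations must be pure given fixed weights/seed: the same image
    yields the same detections, every score lies in [0, 1], and an empty
    result is allowed.
    """

    def __call__(self, image: np.ndarray, image_id: str) -> Sequence[Detection]: ...


@dataclass
class SimulatedDetector:
    """Adapter exposing :func:`simulate_detections` through the per-image
    detector contract (the seed is mixed with the image id for purity)."""

    config: DetectorConfig
    dataset_index: DatasetIndex

    def __post_init__(self) -> None:
        self._all = simulate_detections(self.dataset_index, self.config)

    def __call__(self, image: np.ndarray, image_id: str) -> list[Detection]:
        return [d for d in self._all if d.image_id == image_id]
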