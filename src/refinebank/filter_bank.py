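"""Secondary diagnosis unit: per-class verifier CNNs ("filter bank").

One independent binary CNN per class judges whether a detection of that
class truly depicts it.  Positives are the class's true-positive patches;
negatives are the false positives the primary detector assigned to the
class plus background patches (hard negatives: regions the detector found
plausible, or healthy tissue/scene clutter), sampled up to a 1:1 balance.
Patches are scale-adapted to a small or large canonical square by the
source box's longest side before entering the network.

Adding a class to the system adds exactly one verifier; removing one
never touches the others.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from skimage.transform import resize as sk_resize

from .core_io import (
    Box,
    DatasetIndex,
    Detection,
    GroundTruthBox,
    Patch,
    extract_patch,
)
from .evaluation import MatchResult, iou, match_detections
from .nn import ConvNet, TrainHistory

__all__ = [
    "ScalePolicy",
    "VerifierSpec",
    "LabeledPatchSet",
    "VerifierDecision",
    "Verifier",
    "FilterBankModel",
    "OracleFilterBank",
    "scale_adapt",
    "sample_background_boxes",
    "build_training_set",
    "train_verifier",
    "build_filter_bank",
    "verify",
]


@dataclass(frozen=True)
class ScalePolicy:
    """Two-scale patch canonicalisation.

    Boxes whose longest side is at most ``side_cutoff`` px resize to
    ``small_size``^2, the rest to ``large_size``^2 (bilinear).  Defaults
    are the production 300/500 sizes; test suites shrink them (e.g. 64/96)
    without changing semantics.
    """

    small_size: int = 300
    large_size: int = 500
    side_cutoff: float = 150.0

    def __post_init__(self) -> None:
        if not self.small_size < self.large_size:
            raise ValueError("small_size must be < large_size")
        if self.side_cutoff <= 0:
            raise ValueError("side_cutoff must be positive")

    def target_for(self, box: Box) -> tuple[int, str]:
        if box.max_side <= self.side_cutoff:
            return self.small_size, "small"
        return self.large_size, "large"


@dataclass(frozen=True)
class VerifierSpec:
    """Hyperparameters of one verifier CNN.

    ``conv_depth`` in 1..5 conv blocks (3x3 conv + ReLU + 2x2 pool),
    followed by three fully-connected layers (two hidden + the 2-way
    head).  ``decision_threshold`` converts the verification probability
    into the True/False verdict (>= rule).
    """

    class_label: str = ""
    conv_depth: int = 5
    input_size: int = 64
    base_width: int = 16
    max_width: int = 128
    fc_widths: tuple[int, int] = (256, 64)
    decision_threshold: float = 0.5
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.conv_depth not in (1, 2, 3, 4, 5):
            raise ValueError("conv_depth must be in 1..5")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError("decision_threshold must be in (0, 1)")
        if self.input_size % (2**self.conv_depth) != 0:
            raise ValueError("input_size must be divisible by 2^conv_depth")


@dataclass
class LabeledPatchSet:
    """Positive/negative patches for one class's verifier.

    ``labels`` are 1 for positives (true-target patches) and 0 for
    negatives; ``provenance`` records where each sample came from
    (``tp`` | ``fp`` | ``background``).
    """

    class_label: str
    patches: list[Patch]
    labels: np.ndarray
    provenance: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if not (len(self.patches) == len(self.labels) == len(self.provenance)):
            raise ValueError("patches/labels/provenance length mismatch")

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int(len(self.labels) - self.labels.sum())

    def __len__(self) -> int:
        return len(self.patches)


@dataclass(frozen=True)
class VerifierDecision:
    class_label: str
    probability: float
    verdict: bool


def scale_adapt(patch: Patch, policy: ScalePolicy = ScalePolicy()) -> Patch:
    """Resize a patch to its canonical square per the two-scale policy.

    Routing uses the *source box* side when the patch carries one, else
    the pixel dimensions.  A patch already at its target size and tagged
    passes through pixel-identical.
    """
    if patch.source is not None:
        box = patch.source.box
        target, tag = policy.target_for(box)
    else:
        side = float(max(patch.height, patch.width))
        target, tag = policy.target_for(Box(0, 0, max(side, 1e-3), max(side, 1e-3)))
    if patch.scale_tag == tag and patch.height == target and patch.width == target:
        return patch
    pixels = sk_resize(
        patch.pixels, (target, target, 3), order=1, anti_aliasing=False,
        preserve_range=True,
    ).astype(np.float32)
    return Patch(np.clip(pixels, 0.0, 1.0), source=patch.source, scale_tag=tag)


def _resize_to(pixels: np.ndarray, size: int) -> np.ndarray:
    if pixels.shape[0] == size and pixels.shape[1] == size:
        return pixels.astype(np.float32)
    out = sk_resize(pixels, (size, size, 3), order=1, anti_aliasing=False,
                    preserve_range=True)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def sample_background_boxes(
    dataset_index: DatasetIndex,
    n: int,
    seed: int = 0,
    min_side: int = 24,
    max_side: int = 128,
    max_gt_iou: float = 0.2,
    max_attempts_factor: int = 50,
) -> list[GroundTruthBox]:
    """Sample boxes of healthy background: random geometry with IoU at most
    ``max_gt_iou`` against every annotated box of the image."""
    rng = np.random.default_rng(seed)
    ids = dataset_index.image_ids
    if not ids:
        return []
    out: list[GroundTruthBox] = []
    attempts = 0
    max_attempts = max(n, 1) * max_attempts_factor
    while len(out) < n and attempts < max_attempts:
        attempts += 1
        rec = dataset_index[ids[rng.choice(len(ids))]]
        hi = min(max_side, rec.width, rec.height)
        if hi <= min_side:
            continue
        w = int(rng.integers(min_side, hi + 1))
        h = int(rng.integers(min_side, hi + 1))
        x0 = int(rng.integers(0, rec.width - w + 1))
        y0 = int(rng.integers(0, rec.height - h + 1))
        cand = Box(float(x0), float(y0), float(x0 + w), float(y0 + h))
        if all(iou(cand, gt.box) <= max_gt_iou for gt in rec.boxes):
            out.append(GroundTruthBox(rec.image_id, cand, "background"))
    if len(out) < n:
        warnings.warn(f"sampled only {len(out)}/{n} background boxes")
    return out


def _patch_for(det_or_gt, dataset_index: DatasetIndex, policy: ScalePolicy) -> Patch:
    rec = dataset_index[det_or_gt.image_id]
    patch = extract_patch(rec.load(), det_or_gt.box, source=det_or_gt)
    return scale_adapt(patch, policy)


def build_training_set(
    class_label: str,
    detections: Sequence[Detection],
    match_result: MatchResult,
    dataset_index: DatasetIndex,
    background_boxes: Sequence[GroundTruthBox] = (),
    split_fraction: float = 0.8,
    seed: int = 0,
    scale_policy: ScalePolicy = ScalePolicy(),
) -> tuple[LabeledPatchSet, LabeledPatchSet]:
    """Construct the stratified train/test patch sets for one class.

    Positives are the class's TP detections; negatives its FP detections
    plus background boxes drawn (seeded) to top the negatives up to a 1:1
    balance with the positives.  The split is stratified per label side.
    """
    if not 0.0 < split_fraction < 1.0:
        raise ValueError("split_fraction must be in (0, 1)")
    pos_dets = [d for d in match_result.tp_detections() if d.class_label == class_label]
    neg_dets = [d for d in match_result.fp_detections() if d.class_label == class_label]
    if not pos_dets:
        raise ValueError(f"class {class_label!r} has no true positives to learn from")

    rng = np.random.default_rng(seed)
    backgrounds = list(background_boxes)
    n_fill = max(len(pos_dets) - len(neg_dets), 0)
    if n_fill > 0 and backgrounds:
        take = min(n_fill, len(backgrounds))
        chosen = rng.choice(len(backgrounds), size=take, replace=False)
        bg_chosen = [backgrounds[i] for i in chosen]
    else:
        bg_chosen = []

    samples: list[tuple[Patch, int, str]] = []
    for d in pos_dets:
        samples.append((_patch_for(d, dataset_index, scale_policy), 1, "tp"))
    for d in neg_dets:
        samples.append((_patch_for(d, dataset_index, scale_policy), 0, "fp"))
    for b in bg_chosen:
        samples.append((_patch_for(b, dataset_index, scale_policy), 0, "background"))

    def split(items: list[tuple[Patch, int, str]]):
        idx = rng.permutation(len(items))
        n_train = int(round(split_fraction * len(items)))
        return [items[i] for i in idx[:n_train]], [items[i] for i in idx[n_train:]]

    pos = [s for s in samples if s[1] == 1]
    neg = [s for s in samples if s[1] == 0]
    train_items, test_items = [], []
    for side in (pos, neg):
        tr, te = split(side)
        train_items += tr
        test_items += te

    def pack(items):
        return LabeledPatchSet(
            class_label,
            [p for p, _, _ in items],
            np.array([l for _, l, _ in items], dtype=np.int64),
            [t for _, _, t in items],
        )

    return pack(train_items), pack(test_items)


@dataclass
class Verifier:
    """One trained class verifier: CNN + its spec and scale policy."""

    spec: VerifierSpec
    scale_policy: ScalePolicy
    net: ConvNet
    history: TrainHistory = field(default_factory=TrainHistory)

    def probability(self, patch: Patch) -> float:
        adapted = scale_adapt(patch, self.scale_policy)
        x = _resize_to(adapted.pixels, self.spec.input_size)
        return float(self.net.predict_proba(x)[0])

    def decide(self, patch: Patch) -> VerifierDecision:
        p = self.probability(patch)
        return VerifierDecision(self.spec.class_label, p,
                                p >= self.spec.decision_threshold)


def train_verifier(
    spec: VerifierSpec,
    train_set: LabeledPatchSet,
    test_set: LabeledPatchSet | None = None,
    scale_policy: ScalePolicy = ScalePolicy(),
) -> Verifier:
    """Train one verifier CNN with cross-entropy; deterministic given the
    spec seed.  Both labels must be present in the training set."""
    labels = set(np.unique(train_set.labels).tolist())
    if labels != {0, 1}:
        raise ValueError(
            f"training set for {spec.class_label!r} must contain both labels, got {labels}"
        )
    net = ConvNet(
        input_size=spec.input_size,
        conv_depth=spec.conv_depth,
        base_width=spec.base_width,
        max_width=spec.max_width,
        fc_widths=spec.fc_widths,
        seed=spec.seed,
    )
    x = np.stack([_resize_to(p.pixels, spec.input_size) for p in train_set.patches])
    y = train_set.labels
    kwargs = {}
    if test_set is not None and len(test_set):
        kwargs["x_val"] = np.stack(
            [_resize_to(p.pixels, spec.input_size) for p in test_set.patches]
        )
        kwargs["y_val"] = test_set.labels
    history = net.fit(
        x, y, epochs=spec.epochs, batch_size=spec.batch_size,
        lr=spec.learning_rate, seed=spec.seed, **kwargs
    )
    return Verifier(spec, scale_policy, net, history)


@dataclass
class FilterBankModel:
    """k independent verifiers, one per class.

    ``on_missing`` controls verdicts for classes without a trained
    verifier: ``"error"`` (default) raises; ``"accept"`` passes the
    detection through with probability 1 (used when a class had no
    positives to train on).
    """

    verifiers: dict[str, Verifier] = field(default_factory=dict)
    on_missing: str = "error"

    def __len__(self) -> int:
        return len(self.verifiers)

    @property
    def class_labels(self) -> list[str]:
        return sorted(self.verifiers)

    def add(self, verifier: Verifier) -> None:
        self.verifiers[verifier.spec.class_label] = verifier

    def decide(self, detection: Detection, image: np.ndarray) -> VerifierDecision:
        verifier = self.verifiers.get(detection.class_label)
        if verifier is None:
            if self.on_missing == "accept":
                return VerifierDecision(detection.class_label, 1.0, True)
            raise KeyError(
                f"filter bank has no verifier for class {detection.class_label!r}"
            )
        patch = extract_patch(image, detection.box, source=detection)
        return verifier.decide(patch)

    # -- persistence --------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for label, v in self.verifiers.items():
            spec = {
                "class_label": v.spec.class_label,
                "conv_depth": v.spec.conv_depth,
                "input_size": v.spec.input_size,
                "base_width": v.spec.base_width,
                "max_width": v.spec.max_width,
                "fc_widths": list(v.spec.fc_widths),
                "decision_threshold": v.spec.decision_threshold,
                "epochs": v.spec.epochs,
                "batch_size": v.spec.batch_size,
                "learning_rate": v.spec.learning_rate,
                "seed": v.spec.seed,
                "scale_policy": {
                    "small_size": v.scale_policy.small_size,
                    "large_size": v.scale_policy.large_size,
                    "side_cutoff": v.scale_policy.side_cutoff,
                },
                "train_loss": v.history.train_loss,
                "val_loss": v.history.val_loss,
            }
            (directory / f"{label}.json").write_text(json.dumps(spec, indent=1))
            np.savez(directory / f"{label}.npz", **v.net.state_dict())

    @classmethod
    def load(cls, directory: str | Path, on_missing: str = "error") -> "FilterBankModel":
        directory = Path(directory)
        bank = cls(on_missing=on_missing)
        for spec_path in sorted(directory.glob("*.json")):
            meta = json.loads(spec_path.read_text())
            sp = meta.pop("scale_policy")
            train_loss = meta.pop("train_loss", [])
            val_loss = meta.pop("val_loss", [])
            spec = VerifierSpec(**{k: tuple(v) if k == "fc_widths" else v
                                   for k, v in meta.items()})
            policy = ScalePolicy(**sp)
            net = ConvNet(
                input_size=spec.input_size, conv_depth=spec.conv_depth,
                base_width=spec.base_width, max_width=spec.max_width,
                fc_widths=spec.fc_widths, seed=spec.seed,
            )
            with np.load(spec_path.with_suffix(".npz")) as data:
                net.load_state_dict({k: data[k] for k in data.files})
            history = TrainHistory(train_loss=train_loss, val_loss=val_loss)
            bank.add(Verifier(spec, policy, net, history))
        return bank


@dataclass
class OracleFilterBank:
    """Ground-truth-informed bank for testing: probability 1 on detections
    known to be true positives, 0 otherwise."""

    tp_keys: set[tuple[str, str, tuple[float, float, float, float]]]

    @classmethod
    def from_matches(cls, matches: Mapping[str, MatchResult]) -> "OracleFilterBank":
        keys = set()
        for m in matches.values():
            for d in m.tp_detections():
                keys.add((d.image_id, d.class_label, d.box.as_tuple()))
        return cls(keys)

    def decide(self, detection: Detection, image: np.ndarray) -> VerifierDecision:
        hit = (detection.image_id, detection.class_label,
               detection.box.as_tuple()) in self.tp_keys
        return VerifierDecision(detection.class_label, 1.0 if hit else 0.0, hit)


def verify(bank, detection: Detection, image: np.ndarray) -> VerifierDecision:
    """Score one detection through the bank: extract patch, scale-adapt,
    classify; verdict = probability >= the class verifier's threshold."""
    return bank.decide(detection, image)


def build_filter_bank(
    dataset_index: DatasetIndex,
    detections: Sequence[Detection],
    class_set: Sequence[str],
    iou_threshold: float = 0.5,
    spec_template: VerifierSpec = VerifierSpec(),
    scale_policy: ScalePolicy = ScalePolicy(),
    split_fraction: float = 0.8,
    n_background: int | None = None,
    seed: int = 0,
) -> FilterBankModel:
    """Match detections at ``iou_threshold``, build per-class training sets
    and train one verifier per class.

    Classes with no true-positive detections cannot be trained; they are
    skipped with a warning and the bank accepts their detections
    unjudged (``on_missing='accept'``).
    """
    gts = dataset_index.ground_truths()
    seeds = np.random.SeedSequence(seed).spawn(len(class_set) + 1)
    bg_seed = int(seeds[-1].generate_state(1)[0] % (2**31))
    if n_background is None:
        n_background = max(len(detections) // 2, 32)
    backgrounds = sample_background_boxes(dataset_index, n_background, seed=bg_seed)

    bank = FilterBankModel(on_missing="accept")
    for label, ss in zip(class_set, seeds):
        cls_dets = [d for d in detections if d.class_label == label]
        cls_gts = [g for g in gts if g.class_label == label]
        match = match_detections(cls_dets, cls_gts, iou_threshold)
        cls_seed = int(ss.generate_state(1)[0] % (2**31))
        try:
            train_set, test_set = build_training_set(
                label, cls_dets, match, dataset_index, backgrounds,
                split_fraction=split_fraction, seed=cls_seed,
                scale_policy=scale_policy,
            )
        except ValueError as exc:
            warnings.warn(f"skipping verifier for {label!r}: {exc}")
            continue
        if train_set.n_neg == 0 or train_set.n_pos == 0:
            warnings.warn(
                f"skipping verifier for {label!r}: single-label training set"
            )
            continue
        spec = replace(spec_template, class_label=label, seed=cls_seed)
        bank.add(train_verifier(spec, train_set, test_set, scale_policy))
    return bank
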