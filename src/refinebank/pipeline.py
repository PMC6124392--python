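"""End-to-end orchestration: dataset splits, configuration and the full
scene -> detect -> evaluate -> train filters -> refine -> report pipeline."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import __version__
from . import benchmark_data as bd
from .core_io import DatasetIndex, read_voc_annotations, write_detections
from .detector_sim import default_detector_config, simulate_detections
from .evaluation import iou_sweep
from .filter_bank import ScalePolicy, VerifierSpec, build_filter_bank
from .integration import RefinementReport, compare, refine
from .synth_scenes import SceneSpec, generate_dataset

logger = logging.getLogger("refinebank")

__all__ = ["RunConfig", "split_dataset", "run_pipeline"]


def split_dataset(
    dataset_index: DatasetIndex,
    fractions: Mapping[str, float] | Sequence[float],
    seed: int = 0,
) -> dict[str, list[str]]:
    """Image-level disjoint splits by seeded shuffle + contiguous assignment.

    ``fractions`` must sum to 1 (within 1e-9).  Split sizes are the
    largest-remainder apportionment of the image count, so 10 images at
    (0.8, 0.1, 0.1) give 8/1/1.
    """
    if not isinstance(fractions, Mapping):
        fractions = {f"split_{i}": f for i, f in enumerate(fractions)}
    total = sum(fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"split fractions sum to {total}, expected 1")
    ids = dataset_index.image_ids
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    n = len(ids)
    names = list(fractions)
    raw = np.array([fractions[k] * n for k in names])
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts)):
        if counts.sum() >= n:
            break
        counts[i] += 1
    out: dict[str, list[str]] = {}
    start = 0
    for name, c in zip(names, counts):
        out[name] = order[start : start + c]
        start += c
    return out


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-loadable; flags override)."""

    out_dir: str = "run"
    dataset_dir: str | None = None  # None -> generate synthetic scenes
    n_images: int = 40
    image_size: int = 256
    boxes_per_image: float = 6.0
    classes: tuple[str, ...] = bd.DISEASE_CLASSES
    iou_threshold: float = 0.5
    sweep_thresholds: tuple[float, ...] = tuple(np.round(np.arange(0.1, 0.95, 0.1), 2))
    # detector simulator
    loc_jitter_sd: float = 2.0
    miss_rate: float = 0.05
    fp_rate: float | None = None  # None -> calibrated to ~10% FP share
    confusion_leak: float = 0.05
    # filter bank
    conv_depth: int = 5
    input_size: int = 64
    epochs: int = 8
    batch_size: int = 32
    learning_rate: float = 1e-3
    decision_threshold: float = 0.5
    split_fraction: float = 0.8
    small_size: int = 64
    large_size: int = 96
    side_cutoff: float = 96.0
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("classes", "sweep_thresholds"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["classes"] = list(d["classes"])
        d["sweep_thresholds"] = [float(t) for t in d["sweep_thresholds"]]
        return d


def run_pipeline(config: RunConfig) -> RefinementReport:
    """Run the full refinement pipeline and persist every stage artifact.

    Stages: scene generation (or dataset load) -> simulated primary
    detections -> before-evaluation -> filter-bank training -> refinement
    -> after-evaluation -> report + provenance.  Deterministic given
    ``config.seed``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    seed_of = lambda i: int(seeds[i].generate_state(1)[0] % (2**31))

    def stage(name):
        logger.info("stage %s (t=%.1fs)", name, time.time() - t0)

    try:
        if config.dataset_dir is None:
            stage("synth")
            spec = SceneSpec(
                image_size=config.image_size,
                boxes_per_image=config.boxes_per_image,
                min_box_side=min(32, config.image_size // 4),
                max_box_side=min(160, config.image_size // 2),
                seed=seed_of(0),
            )
            index = generate_dataset(spec, config.n_images, out / "dataset")
        else:
            stage("load-dataset")
            dataset_dir = Path(config.dataset_dir)
            if not dataset_dir.is_dir():
                raise FileNotFoundError(f"dataset directory not found: {dataset_dir}")
            index = read_voc_annotations(dataset_dir / "annotations")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'dataset' failed: {exc}") from exc

    try:
        stage("detect-sim")
        det_config = default_detector_config(
            classes=config.classes,
            boxes_per_image=config.boxes_per_image,
            seed=seed_of(1),
            loc_jitter_sd=config.loc_jitter_sd,
            **({"fp_rate": config.fp_rate} if config.fp_rate is not None else {}),
        )
        detections = simulate_detections(index, det_config)
        write_detections(detections, out / "detections.csv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'detect-sim' failed: {exc}") from exc

    try:
        stage("train-filters")
        policy = ScalePolicy(config.small_size, config.large_size, config.side_cutoff)
        spec_template = VerifierSpec(
            conv_depth=config.conv_depth,
            input_size=config.input_size,
            decision_threshold=config.decision_threshold,
            epochs=config.epochs,
            batch_size=config.batch_size,
            learning_rate=config.learning_rate,
        )
        bank = build_filter_bank(
            index, detections, config.classes,
            iou_threshold=config.iou_threshold,
            spec_template=spec_template,
            scale_policy=policy,
            split_fraction=config.split_fraction,
            seed=seed_of(2),
        )
        bank.save(out / "bank")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'train-filters' failed: {exc}") from exc

    try:
        stage("refine")
        refined, log = refine(detections, bank, index)
        write_detections(refined, out / "refined.csv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'refine' failed: {exc}") from exc

    try:
        stage("report")
        report = compare(detections, refined, index, config.iou_threshold,
                         config.classes)
        sweep = iou_sweep(detections, index, config.sweep_thresholds, config.classes)
        sweep.to_csv(out / "iou_sweep_before.csv", index=False)
        losses = {
            label: {"train": v.history.train_loss, "val": v.history.val_loss}
            for label, v in getattr(bank, "verifiers", {}).items()
        }
        (out / "report.json").write_text(
            json.dumps({**report.to_dict(), "loss_history": losses}, indent=1)
        )
        provenance = {
            "config": config.to_dict(),
            "seed": config.seed,
            "refinebank_version": __version__,
            "stage_seeds": {name: seed_of(i) for i, name in
                            enumerate(["synth", "detect", "filters", "misc"])},
        }
        (out / "provenance.json").write_text(json.dumps(provenance, indent=1))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage 'report' failed: {exc}") from exc

    stage("done")
    return report
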