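"""Seeded synthetic benchmarks: end-to-end refinement and the depth study.

The refinement benchmark measures the package's central claim on the
synthetic surrogate of the tomato benchmark: with a primary detector
calibrated to ~10% false positives, training one verifier CNN per class
and dropping False verdicts should raise micro-averaged precision at IoU
0.5 substantially while retaining almost all true positives.  The depth
study trains verifiers of 1..5 conv layers on a confusable-pair patch
fixture and records final held-out loss per depth.

Problem sizes (200 scenes of 512^2, verifier input 64^2) keep a full run
on one CPU core in minutes; they are the package's reference desk-scale
conditions, not the real benchmark's scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import benchmark_data as bd
from .detector_sim import default_detector_config, simulate_detections
from .evaluation import micro_precision_recall
from .filter_bank import (
    LabeledPatchSet,
    OracleFilterBank,
    ScalePolicy,
    VerifierSpec,
    build_filter_bank,
    train_verifier,
)
from .integration import compare, refine
from .core_io import Patch
from .synth_scenes import (
    SceneSpec,
    default_appearances,
    generate_index,
    render_patch,
)

__all__ = [
    "RefinementBenchmarkResult",
    "run_refinement_benchmark",
    "confusable_patch_sets",
    "run_depth_study",
]


@dataclass
class RefinementBenchmarkResult:
    precision_before: float
    precision_after: float
    recall_before: float
    recall_after: float
    recall_retention: float
    mean_ap_before: float
    mean_ap_after: float
    oracle_precision: float
    oracle_recall_retention: float
    fp_share_before: float
    n_detections: int
    n_images: int
    per_class_ap_delta: dict[str, float] = field(default_factory=dict)


def run_refinement_benchmark(
    n_images: int = 200,
    image_size: int = 512,
    seed: int = 1234,
    input_size: int = 64,
    conv_depth: int = 5,
    epochs: int = 12,
    boxes_per_image: float = 6.0,
    iou_threshold: float = 0.5,
) -> RefinementBenchmarkResult:
    """Generate scenes, simulate the primary detector, train the filter
    bank, refine, and measure before/after precision plus the oracle
    upper bound.  Deterministic given ``seed``."""
    seeds = np.random.SeedSequence(seed).spawn(3)
    seed_of = lambda i: int(seeds[i].generate_state(1)[0] % (2**31))

    spec = SceneSpec(image_size=image_size, boxes_per_image=boxes_per_image,
                     seed=seed_of(0))
    index = generate_index(spec, n_images, keep_arrays=True)

    det_config = default_detector_config(
        boxes_per_image=boxes_per_image, seed=seed_of(1)
    )
    detections = simulate_detections(index, det_config)

    p_before, r_before, matches = micro_precision_recall(
        detections, index, iou_threshold
    )

    # oracle upper bound: keep exactly the TP subset
    oracle = OracleFilterBank.from_matches(matches)
    oracle_kept, _ = refine(detections, oracle, index)
    p_oracle, _, oracle_matches = micro_precision_recall(
        oracle_kept, index, iou_threshold
    )
    tp_before = sum(m.tp for m in matches.values())
    tp_oracle = sum(m.tp for m in oracle_matches.values())

    policy = ScalePolicy(small_size=input_size, large_size=int(input_size * 1.5),
                         side_cutoff=96.0)
    spec_template = VerifierSpec(conv_depth=conv_depth, input_size=input_size,
                                 epochs=epochs)
    bank = build_filter_bank(
        index, detections, bd.DISEASE_CLASSES,
        iou_threshold=iou_threshold,
        spec_template=spec_template,
        scale_policy=policy,
        seed=seed_of(2),
    )

    refined, _ = refine(detections, bank, index)
    report = compare(detections, refined, index, iou_threshold, bd.DISEASE_CLASSES)

    return RefinementBenchmarkResult(
        precision_before=report.before_precision,
        precision_after=report.after_precision,
        recall_before=report.before_recall,
        recall_after=report.after_recall,
        recall_retention=report.recall_retention,
        mean_ap_before=report.before_ap.mean_ap,
        mean_ap_after=report.after_ap.mean_ap,
        oracle_precision=p_oracle,
        oracle_recall_retention=tp_oracle / tp_before if tp_before else float("nan"),
        fp_share_before=1.0 - p_before,
        n_detections=len(detections),
        n_images=n_images,
        per_class_ap_delta=report.ap_delta,
    )


def confusable_patch_sets(
    n_train: int = 400,
    n_test: int = 100,
    patch_size: int = 32,
    seed: int = 7,
    positive_class: str = "canker",
    negative_class: str = "plague",
    noise_scale: float = 1.0,
    density_scale: float = 1.0,
) -> tuple[LabeledPatchSet, LabeledPatchSet]:
    """Patch-level fixture for the confusable pair: positives rendered with
    the positive class's texture recipe, negatives with its confusable
    partner's.  ``noise_scale`` multiplies appearance noise (the
    controllable difficulty axis); ``density_scale`` multiplies spot
    density (small patches otherwise contain too few spots to carry the
    textural difference)."""
    from dataclasses import replace

    apps = default_appearances()
    pos_app = apps[positive_class]
    neg_app = apps[negative_class]
    pos_app = replace(pos_app, noise_sd=pos_app.noise_sd * noise_scale,
                      spot_density=pos_app.spot_density * density_scale)
    neg_app = replace(neg_app, noise_sd=neg_app.noise_sd * noise_scale,
                      spot_density=neg_app.spot_density * density_scale)
    rng = np.random.default_rng(seed)

    def make(n: int) -> tuple[list[Patch], np.ndarray, list[str]]:
        patches, labels, prov = [], [], []
        for i in range(n):
            if i % 2 == 0:
                patches.append(Patch(render_patch(pos_app, patch_size, rng),
                                     scale_tag="small"))
                labels.append(1)
                prov.append("tp")
            else:
                patches.append(Patch(render_patch(neg_app, patch_size, rng),
                                     scale_tag="small"))
                labels.append(0)
                prov.append("fp")
        return patches, np.array(labels), prov

    tr = LabeledPatchSet(positive_class, *make(n_train))
    te = LabeledPatchSet(positive_class, *make(n_test))
    return tr, te


def run_depth_study(
    depths: Sequence[int] = (1, 2, 3, 4, 5),
    n_train: int = 160,
    n_test: int = 400,
    patch_size: int = 32,
    epochs: int = 25,
    seed: int = 7,
    n_replicates: int = 5,
    noise_scale: float = 1.3,
    density_scale: float = 3.0,
) -> dict[int, float]:
    """Mean final held-out loss per conv depth on the confusable fixture.

    The fixture is the canker/plague pair with spot density tripled (so a
    32x32 patch carries enough texture to discriminate) and appearance
    noise scaled up, at a training-set size small enough that shallow
    verifiers overfit.  A single training run's final loss carries
    optimisation noise of the same order as adjacent-depth differences,
    so each depth is trained ``n_replicates`` times with distinct seeds
    and the replicate mean is reported.
    """
    train_set, test_set = confusable_patch_sets(
        n_train=n_train, n_test=n_test, patch_size=patch_size, seed=seed,
        noise_scale=noise_scale, density_scale=density_scale,
    )
    policy = ScalePolicy(small_size=patch_size, large_size=patch_size * 2,
                         side_cutoff=float(patch_size))
    losses: dict[int, float] = {}
    for depth in depths:
        finals = []
        for rep in range(n_replicates):
            spec = VerifierSpec(
                class_label=train_set.class_label, conv_depth=depth,
                input_size=patch_size, epochs=epochs,
                seed=(1000 * seed + rep) % (2**31),
            )
            verifier = train_verifier(spec, train_set, test_set, policy)
            finals.append(verifier.history.val_loss[-1])
        losses[depth] = float(np.mean(finals))
    return losses
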