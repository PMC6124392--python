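"""Synthetic greenhouse-like scenes with class-unbalanced lesion boxes.

The generator renders images whose statistical structure mirrors a real
tomato-disease detection dataset: a textured foliage-like background, a
Poisson number of elliptical "lesion" regions per image with class-specific
colour/spot textures, class frequencies defaulting to the benchmark's
heavily unbalanced annotation shares, and designated confusable class
pairs whose appearances are nearly identical (so that a verifier has a
genuinely hard discrimination job).  Annotations are returned as
ground-truth boxes and can be written as Pascal VOC XML alongside PNGs.

What these scenes do *not* emulate: photorealistic plant morphology,
illumination changes, occlusion, or multi-scale camera variation.  Results
on them bound algorithmic correctness, not field performance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as draw_ellipse
from skimage.transform import resize as sk_resize
from skimage.transform import rotate as sk_rotate

from . import benchmark_data as bd
from .core_io import (
    Box,
    DatasetIndex,
    GroundTruthBox,
    ImageRecord,
    save_image,
    write_voc_annotation,
)

__all__ = [
    "ClassAppearance",
    "SceneSpec",
    "default_appearances",
    "default_scene_spec",
    "generate_scene",
    "generate_index",
    "generate_dataset",
    "render_patch",
    "augment",
    "write_splits",
]


@dataclass(frozen=True)
class ClassAppearance:
    """Procedural texture recipe for one class.

    ``spot_density`` is spots per 10^4 px^2; ``spot_radius`` the (min, max)
    spot radius in px; ``anisotropy`` in [0, 1] elongates spots;
    ``noise_sd`` is per-pixel Gaussian appearance noise.  Confusable pairs
    are produced by giving two classes nearly identical recipes.
    """

    class_label: str
    base_color: tuple[float, float, float]
    spot_color: tuple[float, float, float]
    spot_density: float = 8.0
    spot_radius: tuple[float, float] = (2.0, 5.0)
    anisotropy: float = 0.0
    noise_sd: float = 0.03

    def __post_init__(self) -> None:
        if not 0.0 <= self.anisotropy <= 1.0:
            raise ValueError("anisotropy must be in [0, 1]")
        if self.spot_density < 0 or self.noise_sd < 0:
            raise ValueError("densities and noise must be non-negative")


def default_appearances(noise_sd: float = 0.03) -> dict[str, ClassAppearance]:
    """Eleven appearance profiles: 10 disease classes + background.

    gray_mold/canker and canker/plague intentionally share near-identical
    recipes (the benchmark's observed confusions); the remaining classes
    get well-separated colours.
    """
    a = {
        "leaf_mold": ClassAppearance(
            "leaf_mold", (0.72, 0.68, 0.25), (0.45, 0.40, 0.10), 10.0, (2.0, 5.0), 0.2, noise_sd
        ),
        # confusable trio: canker ~ plague, gray_mold ~ canker
        "gray_mold": ClassAppearance(
            "gray_mold", (0.52, 0.47, 0.40), (0.33, 0.28, 0.24), 7.0, (2.5, 6.0), 0.1, noise_sd
        ),
        "canker": ClassAppearance(
            "canker", (0.55, 0.46, 0.38), (0.34, 0.26, 0.21), 8.0, (2.0, 5.0), 0.3, noise_sd
        ),
        "plague": ClassAppearance(
            "plague", (0.56, 0.44, 0.37), (0.33, 0.25, 0.22), 9.0, (1.5, 4.0), 0.5, noise_sd
        ),
        "miner": ClassAppearance(
            "miner", (0.80, 0.82, 0.55), (0.95, 0.95, 0.85), 5.0, (1.5, 3.0), 0.9, noise_sd
        ),
        "low_temperature": ClassAppearance(
            "low_temperature", (0.45, 0.40, 0.55), (0.30, 0.28, 0.40), 4.0, (3.0, 7.0), 0.1, noise_sd
        ),
        "powdery_mildew": ClassAppearance(
            "powdery_mildew", (0.85, 0.88, 0.80), (0.97, 0.97, 0.95), 12.0, (1.5, 3.5), 0.0, noise_sd
        ),
        "whitefly": ClassAppearance(
            "whitefly", (0.35, 0.60, 0.30), (0.95, 0.95, 0.90), 6.0, (1.0, 2.5), 0.2, noise_sd
        ),
        "nutritional_excess": ClassAppearance(
            "nutritional_excess", (0.25, 0.45, 0.65), (0.15, 0.30, 0.50), 6.0, (2.5, 6.0), 0.0, noise_sd
        ),
        "yellow_leaf_curl": ClassAppearance(
            "yellow_leaf_curl", (0.90, 0.80, 0.30), (0.75, 0.60, 0.15), 8.0, (2.0, 4.5), 0.4, noise_sd
        ),
        bd.BACKGROUND_CLASS: ClassAppearance(
            bd.BACKGROUND_CLASS, (0.22, 0.42, 0.20), (0.15, 0.32, 0.14), 3.0, (3.0, 8.0), 0.3, noise_sd
        ),
    }
    return a


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic-scene distribution.

    ``class_frequencies`` default to the benchmark's annotation shares
    renormalised over the 10 disease classes; ``boxes_per_image`` is the
    Poisson mean of lesions per scene.
    """

    image_size: int = 512
    class_frequencies: Mapping[str, float] = field(
        default_factory=bd.disease_class_frequencies
    )
    boxes_per_image: float = 6.0
    min_box_side: int = 32
    max_box_side: int = 160
    background_smoothness: float = 8.0
    max_mutual_overlap: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        freqs = dict(self.class_frequencies)
        total = sum(freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class frequencies sum to {total}, expected 1")
        if self.max_box_side >= self.image_size:
            raise ValueError("box sides must fit inside the image")
        object.__setattr__(self, "class_frequencies", freqs)


def default_scene_spec(**overrides) -> SceneSpec:
    return replace(SceneSpec(), **overrides) if overrides else SceneSpec()


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _render_background(size: int, app: ClassAppearance, rng: np.random.Generator,
                       smoothness: float) -> np.ndarray:
    base = np.asarray(app.base_color, dtype=np.float32)
    noise = rng.normal(0.0, 1.0, size=(size, size, 3)).astype(np.float32)
    for c in range(3):
        noise[:, :, c] = gaussian_filter(noise[:, :, c], smoothness)
    # smoothing shrinks the sd by ~2*sqrt(pi)*sigma; rescale to a visible
    # low-frequency mottle then add fine pixel noise
    noise *= 12.0 * app.noise_sd * smoothness
    img = base[None, None, :] + noise
    img += rng.normal(0.0, app.noise_sd, size=img.shape).astype(np.float32)
    return np.clip(img, 0.0, 1.0)


def _texture_tile(app: ClassAppearance, h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    """Render one class texture of shape (h, w, 3) in [0, 1]."""
    base = np.asarray(app.base_color, dtype=np.float32)
    tile = np.empty((h, w, 3), dtype=np.float32)
    tile[:] = base
    # low-frequency mottling so patches are not flat colour
    low = rng.normal(0.0, 1.0, size=(h, w, 1)).astype(np.float32)
    low[:, :, 0] = gaussian_filter(low[:, :, 0], max(min(h, w) / 12.0, 1.0))
    tile += low * (4.0 * app.noise_sd)
    n_spots = rng.poisson(app.spot_density * h * w / 1e4)
    spot = np.asarray(app.spot_color, dtype=np.float32)
    r_lo, r_hi = app.spot_radius
    for _ in range(n_spots):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        r = rng.uniform(r_lo, r_hi)
        r_major = r * (1.0 + 2.0 * app.anisotropy)
        angle = rng.uniform(0, np.pi)
        rr, cc = draw_ellipse(cy, cx, r_major, r, shape=(h, w), rotation=angle)
        alpha = rng.uniform(0.5, 0.9)
        tile[rr, cc] = (1 - alpha) * tile[rr, cc] + alpha * spot
    tile += rng.normal(0.0, app.noise_sd, size=tile.shape).astype(np.float32)
    return np.clip(tile, 0.0, 1.0)


def render_patch(app: ClassAppearance, size: int, rng: np.random.Generator) -> np.ndarray:
    """Standalone square texture patch of one class (float32, [0, 1]).

    Used for patch-level fixtures (e.g. confusable-pair training studies)
    without generating full scenes.
    """
    return _texture_tile(app, size, size, rng)


def _overlap_fraction(a: Box, b: Box) -> float:
    inter = a.intersection_area(b)
    return inter / min(a.area, b.area)


def generate_scene(
    spec: SceneSpec,
    appearances: Mapping[str, ClassAppearance] | None = None,
    seed: int | None = None,
    image_id: str = "scene",
) -> tuple[np.ndarray, list[GroundTruthBox]]:
    """Render one scene: uint8 image plus its ground-truth boxes.

    Lesion boxes are placed rejecting >``max_mutual_overlap`` pairwise
    overlap (intersection over the smaller box); each is filled with an
    inscribed ellipse of its class texture so the box is the tight
    axis-aligned bound of the lesion.  Deterministic given the seed.
    """
    if appearances is None:
        appearances = default_appearances()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    size = spec.image_size
    labels = [c for c, f in spec.class_frequencies.items() if f > 0]
    for lab in labels:
        if lab not in appearances:
            raise KeyError(f"no appearance for class {lab!r}")
    probs = np.array([spec.class_frequencies[c] for c in labels])

    img = _render_background(size, appearances[bd.BACKGROUND_CLASS], rng,
                             spec.background_smoothness)

    n_boxes = rng.poisson(spec.boxes_per_image)
    boxes: list[GroundTruthBox] = []
    placed: list[Box] = []
    for _ in range(n_boxes):
        label = labels[rng.choice(len(labels), p=probs)]
        box = None
        for _attempt in range(100):
            w = int(rng.integers(spec.min_box_side, spec.max_box_side + 1))
            h = int(rng.integers(spec.min_box_side, spec.max_box_side + 1))
            x0 = int(rng.integers(0, size - w + 1))
            y0 = int(rng.integers(0, size - h + 1))
            cand = Box(float(x0), float(y0), float(x0 + w), float(y0 + h))
            if all(_overlap_fraction(cand, p) <= spec.max_mutual_overlap for p in placed):
                box = cand
                break
        if box is None:
            warnings.warn(
                f"could not place a {label} box after 100 attempts; "
                f"scene {image_id} has fewer boxes than drawn"
            )
            continue
        y0, y1 = int(box.y_min), int(box.y_max)
        x0, x1 = int(box.x_min), int(box.x_max)
        h, w = y1 - y0, x1 - x0
        tile = _texture_tile(appearances[label], h, w, rng)
        # inscribed ellipse touching all four box edges -> tight bbox
        yy, xx = np.mgrid[0:h, 0:w]
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        mask = (((yy - cy) / (h / 2.0)) ** 2 + ((xx - cx) / (w / 2.0)) ** 2) <= 1.0
        region = img[y0:y1, x0:x1]
        region[mask] = tile[mask]
        placed.append(box)
        boxes.append(GroundTruthBox(image_id, box, label))

    return (np.clip(img * 255.0, 0, 255).astype(np.uint8), boxes)


def generate_index(
    spec: SceneSpec,
    n_images: int,
    seed: int | None = None,
    appearances: Mapping[str, ClassAppearance] | None = None,
    keep_arrays: bool = True,
) -> DatasetIndex:
    """Generate ``n_images`` scenes into an in-memory :class:`DatasetIndex`."""
    root_seed = spec.seed if seed is None else seed
    seeds = np.random.SeedSequence(root_seed).spawn(n_images)
    index = DatasetIndex()
    for i, ss in enumerate(seeds):
        image_id = f"scene_{i:05d}"
        img, boxes = generate_scene(
            spec, appearances, seed=int(ss.generate_state(1)[0] % (2**31)), image_id=image_id
        )
        index.images[image_id] = ImageRecord(
            image_id=image_id,
            width=spec.image_size,
            height=spec.image_size,
            boxes=boxes,
            array=img if keep_arrays else None,
        )
    return index


def generate_dataset(
    spec: SceneSpec,
    n_images: int,
    out_dir: str | Path,
    seed: int | None = None,
    appearances: Mapping[str, ClassAppearance] | None = None,
    split_fractions: Mapping[str, float] | None = None,
) -> DatasetIndex:
    """Generate scenes to disk: ``images/*.png``, ``annotations/*.xml`` and a
    ``splits.json`` with disjoint train/val/test image-id sets (80/10/10 by
    default).  Deterministic given the seed, including the split."""
    from .pipeline import split_dataset  # local import: avoid cycle

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "annotations").mkdir(parents=True, exist_ok=True)
    index = generate_index(spec, n_images, seed=seed, appearances=appearances)
    for image_id in index.image_ids:
        rec = index[image_id]
        img_path = out / "images" / f"{image_id}.png"
        save_image(rec.array, img_path)
        rec.path = img_path
        write_voc_annotation(rec, out / "annotations" / f"{image_id}.xml")
        rec.array = None  # pixels live on disk now
    fractions = dict(split_fractions or {"train": 0.8, "val": 0.1, "test": 0.1})
    splits = split_dataset(index, fractions, seed=spec.seed if seed is None else seed)
    write_splits(splits, out / "splits.json")
    return index


def write_splits(splits: Mapping[str, Sequence[str]], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps({k: list(v) for k, v in splits.items()}, indent=1), encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------


def augment(
    image: np.ndarray,
    boxes: Sequence[GroundTruthBox],
    ops_config: Mapping[str, object],
    seed: int = 0,
) -> tuple[np.ndarray, list[GroundTruthBox]]:
    """Apply a configured subset of the standard augmentation transforms.

    Geometric: ``resize`` (scale factor), ``crop`` ((x0, y0, w, h)),
    ``rotation`` (degrees, about the image centre; boxes become the
    axis-aligned bound of their rotated corners), ``hflip`` (bool).
    Intensity: ``contrast`` (factor), ``brightness`` (additive, [0,1]
    scale), ``color`` (per-channel factors), ``noise`` (Gaussian sd).
    Intensity ops leave boxes untouched.  Crops drop boxes retaining
    <25% of their area.  Deterministic given ``seed``.
    """
    known = {"resize", "crop", "rotation", "hflip", "contrast", "brightness", "color", "noise"}
    unknown = set(ops_config) - known
    if unknown:
        raise ValueError(f"unknown augmentation ops: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    img = image.astype(np.float32) / 255.0 if image.dtype == np.uint8 else image.astype(np.float32)
    out_boxes = list(boxes)
    h, w = img.shape[:2]

    def remap(fn) -> None:
        nonlocal out_boxes
        new = []
        for gt in out_boxes:
            b = fn(gt.box)
            if b is not None:
                new.append(GroundTruthBox(gt.image_id, b, gt.class_label))
        out_boxes = new

    if "resize" in ops_config:
        s = float(ops_config["resize"])
        if s <= 0:
            raise ValueError("resize factor must be positive")
        nh, nw = max(int(round(h * s)), 1), max(int(round(w * s)), 1)
        img = sk_resize(img, (nh, nw, 3), order=1, anti_aliasing=s < 1, preserve_range=True)
        sy, sx = nh / h, nw / w
        remap(lambda b: Box(b.x_min * sx, b.y_min * sy, b.x_max * sx, b.y_max * sy))
        h, w = nh, nw

    if "hflip" in ops_config and ops_config["hflip"]:
        img = img[:, ::-1].copy()
        remap(lambda b: Box(w - b.x_max, b.y_min, w - b.x_min, b.y_max))

    if "rotation" in ops_config:
        angle = float(ops_config["rotation"])
        img = sk_rotate(img, angle, resize=False, order=1, mode="edge", preserve_range=True)
        theta = np.deg2rad(angle)
        # skimage rotates counter-clockwise about the centre in (row, col);
        # in x/y image coordinates (y down) a point maps through the
        # inverse-of-display rotation below.
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
        cos_t, sin_t = np.cos(theta), np.sin(theta)

        def rot_box(b: Box) -> Box | None:
            xs = np.array([b.x_min, b.x_max, b.x_min, b.x_max]) - 0.5 - cx
            ys = np.array([b.y_min, b.y_min, b.y_max, b.y_max]) - 0.5 - cy
            xr = cos_t * xs + sin_t * ys + cx + 0.5
            yr = -sin_t * xs + cos_t * ys + cy + 0.5
            x0, x1 = float(xr.min()), float(xr.max())
            y0, y1 = float(yr.min()), float(yr.max())
            try:
                return Box(max(x0, 0.0), max(y0, 0.0), min(x1, w), min(y1, h))
            except ValueError:
                return None

        remap(rot_box)

    if "crop" in ops_config:
        x0, y0, cw, ch = (int(v) for v in ops_config["crop"])  # type: ignore[misc]
        if cw > w or ch > h or x0 < 0 or y0 < 0 or x0 + cw > w or y0 + ch > h:
            raise ValueError("crop window exceeds image bounds")
        img = img[y0 : y0 + ch, x0 : x0 + cw].copy()

        def crop_box(b: Box) -> Box | None:
            nx0 = max(b.x_min - x0, 0.0)
            ny0 = max(b.y_min - y0, 0.0)
            nx1 = min(b.x_max - x0, float(cw))
            ny1 = min(b.y_max - y0, float(ch))
            if nx1 <= nx0 or ny1 <= ny0:
                return None
            kept = (nx1 - nx0) * (ny1 - ny0)
            if kept < 0.25 * b.area:
                return None
            return Box(nx0, ny0, nx1, ny1)

        remap(crop_box)
        h, w = ch, cw

    if "contrast" in ops_config:
        f = float(ops_config["contrast"])
        img = (img - 0.5) * f + 0.5
    if "brightness" in ops_config:
        img = img + float(ops_config["brightness"])
    if "color" in ops_config:
        factors = np.asarray(ops_config["color"], dtype=np.float32).reshape(1, 1, 3)
        img = img * factors
    if "noise" in ops_config:
        img = img + rng.normal(0.0, float(ops_config["noise"]), size=img.shape)

    img = np.clip(img, 0.0, 1.0)
    if image.dtype == np.uint8:
        img = np.round(img * 255.0).astype(np.uint8)
    return img, out_boxes
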