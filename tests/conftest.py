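import numpy as np
import pytest

from refinebank.core_io import Box, DatasetIndex, Detection, GroundTruthBox, ImageRecord
from refinebank.synth_scenes import SceneSpec, default_appearances, generate_index


@pytest.fixture(scope="session")
def small_index() -> DatasetIndex:
    """A handful of small synthetic scenes with pixels held in memory."""
    spec = SceneSpec(image_size=192, boxes_per_image=5.0, max_box_side=96, seed=11)
    return generate_index(spec, 8, keep_arrays=True)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def make_detection(image_id, x0, y0, x1, y1, label, score):
    return Detection(image_id, Box(x0, y0, x1, y1), label, score)


def make_gt(image_id, x0, y0, x1, y1, label):
    return GroundTruthBox(image_id, Box(x0, y0, x1, y1), label)


def geometry_index(
    n_images: int,
    class_frequencies: dict[str, float],
    boxes_per_image: float = 6.0,
    image_size: int = 256,
    seed: int = 0,
) -> DatasetIndex:
    """Random ground-truth geometry without rendering any pixels — enough
    for matching/statistics tests that never look at an image."""
    rng = np.random.default_rng(seed)
    labels = list(class_frequencies)
    probs = np.array([class_frequencies[c] for c in labels])
    index = DatasetIndex()
    for i in range(n_images):
        image_id = f"g{i:05d}"
        rec = ImageRecord(image_id, image_size, image_size)
        for _ in range(rng.poisson(boxes_per_image)):
            w = rng.integers(32, 97)
            h = rng.integers(32, 97)
            x0 = rng.integers(0, image_size - w + 1)
            y0 = rng.integers(0, image_size - h + 1)
            label = labels[rng.choice(len(labels), p=probs)]
            rec.boxes.append(
                GroundTruthBox(image_id, Box(float(x0), float(y0),
                                             float(x0 + w), float(y0 + h)), label)
            )
        index.images[image_id] = rec
    return index


@pytest.fixture()
def single_image_index() -> DatasetIndex:
    """One 100x100 image with two ground-truth boxes, no pixels needed."""
    rec = ImageRecord(
        image_id="img0",
        width=100,
        height=100,
        boxes=[
            make_gt("img0", 10, 10, 40, 40, "canker"),
            make_gt("img0", 60, 60, 90, 90, "plague"),
        ],
        array=np.zeros((100, 100, 3), dtype=np.uint8),
    )
    return DatasetIndex({"img0": rec})
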