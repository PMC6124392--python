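"""Domain types and I/O for detection datasets.

Coordinate convention
---------------------
Boxes are stored 0-based with half-open pixel intervals
``[x_min, x_max) x [y_min, y_max)`` and the origin at the top-left corner,
so ``area = (x_max - x_min) * (y_max - y_min)`` exactly.  Pascal VOC XML
uses 1-based *inclusive* pixel coordinates; the readers and writers here
convert between the two dialects losslessly
(``x_min_internal = xmin_voc - 1``, ``x_max_internal = xmax_voc``).

Coordinates are kept as floats internally (detector simulation produces
sub-pixel jitter) and rounded to two decimals when serialised to CSV.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from lxml import etree
from PIL import Image

__all__ = [
    "Box",
    "GroundTruthBox",
    "Detection",
    "ImageRecord",
    "DatasetIndex",
    "Patch",
    "read_voc_annotations",
    "write_voc_annotation",
    "read_detections",
    "write_detections",
    "load_image",
    "extract_patch",
]


@dataclass(frozen=True)
class Box:
    """Axis-aligned rectangle, half-open pixel intervals, origin top-left."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(
                f"degenerate box: ({self.x_min}, {self.y_min}, "
                f"{self.x_max}, {self.y_max}) must have strictly positive area"
            )
        if min(self.x_min, self.y_min) < 0:
            raise ValueError("box coordinates must be non-negative")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def max_side(self) -> float:
        return max(self.width, self.height)

    def intersection_area(self, other: "Box") -> float:
        iw = min(self.x_max, other.x_max) - max(self.x_min, other.x_min)
        ih = min(self.y_max, other.y_max) - max(self.y_min, other.y_min)
        if iw <= 0 or ih <= 0:
            return 0.0
        return iw * ih

    def clamped(self, width: float, height: float) -> "Box":
        """Clamp to image bounds ``[0, width) x [0, height)``.

        Raises ``ValueError`` if nothing remains inside the image.
        """
        x0 = min(max(self.x_min, 0.0), width)
        y0 = min(max(self.y_min, 0.0), height)
        x1 = min(max(self.x_max, 0.0), width)
        y1 = min(max(self.y_max, 0.0), height)
        if x1 <= x0 or y1 <= y0:
            raise ValueError("box lies entirely outside the image")
        return Box(x0, y0, x1, y1)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)


@dataclass(frozen=True)
class GroundTruthBox:
    """One annotated region: the reference against which detections are judged."""

    image_id: str
    box: Box
    class_label: str


@dataclass(frozen=True)
class Detection:
    """One detector output: a box, a single class label and a confidence score."""

    image_id: str
    box: Box
    class_label: str
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")


@dataclass
class ImageRecord:
    """One image of a dataset: pixels on disk and/or in memory plus its boxes."""

    image_id: str
    width: int
    height: int
    boxes: list[GroundTruthBox] = field(default_factory=list)
    path: Path | None = None
    array: np.ndarray | None = None  # uint8 H x W x 3, optional in-memory cache

    def load(self) -> np.ndarray:
        """Return the image as uint8 ``H x W x 3``."""
        if self.array is not None:
            return self.array
        if self.path is None:
            raise FileNotFoundError(
                f"image {self.image_id!r} has neither pixels in memory nor a path"
            )
        return load_image(self.path)


@dataclass
class DatasetIndex:
    """Mapping image_id -> :class:`ImageRecord` for a whole dataset."""

    images: dict[str, ImageRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.images)

    def __iter__(self) -> Iterator[ImageRecord]:
        return iter(self.images.values())

    def __getitem__(self, image_id: str) -> ImageRecord:
        return self.images[image_id]

    def __contains__(self, image_id: str) -> bool:
        return image_id in self.images

    @property
    def image_ids(self) -> list[str]:
        return sorted(self.images)

    def ground_truths(self) -> list[GroundTruthBox]:
        out: list[GroundTruthBox] = []
        for image_id in self.image_ids:
            out.extend(self.images[image_id].boxes)
        return out

    def class_labels(self) -> list[str]:
        return sorted({gt.class_label for gt in self.ground_truths()})

    def subset(self, image_ids: Iterable[str]) -> "DatasetIndex":
        ids = list(image_ids)
        missing = [i for i in ids if i not in self.images]
        if missing:
            raise KeyError(f"unknown image ids: {missing}")
        return DatasetIndex({i: self.images[i] for i in ids})


@dataclass
class Patch:
    """Pixels cut out of an image for one box, values in [0, 1].

    ``scale_tag`` is set by scale adaptation (``small`` / ``large``) and is
    ``None`` straight after extraction.
    """

    pixels: np.ndarray  # float32 H x W x 3 in [0, 1]
    source: Detection | GroundTruthBox | None = None
    scale_tag: str | None = None

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


# ---------------------------------------------------------------------------
# Pascal VOC annotations
# ---------------------------------------------------------------------------


def _voc_to_internal(xmin: float, ymin: float, xmax: float, ymax: float) -> Box:
    return Box(xmin - 1.0, ymin - 1.0, float(xmax), float(ymax))


def _internal_to_voc(box: Box) -> tuple[float, float, float, float]:
    return (box.x_min + 1.0, box.y_min + 1.0, box.x_max, box.y_max)


def read_voc_annotations(
    directory_path: str | Path,
    class_set: Sequence[str] | None = None,
    *,
    permissive: bool = False,
    background_label: str = "background",
    image_dir: str | Path | None = None,
) -> DatasetIndex:
    """Read a directory of Pascal VOC XML files into a :class:`DatasetIndex`.

    VOC's 1-based inclusive ``<bndbox>`` coordinates are converted to the
    internal 0-based half-open convention.  ``class_set``, when given,
    restricts ``<object><name>`` values; an unknown name raises unless
    ``permissive`` is set, in which case it is mapped to ``background_label``.

    Image files are looked up via the ``<path>`` element or, failing that,
    in ``image_dir`` (default: a sibling ``images/`` directory); a record
    whose image file is absent keeps ``path=None`` so that purely geometric
    work needs no pixels.
    """
    directory = Path(directory_path)
    if not directory.is_dir():
        raise FileNotFoundError(f"annotation directory not found: {directory}")
    if image_dir is None:
        image_dir = directory.parent / "images"
    image_dir = Path(image_dir)

    index = DatasetIndex()
    for xml_path in sorted(directory.glob("*.xml")):
        try:
            tree = etree.parse(str(xml_path))
        except etree.XMLSyntaxError as exc:
            raise ValueError(f"corrupt VOC XML {xml_path}: {exc}") from exc
        root = tree.getroot()
        filename = root.findtext("filename") or xml_path.with_suffix(".png").name
        image_id = Path(filename).stem
        size = root.find("size")
        if size is None:
            raise ValueError(f"VOC XML {xml_path} lacks a <size> element")
        width = int(size.findtext("width"))
        height = int(size.findtext("height"))
        if width <= 0 or height <= 0:
            raise ValueError(f"VOC XML {xml_path}: non-positive image size")

        path_text = root.findtext("path")
        img_path: Path | None = None
        if path_text and Path(path_text).is_file():
            img_path = Path(path_text)
        elif (image_dir / filename).is_file():
            img_path = image_dir / filename

        record = ImageRecord(image_id=image_id, width=width, height=height, path=img_path)
        for obj in root.findall("object"):
            name = obj.findtext("name")
            if class_set is not None and name not in class_set:
                if permissive:
                    name = background_label
                else:
                    raise ValueError(
                        f"VOC XML {xml_path}: unknown class {name!r} "
                        f"(known: {sorted(class_set)})"
                    )
            bnd = obj.find("bndbox")
            if bnd is None:
                raise ValueError(f"VOC XML {xml_path}: <object> without <bndbox>")
            xmin = float(bnd.findtext("xmin"))
            ymin = float(bnd.findtext("ymin"))
            xmax = float(bnd.findtext("xmax"))
            ymax = float(bnd.findtext("ymax"))
            if xmax <= xmin - 1 or ymax <= ymin - 1:
                raise ValueError(f"VOC XML {xml_path}: degenerate box")
            box = _voc_to_internal(xmin, ymin, xmax, ymax).clamped(width, height)
            record.boxes.append(GroundTruthBox(image_id, box, name))
        index.images[image_id] = record
    return index


def write_voc_annotation(record: ImageRecord, xml_path: str | Path) -> None:
    """Write one image's annotations as Pascal VOC XML (1-based inclusive)."""
    root = etree.Element("annotation")
    etree.SubElement(root, "folder").text = "images"
    etree.SubElement(root, "filename").text = f"{record.image_id}.png"
    # no <path> element: keeps annotation files relocatable and runs with
    # identical seeds byte-identical; the reader falls back to images/
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(record.width)
    etree.SubElement(size, "height").text = str(record.height)
    etree.SubElement(size, "depth").text = "3"
    for gt in record.boxes:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = gt.class_label
        etree.SubElement(obj, "difficult").text = "0"
        bnd = etree.SubElement(obj, "bndbox")
        xmin, ymin, xmax, ymax = _internal_to_voc(gt.box)
        # VOC stores integers; generated scenes use integer box edges.
        etree.SubElement(bnd, "xmin").text = _fmt_voc(xmin)
        etree.SubElement(bnd, "ymin").text = _fmt_voc(ymin)
        etree.SubElement(bnd, "xmax").text = _fmt_voc(xmax)
        etree.SubElement(bnd, "ymax").text = _fmt_voc(ymax)
    tree = etree.ElementTree(root)
    tree.write(str(xml_path), pretty_print=True, encoding="utf-8")


def _fmt_voc(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


# ---------------------------------------------------------------------------
# Detections CSV / JSON
# ---------------------------------------------------------------------------

_DET_FIELDS = ["image_id", "class", "score", "x_min", "y_min", "x_max", "y_max"]


def read_detections(file_path: str | Path) -> list[Detection]:
    """Read detections from CSV (header ``image_id,class,score,x_min,...``)
    or a JSON array of objects with the same keys, in file order."""
    path = Path(file_path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text(encoding="utf-8"))
        if not isinstance(rows, list):
            raise ValueError(f"{path}: JSON detections must be an array")
        return [_row_to_detection(row, f"{path}[{i}]") for i, row in enumerate(rows)]

    detections: list[Detection] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _DET_FIELDS:
            raise ValueError(
                f"{path}: expected header {','.join(_DET_FIELDS)}, "
                f"got {reader.fieldnames}"
            )
        for i, row in enumerate(reader, start=2):
            detections.append(_row_to_detection(row, f"{path}:{i}"))
    return detections


def _row_to_detection(row: Mapping[str, object], where: str) -> Detection:
    try:
        score = float(row["score"])  # type: ignore[index]
        box = Box(
            float(row["x_min"]), float(row["y_min"]),  # type: ignore[index]
            float(row["x_max"]), float(row["y_max"]),  # type: ignore[index]
        )
        return Detection(str(row["image_id"]), box, str(row["class"]), score)
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"malformed detection at {where}: {exc}") from exc


def write_detections(detections: Sequence[Detection], file_path: str | Path) -> None:
    """Inverse of :func:`read_detections`; coordinates rounded to 2 decimals."""
    path = Path(file_path)
    if path.suffix.lower() == ".json":
        rows = [
            {
                "image_id": d.image_id,
                "class": d.class_label,
                "score": round(d.score, 6),
                "x_min": round(d.box.x_min, 2),
                "y_min": round(d.box.y_min, 2),
                "x_max": round(d.box.x_max, 2),
                "y_max": round(d.box.y_max, 2),
            }
            for d in detections
        ]
        path.write_text(json.dumps(rows, indent=1), encoding="utf-8")
        return
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_DET_FIELDS)
        for d in detections:
            writer.writerow(
                [
                    d.image_id,
                    d.class_label,
                    f"{d.score:.6f}",
                    f"{d.box.x_min:.2f}",
                    f"{d.box.y_min:.2f}",
                    f"{d.box.x_max:.2f}",
                    f"{d.box.y_max:.2f}",
                ]
            )


# ---------------------------------------------------------------------------
# Images and patches
# ---------------------------------------------------------------------------


def load_image(path: str | Path) -> np.ndarray:
    """Load a PNG/JPEG as uint8 ``H x W x 3``."""
    with Image.open(path) as img:
        return np.asarray(img.convert("RGB"))


def save_image(array: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(array, dtype=np.uint8)).save(path)


def extract_patch(
    image: np.ndarray, box: Box, source: Detection | GroundTruthBox | None = None
) -> Patch:
    """Cut the pixels under ``box`` out of ``image`` (no resampling).

    The box is clamped to the image bounds first; a box with zero overlap
    raises.  Pixel indices are the integer grid covering the clamped box
    (floor of the lower edge, ceil of the upper), so the patch dimensions
    equal the clamped box dimensions for integer-edged boxes.
    """
    height, width = image.shape[:2]
    clamped = box.clamped(float(width), float(height))
    x0 = int(math.floor(clamped.x_min))
    y0 = int(math.floor(clamped.y_min))
    x1 = min(int(math.ceil(clamped.x_max)), width)
    y1 = min(int(math.ceil(clamped.y_max)), height)
    if x1 <= x0 or y1 <= y0:
        raise ValueError("box has no pixel overlap with the image")
    pixels = image[y0:y1, x0:x1]
    if pixels.dtype == np.uint8:
        pixels = pixels.astype(np.float32) / 255.0
    else:
        pixels = np.clip(pixels.astype(np.float32), 0.0, 1.0)
    if pixels.ndim == 2:
        pixels = np.repeat(pixels[:, :, None], 3, axis=2)
    return Patch(pixels=np.ascontiguousarray(pixels), source=source)
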