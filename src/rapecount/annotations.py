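"""Annotation handling for rape-flower-cluster plot images.

Two labeling dialects are supported, mirroring the common field practice of
annotating flower clusters either with tight rectangular boxes (LabelImg /
Pascal VOC XML) or with a single centroid dot per cluster (point lists in CSV
or JSON). Boxes are converted to centroids for density-map training; the
count ``N`` is always the number of annotation records.

Coordinate convention: 0-based pixels, origin at the image's top-left corner,
x increasing rightward (columns), y increasing downward (rows). Box intervals
are treated as closed ``[xmin, xmax]`` so the midpoint formula is exact.
"""

from __future__ import annotations

import csv
import json
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "BoxAnnotationSet",
    "PointAnnotationSet",
    "read_voc_boxes",
    "read_points",
    "write_points",
    "boxes_to_centroids",
    "rescale_points",
]


class AnnotationError(ValueError):
    """Malformed or invariant-violating annotation data."""


@dataclass(frozen=True)
class BoxAnnotationSet:
    """Rectangular-box labels for one image: ``(xmin, ymin, xmax, ymax)`` each."""

    image_id: str
    boxes: tuple[tuple[float, float, float, float], ...] = ()

    def __post_init__(self) -> None:
        for i, (xmin, ymin, xmax, ymax) in enumerate(self.boxes):
            if xmin > xmax or ymin > ymax:
                raise AnnotationError(
                    f"box {i} of {self.image_id!r} has reversed corners: "
                    f"({xmin}, {ymin}, {xmax}, {ymax})"
                )
            if min(xmin, ymin) < 0:
                raise AnnotationError(
                    f"box {i} of {self.image_id!r} has negative coordinates"
                )

    def __len__(self) -> int:
        return len(self.boxes)


@dataclass(frozen=True)
class PointAnnotationSet:
    """Centroid labels for one image; ``n`` is the ground-truth cluster count."""

    image_id: str
    points: tuple[tuple[float, float], ...] = ()

    @property
    def n(self) -> int:
        return len(self.points)

    def __len__(self) -> int:
        return len(self.points)

    def asarray(self) -> np.ndarray:
        """Points as an (N, 2) float array of (x, y) rows."""
        return np.asarray(self.points, dtype=float).reshape(-1, 2)

    @staticmethod
    def from_array(image_id: str, arr: np.ndarray | Sequence) -> "PointAnnotationSet":
        a = np.asarray(arr, dtype=float).reshape(-1, 2)
        return PointAnnotationSet(image_id, tuple((float(x), float(y)) for x, y in a))


def read_voc_boxes(path: str | Path) -> BoxAnnotationSet:
    """Read a Pascal VOC XML annotation file (LabelImg dialect).

    One box per ``object/bndbox`` entry, in document order. Raises
    :class:`AnnotationError` on malformed XML or reversed box corners.
    """
    path = Path(path)
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise AnnotationError(f"cannot parse {path}: {exc}") from exc
    name_el = root.find("filename")
    image_id = (
        name_el.text.strip() if name_el is not None and name_el.text else path.stem
    )
    boxes = []
    for i, obj in enumerate(root.iter("object")):
        bnd = obj.find("bndbox")
        if bnd is None:
            raise AnnotationError(f"object {i} in {path} lacks a bndbox")
        try:
            coords = tuple(
                float(bnd.findtext(tag))  # type: ignore[arg-type]
                for tag in ("xmin", "ymin", "xmax", "ymax")
            )
        except (TypeError, ValueError) as exc:
            raise AnnotationError(f"object {i} in {path}: bad bndbox fields") from exc
        boxes.append(coords)
    return BoxAnnotationSet(image_id, tuple(boxes))


def write_voc_boxes(b: BoxAnnotationSet, path: str | Path,
                    image_size: tuple[int, int] | None = None) -> None:
    """Write boxes as minimal Pascal VOC XML (round-trips with read_voc_boxes)."""
    root = ET.Element("annotation")
    ET.SubElement(root, "filename").text = b.image_id
    if image_size is not None:
        size = ET.SubElement(root, "size")
        ET.SubElement(size, "width").text = str(image_size[0])
        ET.SubElement(size, "height").text = str(image_size[1])
        ET.SubElement(size, "depth").text = "3"
    for xmin, ymin, xmax, ymax in b.boxes:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = "cluster"
        bnd = ET.SubElement(obj, "bndbox")
        for tag, v in zip(("xmin", "ymin", "xmax", "ymax"), (xmin, ymin, xmax, ymax)):
            ET.SubElement(bnd, tag).text = repr(float(v))
    ET.ElementTree(root).write(path, encoding="unicode")


def read_points(path: str | Path) -> PointAnnotationSet:
    """Read centroid points from CSV (header ``x,y``) or JSON (array of {x, y}).

    The dialect is chosen by file suffix (``.json`` vs anything else = CSV).
    Coordinates are kept as reals; an empty record list is valid (N = 0).
    """
    path = Path(path)
    records: list[tuple[float, float]] = []
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            try:
                data = json.load(fh)
            except json.JSONDecodeError as exc:
                raise AnnotationError(f"cannot parse {path}: {exc}") from exc
        if not isinstance(data, list):
            raise AnnotationError(f"{path}: expected a top-level JSON array")
        for i, rec in enumerate(data):
            if not isinstance(rec, dict) or "x" not in rec or "y" not in rec:
                raise AnnotationError(f"{path}: record {i} lacks x or y")
            records.append((float(rec["x"]), float(rec["y"])))
    else:
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"x", "y"} <= set(reader.fieldnames):
                raise AnnotationError(f"{path}: CSV must have an 'x,y' header")
            for i, row in enumerate(reader):
                try:
                    records.append((float(row["x"]), float(row["y"])))
                except (TypeError, ValueError) as exc:
                    raise AnnotationError(f"{path}: row {i} not numeric") from exc
    for i, (x, y) in enumerate(records):
        if x < 0 or y < 0:
            raise AnnotationError(f"{path}: point {i} has a negative coordinate")
    return PointAnnotationSet(path.stem, tuple(records))


def write_points(p: PointAnnotationSet, path: str | Path) -> None:
    """Write points in the dialect implied by the suffix (.json or CSV).

    The CSV writer uses ``repr`` of the floats, so read_points round-trips
    coordinates exactly.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, "w") as fh:
            json.dump([{"x": x, "y": y} for x, y in p.points], fh)
    else:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["x", "y"])
            for x, y in p.points:
                writer.writerow([repr(float(x)), repr(float(y))])


def boxes_to_centroids(b: BoxAnnotationSet) -> PointAnnotationSet:
    """Convert each box to its center point ``((xmin+xmax)/2, (ymin+ymax)/2)``."""
    pts = tuple(
        ((xmin + xmax) / 2.0, (ymin + ymax) / 2.0) for xmin, ymin, xmax, ymax in b.boxes
    )
    return PointAnnotationSet(b.image_id, pts)


def rescale_points(
    p: PointAnnotationSet,
    fx: float,
    fy: float,
    bounds: tuple[float, float] | None = None,
) -> PointAnnotationSet:
    """Scale every point by (fx, fy); N is unchanged.

    If ``bounds = (width, height)`` is given, points that land outside are
    clamped to the boundary (with a logged warning) so the count is preserved.
    """
    if fx <= 0 or fy <= 0:
        raise ValueError(f"scale factors must be positive, got ({fx}, {fy})")
    scaled = [(x * fx, y * fy) for x, y in p.points]
    if bounds is not None:
        w, h = bounds
        clamped = [(min(max(x, 0.0), w), min(max(y, 0.0), h)) for x, y in scaled]
        n_moved = sum(a != b for a, b in zip(scaled, clamped))
        if n_moved:
            logger.warning(
                "%s: clamped %d rescaled point(s) to image bounds %r",
                p.image_id, n_moved, bounds,
            )
        scaled = clamped
    return PointAnnotationSet(p.image_id, tuple(scaled))
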