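"""PASCAL VOC XML annotation reader/writer and CSV trajectory export.

XML files are structured so LabelImg can open and edit them directly.  The
in-memory boxes use the package's 0-based half-open pixel convention; on disk
the VOC convention (1-based, inclusive) is used, so a half-open box
``(xmin, ymin, xmax, ymax)`` is serialized as ``xmin+1, ymin+1, xmax, ymax``
and converted back on read.  The roundtrip is exact.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .geometry import BoundingBox

#: Columns of the trajectory CSV (one row per frame and track).
CSV_COLUMNS = ["frame_index", "track_id", "x", "y", "source", "corrected", "stale"]


@dataclass
class VocAnnotation:
    """One image's labeled objects."""

    folder: str
    filename: str
    width: int
    height: int
    depth: int = 3
    objects: list = field(default_factory=list)  # list of (label, BoundingBox)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image size must be positive")
        if not self.filename:
            raise ValueError("filename must be non-empty")
        for label, box in self.objects:
            if not box.within(self.width, self.height):
                raise ValueError(f"box {box} outside {self.width}x{self.height} image")


def write_voc(ann: VocAnnotation, path) -> None:
    """Serialize an annotation to a LabelImg-compatible VOC XML file."""
    root = ET.Element("annotation")
    ET.SubElement(root, "folder").text = ann.folder
    ET.SubElement(root, "filename").text = ann.filename
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(int(ann.width))
    ET.SubElement(size, "height").text = str(int(ann.height))
    ET.SubElement(size, "depth").text = str(int(ann.depth))
    ET.SubElement(root, "segmented").text = "0"
    for label, box in ann.objects:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = label
        ET.SubElement(obj, "pose").text = "Unspecified"
        ET.SubElement(obj, "truncated").text = "0"
        ET.SubElement(obj, "difficult").text = "0"
        bnd = ET.SubElement(obj, "bndbox")
        # half-open 0-based -> inclusive 1-based
        ET.SubElement(bnd, "xmin").text = str(int(box.xmin) + 1)
        ET.SubElement(bnd, "ymin").text = str(int(box.ymin) + 1)
        ET.SubElement(bnd, "xmax").text = str(int(box.xmax))
        ET.SubElement(bnd, "ymax").text = str(int(box.ymax))
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode")


class VocParseError(ValueError):
    """Raised when a VOC XML file is malformed or violates box invariants."""


def _require(parent, tag, path):
    el = parent.find(tag)
    if el is None or (el.text is None and len(el) == 0):
        raise VocParseError(f"{path}: missing <{tag}> element")
    return el


def read_voc(path) -> VocAnnotation:
    """Parse a VOC XML file; tolerates extra elements (pose, difficult, ...)."""
    path = str(path)
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise VocParseError(f"{path}: malformed XML ({exc})") from exc
    folder_el = root.find("folder")
    folder = folder_el.text or "" if folder_el is not None else ""
    filename = _require(root, "filename", path).text or ""
    size = _require(root, "size", path)
    width = int(_require(size, "width", path).text)
    height = int(_require(size, "height", path).text)
    depth_el = size.find("depth")
    depth = int(depth_el.text) if depth_el is not None and depth_el.text else 3
    objects = []
    for obj in root.findall("object"):
        label = _require(obj, "name", path).text or ""
        bnd = _require(obj, "bndbox", path)
        coords = {tag: int(float(_require(bnd, tag, path).text)) for tag in ("xmin", "ymin", "xmax", "ymax")}
        # inclusive 1-based -> half-open 0-based
        xmin, ymin = coords["xmin"] - 1, coords["ymin"] - 1
        xmax, ymax = coords["xmax"], coords["ymax"]
        if xmin >= xmax or ymin >= ymax:
            raise VocParseError(f"{path}: bndbox has xmin >= xmax or ymin >= ymax")
        objects.append((label, BoundingBox(xmin, ymin, xmax, ymax)))
    return VocAnnotation(folder=folder, filename=filename, width=width, height=height, depth=depth, objects=objects)


def write_records_csv(records, path) -> None:
    """Write tracking records (see tracker.TrackRecord) to CSV."""
    rows = [
        {
            "frame_index": r.frame_index,
            "track_id": r.track_id,
            "x": r.position.x,
            "y": r.position.y,
            "source": r.source,
            "corrected": int(r.corrected),
            "stale": int(r.stale),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def read_records_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df
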