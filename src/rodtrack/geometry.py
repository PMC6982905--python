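"""Axis-aligned boxes, points, overlap (IOU) and non-maximum suppression.

Pixel-area convention used throughout the package (including VOC export):
a box ``(xmin, ymin, xmax, ymax)`` is half-open, covering integer pixel
columns ``xmin .. xmax-1`` and rows ``ymin .. ymax-1``, so its area is
``(xmax - xmin) * (ymax - ymin)``.  Coordinates use a top-left origin with
x increasing rightwards and y downwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class Point2D:
    """A pixel location; fractional coordinates are allowed (predictions)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite point ({self.x}, {self.y})")

    def distance_to(self, other: "Point2D") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


@dataclass(frozen=True)
class BoundingBox:
    """Scored axis-aligned detection rectangle (half-open pixel bounds)."""

    xmin: int
    ymin: int
    xmax: int
    ymax: int
    score: float = 1.0
    label: str = "rat"

    def __post_init__(self) -> None:
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise ValueError(
                f"degenerate box ({self.xmin},{self.ymin},{self.xmax},{self.ymax}): "
                "requires xmin < xmax and ymin < ymax"
            )
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")

    @property
    def width(self) -> int:
        return self.xmax - self.xmin

    @property
    def height(self) -> int:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> Point2D:
        return Point2D((self.xmin + self.xmax) / 2.0, (self.ymin + self.ymax) / 2.0)

    def within(self, width: int, height: int) -> bool:
        """True if the box lies inside a ``width x height`` image."""
        return 0 <= self.xmin and 0 <= self.ymin and self.xmax <= width and self.ymax <= height


@dataclass
class FrameDetections:
    """Scored boxes for one frame (conventionally post-NMS)."""

    frame_index: int
    boxes: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.boxes)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes; symmetric, 0 when disjoint."""
    ix = min(a.xmax, b.xmax) - max(a.xmin, b.xmin)
    iy = min(a.ymax, b.ymax) - max(a.ymin, b.ymin)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = float(ix) * float(iy)
    union = a.area + b.area - inter
    return inter / union


def nms(boxes: list, iou_threshold: float = 0.45) -> list:
    """Greedy non-maximum suppression.

    Repeatedly keeps the highest-scoring remaining box and deletes every
    remaining box whose IOU with it exceeds ``iou_threshold``.  Output is
    sorted by descending score; ties keep input order (stable sort), so the
    result is deterministic.  An empty input yields an empty output.
    """
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError(f"iou_threshold {iou_threshold} outside (0, 1)")
    # stable: equal scores keep insertion order
    remaining = sorted(boxes, key=lambda b: -b.score)
    kept: list = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [b for b in remaining if iou(best, b) <= iou_threshold]
    return kept
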