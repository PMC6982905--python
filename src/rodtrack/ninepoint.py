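"""Nine-point gray-value position correction.

A claimed animal position (from the detector or a Kalman prediction) is
verified against the image: the gray value at the point and at the eight
surrounding points of a 3x3 grid (default spacing 30 px) is compared with an
empirical body threshold (default 105; the animal is darker than the floor).
If the claimed point already reads as body it is kept; otherwise the probe
with the minimum gray value among those reading as body replaces it; if no
probe reads as body the original point is returned and flagged failed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Point2D

STATUS_KEPT = "kept"
STATUS_CORRECTED = "corrected"
STATUS_FAILED = "failed"


@dataclass
class NinePointParams:
    spacing: float = 30.0
    gray_threshold: int = 105
    polarity: str = "dark_object"  # or "light_object"
    patch_radius: int = 0  # 0 = single-pixel sampling

    def __post_init__(self) -> None:
        if self.spacing < 0:
            raise ValueError("spacing must be >= 0")
        if not 0 <= self.gray_threshold <= 255:
            raise ValueError("gray_threshold must lie in [0, 255]")
        if self.polarity not in ("dark_object", "light_object"):
            raise ValueError(f"unknown polarity {self.polarity!r}")


def nine_points(center: Point2D, spacing: float, bounds: tuple | None = None) -> list:
    """Center plus the 8 surrounding grid points at offsets {-s, 0, +s}.

    Scan order is row-major from the top-left offset.  With ``bounds``
    (width, height) supplied, off-image points are clipped to the border so
    the candidate count stays at 9.
    """
    pts = []
    for dy in (-spacing, 0.0, spacing):
        for dx in (-spacing, 0.0, spacing):
            x, y = center.x + dx, center.y + dy
            if bounds is not None:
                w, h = bounds
                x = min(max(x, 0.0), w - 1.0)
                y = min(max(y, 0.0), h - 1.0)
            pts.append(Point2D(x, y))
    return pts


def _sample_gray(gray: np.ndarray, point: Point2D, radius: int) -> float:
    h, w = gray.shape
    xi = int(round(min(max(point.x, 0), w - 1)))
    yi = int(round(min(max(point.y, 0), h - 1)))
    if radius <= 0:
        return float(gray[yi, xi])
    y0, y1 = max(yi - radius, 0), min(yi + radius + 1, h)
    x0, x1 = max(xi - radius, 0), min(xi + radius + 1, w)
    return float(gray[y0:y1, x0:x1].mean())


def correct_position(
    gray: np.ndarray, center: Point2D, params: NinePointParams | None = None
) -> tuple:
    """Verify/fine-tune a claimed position; returns ``(point, status)``.

    Status is ``kept`` when the claimed point already reads as body,
    ``corrected`` when a grid probe replaced it (minimum gray value; ties
    broken by distance to the claimed point, then scan order), and
    ``failed`` when no probe reads as body (the original point is returned).
    """
    p = params or NinePointParams()
    if gray.ndim != 2 or gray.size == 0:
        raise ValueError("correct_position requires a non-empty grayscale image")
    h, w = gray.shape

    def is_body(value: float) -> bool:
        if p.polarity == "dark_object":
            return value < p.gray_threshold
        return value > p.gray_threshold

    if is_body(_sample_gray(gray, center, p.patch_radius)):
        return center, STATUS_KEPT
    candidates = nine_points(center, p.spacing, bounds=(w, h))
    best = None
    for order, pt in enumerate(candidates):
        value = _sample_gray(gray, pt, p.patch_radius)
        if not is_body(value):
            continue
        key = (value, center.distance_to(pt), order)
        if best is None or key < best[0]:
            best = (key, pt)
    if best is None:
        return center, STATUS_FAILED
    return best[1], STATUS_CORRECTED
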