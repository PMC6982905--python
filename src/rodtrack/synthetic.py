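"""Synthetic overhead-arena scenes with ground truth.

Renders N dark elliptical animals moving with approximately constant
velocity on a light arena floor, with optional sensor noise, salt-and-pepper
specks, a saturated highlight blob, and per-animal detection dropout.  The
geometry emulates a bird-view capture of a 1024x760 px arena.  Dropout is
applied to the detection stream (:class:`TruthDetector`), never to the
rendering, so the accuracy of gap-filled track positions can be measured
against intact truth.

Everything is seeded: the same scene specification reproduces bit-identical
frames and truth tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import BoundingBox, Point2D

TRUTH_COLUMNS = ["frame", "id", "x", "y", "vx", "vy", "heading"]


@dataclass
class ArenaScene:
    """Scene specification; defaults model the standard three-animal arena."""

    width: int = 1024
    height: int = 760
    n_animals: int = 3
    n_frames: int = 100
    floor_gray: int = 180
    body_gray: int = 60
    axes: tuple = (60.0, 30.0)  # full major/minor ellipse axes, px
    speed: float = 5.0  # px/frame
    heading_jitter: float = 0.05  # rad/frame, std of random turning
    turn_rate: float = 0.0  # rad/frame, deterministic turning
    noise_sigma: float = 5.0  # gray levels of per-pixel sensor noise
    salt_pepper: float = 0.0  # density of 0/255 specks
    highlight: tuple | None = None  # (cx, cy, radius) saturated disk
    dropout: float = 0.0  # per-animal per-frame detection suppression
    detection_noise: float = 2.0  # px std of detection-center jitter
    min_separation: float = 120.0  # px between animals at placement
    seed: int = 0
    initial_states: list | None = None  # [(x, y, vx, vy)] overrides placement

    @property
    def margin(self) -> float:
        """Wall margin keeping the whole body inside the arena."""
        return self.axes[0] / 2.0 + 2.0


def _check_scene(scene: ArenaScene) -> None:
    if scene.axes[0] >= scene.width - 2 * scene.margin or scene.axes[0] >= scene.height - 2 * scene.margin:
        raise ValueError("animals larger than arena")
    if scene.n_animals < 1 or scene.n_frames < 1:
        raise ValueError("need at least one animal and one frame")


def simulate_truth(scene: ArenaScene) -> pd.DataFrame:
    """Per-frame ground truth: one row per (frame, id).

    Motion is constant-velocity with optional per-frame heading jitter and
    deterministic turn rate; walls reflect.  Headings follow the velocity.
    """
    _check_scene(scene)
    rng = np.random.default_rng(scene.seed)
    m = scene.margin
    if scene.initial_states is not None:
        if len(scene.initial_states) != scene.n_animals:
            raise ValueError("initial_states length must equal n_animals")
        states = [list(map(float, s)) for s in scene.initial_states]
    else:
        states = []
        for _ in range(scene.n_animals):
            for _attempt in range(1000):
                x = rng.uniform(m, scene.width - m)
                y = rng.uniform(m, scene.height - m)
                if all(math.hypot(x - s[0], y - s[1]) >= scene.min_separation for s in states):
                    break
            else:
                raise ValueError("could not place animals with the requested separation")
            theta = rng.uniform(0, 2 * math.pi)
            states.append([x, y, scene.speed * math.cos(theta), scene.speed * math.sin(theta)])

    rows = []
    for t in range(scene.n_frames):
        for i, s in enumerate(states):
            heading = math.atan2(s[3], s[2]) if (s[2] or s[3]) else 0.0
            rows.append((t, i, s[0], s[1], s[2], s[3], heading))
        for s in states:
            turn = scene.turn_rate + (rng.normal(0.0, scene.heading_jitter) if scene.heading_jitter else 0.0)
            if turn:
                c, si = math.cos(turn), math.sin(turn)
                s[2], s[3] = c * s[2] - si * s[3], si * s[2] + c * s[3]
            s[0] += s[2]
            s[1] += s[3]
            # reflective walls
            if s[0] < m:
                s[0], s[2] = 2 * m - s[0], abs(s[2])
            elif s[0] > scene.width - m:
                s[0], s[2] = 2 * (scene.width - m) - s[0], -abs(s[2])
            if s[1] < m:
                s[1], s[3] = 2 * m - s[1], abs(s[3])
            elif s[1] > scene.height - m:
                s[1], s[3] = 2 * (scene.height - m) - s[1], -abs(s[3])
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def true_bbox(x: float, y: float, heading: float, axes: tuple) -> BoundingBox:
    """Axis-aligned bounding box of a rotated ellipse."""
    a, b = axes[0] / 2.0, axes[1] / 2.0
    ex = math.sqrt((a * math.cos(heading)) ** 2 + (b * math.sin(heading)) ** 2)
    ey = math.sqrt((a * math.sin(heading)) ** 2 + (b * math.cos(heading)) ** 2)
    return BoundingBox(
        int(math.floor(x - ex)), int(math.floor(y - ey)), int(math.ceil(x + ex)), int(math.ceil(y + ey))
    )


def _paint_ellipse(frame: np.ndarray, x: float, y: float, heading: float, axes: tuple, gray: int) -> None:
    a, b = axes[0] / 2.0, axes[1] / 2.0
    half = int(math.ceil(a)) + 2
    h, w = frame.shape
    x0, x1 = max(int(x) - half, 0), min(int(x) + half + 1, w)
    y0, y1 = max(int(y) - half, 0), min(int(y) + half + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1) - x
    ys = np.arange(y0, y1) - y
    dx, dy = np.meshgrid(xs, ys)
    c, s = math.cos(heading), math.sin(heading)
    xr = c * dx + s * dy
    yr = -s * dx + c * dy
    inside = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
    frame[y0:y1, x0:x1][inside] = gray


def render_frame(scene: ArenaScene, truth_rows: pd.DataFrame, rng: np.random.Generator | None = None) -> np.ndarray:
    """Render one 8-bit grayscale frame from the truth rows of one frame."""
    frame = np.full((scene.height, scene.width), scene.floor_gray, dtype=np.uint8)
    for row in truth_rows.itertuples():
        _paint_ellipse(frame, row.x, row.y, row.heading, scene.axes, scene.body_gray)
    if scene.highlight is not None:
        cx, cy, r = scene.highlight
        ys, xs = np.ogrid[: scene.height, : scene.width]
        frame[(xs - cx) ** 2 + (ys - cy) ** 2 <= r * r] = 255
    if rng is not None and (scene.noise_sigma or scene.salt_pepper):
        out = frame.astype(float)
        if scene.noise_sigma:
            out += rng.normal(0.0, scene.noise_sigma, frame.shape)
        out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
        if scene.salt_pepper:
            hit = rng.random(frame.shape) < scene.salt_pepper
            salt = rng.random(frame.shape) < 0.5
            out[hit & salt] = 255
            out[hit & ~salt] = 0
        return out
    return frame


def generate_scene(scene: ArenaScene):
    """Return ``(frame stream, truth table)`` for a scene specification.

    The frame stream is a generator re-creatable by calling again with the
    same scene; noise is drawn from a fresh seeded generator on each
    iteration, so repeated runs yield byte-identical frames.
    """
    _check_scene(scene)
    truth = simulate_truth(scene)
    grouped = {t: g for t, g in truth.groupby("frame")}

    def frames():
        rng = np.random.default_rng(scene.seed + 1)
        for t in range(scene.n_frames):
            yield render_frame(scene, grouped[t], rng)

    return frames(), truth


class TruthDetector:
    """Detector emitting ground-truth boxes with dropout and center jitter.

    Emulates an imperfect per-animal detector on a scene whose truth is
    known: each animal's box appears independently with probability
    ``1 - dropout`` and its center is jittered by ``detection_noise`` px.
    Detections are precomputed at construction, so the instance is
    deterministic; call it once per frame in order (or index
    ``per_frame``).
    """

    def __init__(self, scene: ArenaScene, truth: pd.DataFrame | None = None, seed: int | None = None):
        self.scene = scene
        if truth is None:
            truth = simulate_truth(scene)
        rng = np.random.default_rng(scene.seed + 2 if seed is None else seed)
        self.per_frame: list = []
        self.truth_ids: list = []  # parallel: which animal produced each box
        for t in range(scene.n_frames):
            rows = truth[truth["frame"] == t]
            boxes, ids = [], []
            for row in rows.itertuples():
                if scene.dropout and rng.random() < scene.dropout:
                    continue
                jx = rng.normal(0.0, scene.detection_noise) if scene.detection_noise else 0.0
                jy = rng.normal(0.0, scene.detection_noise) if scene.detection_noise else 0.0
                base = true_bbox(row.x + jx, row.y + jy, row.heading, scene.axes)
                boxes.append(base)
                ids.append(int(row.id))
            self.per_frame.append(boxes)
            self.truth_ids.append(ids)
        self._cursor = 0

    def reset(self) -> None:
        self._cursor = 0

    def __call__(self, frame) -> list:
        boxes = self.per_frame[self._cursor]
        self._cursor += 1
        return list(boxes)


def crossing_scene(n_frames: int = 100, n_animals: int = 2) -> tuple:
    """A designed path-crossing scene and the frame where identities swap.

    Two animals travel toward each other along the same horizontal line and
    pass within half a step of each other near mid-sequence, so right after
    the pass each animal's position is nearer the *other* animal's previous
    position — the ambiguity that last-position assignment resolves wrongly
    and prediction-based assignment resolves correctly.  With
    ``n_animals=3`` a third animal travels a well-separated line.
    """
    speed = 800.0 / n_frames
    t_cross = int(n_frames * 0.45)
    ax0 = 150.0
    bx0 = ax0 + 2.0 * speed * t_cross + speed / 2.0
    states = [(ax0, 380.0, speed, 0.0), (bx0, 380.0, -speed, 0.0)]
    if n_animals == 3:
        states.append((700.0, 600.0, -3.0, 0.0))
    elif n_animals != 2:
        raise ValueError("crossing_scene supports 2 or 3 animals")
    scene = ArenaScene(
        n_animals=n_animals,
        n_frames=n_frames,
        speed=speed,
        heading_jitter=0.0,
        noise_sigma=0.0,
        detection_noise=0.0,
        min_separation=0.0,
        initial_states=states,
        seed=7,
    )
    truth = simulate_truth(scene)
    crossing_frame = None
    for t in range(1, n_frames):
        prev = truth[truth["frame"] == t - 1].set_index("id")
        cur = truth[truth["frame"] == t].set_index("id")
        d_own = math.hypot(cur.loc[0, "x"] - prev.loc[0, "x"], cur.loc[0, "y"] - prev.loc[0, "y"])
        d_other = math.hypot(cur.loc[0, "x"] - prev.loc[1, "x"], cur.loc[0, "y"] - prev.loc[1, "y"])
        if d_other < d_own:
            crossing_frame = t
            break
    if crossing_frame is None:
        raise RuntimeError("crossing construction failed to produce a swap frame")
    return scene, crossing_frame
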