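"""Identity assignment: Hungarian matching of detections to tracks.

The cost of pairing a track with a detection is the plain Euclidean distance
between the track's reference point and the detection's center.  The
reference point is either the track's last estimated position
(``last_position``) or its one-step Kalman prediction (``kalman_predicted``).
The predicted reference resolves path-crossing ambiguity: when two animals
swap proximal positions between frames, last-position costs favor swapping
their identities while predicted positions land on the correct detections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from . import kalman
from .geometry import Point2D

MODES = ("last_position", "kalman_predicted")


def cost_matrix(track_points: list, detections: list) -> np.ndarray:
    """Pairwise Euclidean distances, entry (i, j) = |track_i - detection_j|."""
    a = np.array([[p.x, p.y] for p in track_points], dtype=float)
    b = np.array([[p.x, p.y] for p in detections], dtype=float)
    return cdist(a, b)


def solve_assignment(cost: np.ndarray) -> list:
    """Minimum-total-cost matching covering min(rows, cols) pairs.

    Returns (row, col) index pairs sorted by row. Empty matrices give an
    empty matching.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.size == 0:
        return []
    if not np.all(np.isfinite(cost)):
        raise ValueError("cost matrix must be finite")
    rows, cols = linear_sum_assignment(cost)
    return sorted(zip(rows.tolist(), cols.tolist()))


@dataclass
class Association:
    """Result of matching one frame's detections to the live tracks."""

    matches: list  # (track_index, detection_index) pairs
    unmatched_tracks: list  # track indices with no detection this frame
    unmatched_detections: list  # detection indices left over / gated out


def associate(
    tracks: list,
    detections: list,
    mode: str = "kalman_predicted",
    gate: float = 150.0,
    params: kalman.KalmanParams | None = None,
) -> Association:
    """Match detections to tracks by minimum total Euclidean distance.

    ``mode`` selects the track reference point (see module docstring).  Pairs
    whose distance exceeds ``gate`` pixels are rejected after the optimal
    matching is computed; both sides then count as unmatched, so a spurious
    far-away detection cannot capture a coasting track.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if not tracks or not detections:
        return Association([], list(range(len(tracks))), list(range(len(detections))))
    if mode == "kalman_predicted":
        refs = [kalman.predict(t, params=params).position for t in tracks]
    else:
        refs = [t.position for t in tracks]
    cost = cost_matrix(refs, detections)
    matches = []
    unmatched_t = set(range(len(tracks)))
    unmatched_d = set(range(len(detections)))
    for ti, dj in solve_assignment(cost):
        if cost[ti, dj] > gate:
            continue
        matches.append((ti, dj))
        unmatched_t.discard(ti)
        unmatched_d.discard(dj)
    return Association(matches, sorted(unmatched_t), sorted(unmatched_d))
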