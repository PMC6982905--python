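"""Frame-loop orchestration: detect, assign, filter, fill, correct, report.

Per frame: the pluggable detector proposes boxes, non-maximum suppression
removes duplicates, the Hungarian assignment (against Kalman-predicted track
positions by default) attaches detections to identities, matched tracks take
a measurement update, and unmatched tracks are *filled* with their Kalman
prediction.  Both detected and filled positions pass through the nine-point
gray-value correction before being reported.  A fixed number of animals is
tracked: once identities are initialized, every frame yields exactly
``n_objects`` records, each tagged with its provenance (``detected`` or
``filled``).

The module also bins records into the 40x30 arena-exploration grid and
writes trajectory/heatmap images plus the CSV twin of the on-video labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import assignment, kalman, ninepoint, voc_io
from .geometry import Point2D, nms
from .seglabel import to_gray

SOURCE_DETECTED = "detected"
SOURCE_FILLED = "filled"


@dataclass
class TrackerConfig:
    nms_iou: float = 0.45
    mode: str = "kalman_predicted"  # assignment reference, see assignment module
    gate: float = 150.0  # px; association rejection distance
    max_coast: int = 30  # frames filled in a row before a track is flagged stale
    correct_detections: bool = True  # run nine-point correction on detections
    correct_filled: bool = True  # run nine-point correction on filled positions
    update_filled: bool = True  # feed corrected filled points back into the filter
    kalman: kalman.KalmanParams = field(default_factory=kalman.KalmanParams)
    ninepoint: ninepoint.NinePointParams = field(default_factory=ninepoint.NinePointParams)


@dataclass
class TrackRecord:
    """One animal's reported position in one frame, with provenance."""

    frame_index: int
    track_id: int
    position: Point2D
    source: str  # detected | filled
    corrected: bool = False
    stale: bool = False


@dataclass
class ExplorationGrid:
    """Per-cell frame tallies over the arena (40 columns x 30 rows)."""

    n_cols: int = 40
    n_rows: int = 30
    counts: np.ndarray = None
    arena: tuple = None  # (xmin, ymin, xmax, ymax)

    def __post_init__(self) -> None:
        if self.counts is None:
            self.counts = np.zeros((self.n_rows, self.n_cols), dtype=np.int64)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _correct(gray, point, cfg, enabled):
    if not enabled or gray is None:
        return point, False
    pt, status = ninepoint.correct_position(gray, point, cfg.ninepoint)
    return pt, status == ninepoint.STATUS_CORRECTED


def track_video(frames, detector, n_objects: int, config: TrackerConfig | None = None) -> list:
    """Track a fixed number of animals through a frame stream.

    ``frames`` is any iterable of 8-bit images; ``detector`` maps a frame to
    a list of scored :class:`~rodtrack.geometry.BoundingBox`.  Identities are
    assigned on the first frame producing at least ``n_objects`` detections
    (the ``n_objects`` best by score); the stream errors out at the end if no
    frame ever does.  Returns the flat list of :class:`TrackRecord`.
    """
    if n_objects < 1:
        raise ValueError("n_objects must be >= 1")
    cfg = config or TrackerConfig()
    tracks: list = []
    records: list = []
    initialized = False
    for frame_index, frame in enumerate(frames):
        boxes = nms(detector(frame), cfg.nms_iou)
        gray = to_gray(np.asarray(frame))
        if not initialized:
            if len(boxes) < n_objects:
                continue
            for tid, box in enumerate(boxes[:n_objects]):
                point, corr = _correct(gray, box.center, cfg, cfg.correct_detections)
                tracks.append(kalman.init_track(tid, point, cfg.kalman))
                records.append(TrackRecord(frame_index, tid, point, SOURCE_DETECTED, corr))
            initialized = True
            continue

        centers = [b.center for b in boxes]
        assoc = assignment.associate(tracks, centers, mode=cfg.mode, gate=cfg.gate, params=cfg.kalman)
        new_tracks = list(tracks)
        for ti, dj in assoc.matches:
            point, corr = _correct(gray, centers[dj], cfg, cfg.correct_detections)
            predicted = kalman.predict(tracks[ti], params=cfg.kalman)
            updated = kalman.update(predicted, point, cfg.kalman)
            new_tracks[ti] = replace(updated, frames_since_detection=0, source_last=SOURCE_DETECTED)
            records.append(TrackRecord(frame_index, tracks[ti].id, point, SOURCE_DETECTED, corr))
        for ti in assoc.unmatched_tracks:
            predicted = kalman.predict(tracks[ti], params=cfg.kalman)
            point, corr = _correct(gray, predicted.position, cfg, cfg.correct_filled)
            if corr and cfg.update_filled:
                predicted = kalman.update(predicted, point, cfg.kalman)
            coast = tracks[ti].frames_since_detection + 1
            new_tracks[ti] = replace(predicted, frames_since_detection=coast, source_last=SOURCE_FILLED)
            records.append(
                TrackRecord(
                    frame_index, tracks[ti].id, point, SOURCE_FILLED, corr, stale=coast > cfg.max_coast
                )
            )
        # detections beyond the fixed animal count (or outside the gate) are dropped
        tracks = new_tracks
    if not initialized:
        raise RuntimeError(f"no frame ever produced {n_objects} detections; cannot initialize tracks")
    return records


def exploration_map(records: list, arena: tuple, n_cols: int = 40, n_rows: int = 30) -> ExplorationGrid:
    """Bin each record's position once into the exploration grid.

    ``arena`` is ``(xmin, ymin, xmax, ymax)`` and must enclose every
    position; the total count equals the number of records.
    """
    if not records:
        raise ValueError("no records to bin")
    x0, y0, x1, y1 = arena
    grid = ExplorationGrid(n_cols=n_cols, n_rows=n_rows, arena=tuple(arena))
    cw = (x1 - x0) / n_cols
    ch = (y1 - y0) / n_rows
    for r in records:
        if not (x0 <= r.position.x <= x1 and y0 <= r.position.y <= y1):
            raise ValueError(
                f"record (frame {r.frame_index}, id {r.track_id}) at "
                f"({r.position.x:.1f}, {r.position.y:.1f}) lies outside the arena {arena}"
            )
        col = min(int((r.position.x - x0) / cw), n_cols - 1)
        row = min(int((r.position.y - y0) / ch), n_rows - 1)
        grid.counts[row, col] += 1
    return grid


def plot_outputs(records: list, grid: ExplorationGrid, out_dir) -> dict:
    """Write the trajectory image, exploration heatmap, and CSV records.

    Returns the paths written.  The heatmap's color intensity encodes the
    number of frames spent in each grid cell (duration of stay).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not records:
        raise ValueError("no records to plot")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "trajectory": out_dir / "trajectory.png",
        "heatmap": out_dir / "exploration.png",
        "csv": out_dir / "records.csv",
    }

    fig, ax = plt.subplots(figsize=(7, 5))
    by_id: dict = {}
    for r in records:
        by_id.setdefault(r.track_id, []).append((r.frame_index, r.position.x, r.position.y))
    for tid, pts in sorted(by_id.items()):
        pts.sort()
        xs = [p[1] for p in pts]
        ys = [p[2] for p in pts]
        ax.plot(xs, ys, lw=1.0, label=f"id {tid}")
    if grid.arena is not None:
        ax.set_xlim(grid.arena[0], grid.arena[2])
        ax.set_ylim(grid.arena[3], grid.arena[1])
    else:
        ax.invert_yaxis()
    ax.set_aspect("equal")
    ax.legend(loc="upper right", fontsize=8)
    ax.set_title("trajectories")
    fig.savefig(paths["trajectory"], dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 5))
    im = ax.imshow(grid.counts, cmap="hot", interpolation="nearest")
    fig.colorbar(im, ax=ax, label="frames in cell")
    ax.set_title(f"exploration ({grid.n_cols}x{grid.n_rows} cells)")
    fig.savefig(paths["heatmap"], dpi=120)
    plt.close(fig)

    voc_io.write_records_csv(records, paths["csv"])
    return paths


# ---------------------------------------------------------------------------
# evaluation against synthetic ground truth


def match_records_to_truth(records: list, truth) -> dict:
    """Per-frame nearest-truth assignment: {(frame, track_id): truth_id}."""
    out = {}
    by_frame: dict = {}
    for r in records:
        by_frame.setdefault(r.frame_index, []).append(r)
    for t, recs in by_frame.items():
        rows = truth[truth["frame"] == t]
        if not len(rows):
            continue
        tx = rows["x"].to_numpy()
        ty = rows["y"].to_numpy()
        ids = rows["id"].to_numpy()
        for r in recs:
            d = np.hypot(tx - r.position.x, ty - r.position.y)
            out[(t, r.track_id)] = int(ids[int(np.argmin(d))])
    return out


def count_id_switches(records: list, truth) -> int:
    """Number of times a track's nearest-truth identity changes over time."""
    mapping = match_records_to_truth(records, truth)
    last: dict = {}
    switches = 0
    for (t, tid), truth_id in sorted(mapping.items()):
        if tid in last and last[tid] != truth_id:
            switches += 1
        last[tid] = truth_id
    return switches


def position_errors(records: list, truth) -> dict:
    """Mean absolute position error split by record source.

    Errors are measured against the truth row whose id the record's track
    follows most often (majority vote), so an identity swap shows up as a
    large error rather than silently re-matching.
    """
    mapping = match_records_to_truth(records, truth)
    votes: dict = {}
    for (t, tid), truth_id in mapping.items():
        votes.setdefault(tid, {}).setdefault(truth_id, 0)
        votes[tid][truth_id] += 1
    follow = {tid: max(v, key=v.get) for tid, v in votes.items()}
    indexed = truth.set_index(["frame", "id"])
    errs: dict = {SOURCE_DETECTED: [], SOURCE_FILLED: []}
    for r in records:
        key = (r.frame_index, follow[r.track_id])
        if key not in indexed.index:
            continue
        row = indexed.loc[key]
        errs[r.source].append(float(np.hypot(row["x"] - r.position.x, row["y"] - r.position.y)))
    return {k: (float(np.mean(v)) if v else float("nan")) for k, v in errs.items()}


def detection_tally(counts: list, n_objects: int) -> dict:
    """Frame tally by raw detection count: {'0': .., '1': .., 'n': .., '>n': ..}."""
    tally = {str(k): 0 for k in range(n_objects + 1)}
    tally[f">{n_objects}"] = 0
    for c in counts:
        key = str(c) if c <= n_objects else f">{n_objects}"
        tally[key] += 1
    return tally
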