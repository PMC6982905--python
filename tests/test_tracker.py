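"""End-to-end tracking loop, fill behavior, exploration outputs."""

import numpy as np
import pytest

from rodtrack import (
    ArenaScene,
    Point2D,
    TrackerConfig,
    TruthDetector,
    exploration_map,
    generate_scene,
    plot_outputs,
    simulate_truth,
    track_video,
)
from rodtrack.tracker import (
    SOURCE_DETECTED,
    SOURCE_FILLED,
    TrackRecord,
    count_id_switches,
    detection_tally,
    position_errors,
)
from rodtrack.voc_io import read_records_csv

from conftest import small_scene


class SuppressWindow:
    """Wrap a detector, dropping every detection inside [lo, hi)."""

    def __init__(self, base, lo, hi):
        self.base, self.lo, self.hi = base, lo, hi
        self.i = 0

    def __call__(self, frame):
        boxes = self.base(frame)
        t = self.i
        self.i += 1
        return [] if self.lo <= t < self.hi else boxes


def run_scene(scene, n=None, config=None, detector=None):
    truth = simulate_truth(scene)
    det = detector if detector is not None else TruthDetector(scene, truth)
    frames, _ = generate_scene(scene)
    records = track_video(frames, det, n or scene.n_animals, config)
    return records, truth


class TestTrackVideo:
    def test_clean_scene_all_detected_no_switches(self):
        scene = small_scene(n_animals=2, n_frames=40, min_separation=100, detection_noise=0.0, seed=2)
        records, truth = run_scene(scene)
        assert all(r.source == SOURCE_DETECTED for r in records)
        assert count_id_switches(records, truth) == 0

    def test_records_per_frame_equals_n_objects(self):
        scene = small_scene(n_animals=2, n_frames=60, min_separation=100, dropout=0.25, seed=4)
        records, _ = run_scene(scene)
        per_frame = {}
        for r in records:
            per_frame.setdefault(r.frame_index, []).append(r)
        init = min(per_frame)
        for t in range(init, scene.n_frames):
            assert len(per_frame[t]) == 2

    def test_fully_suppressed_frame_filled_near_truth(self):
        scene = ArenaScene(width=512, height=400, n_animals=3, n_frames=30, noise_sigma=3.0,
                           detection_noise=1.0, min_separation=130, seed=9)
        truth = simulate_truth(scene)
        det = SuppressWindow(TruthDetector(scene, truth), 15, 16)
        frames, _ = generate_scene(scene)
        records = track_video(frames, det, 3)
        frame15 = [r for r in records if r.frame_index == 15]
        assert len(frame15) == 3
        assert all(r.source == SOURCE_FILLED for r in frame15)
        indexed = truth.set_index(["frame", "id"])
        for r in frame15:
            errs = [
                np.hypot(indexed.loc[(15, i), "x"] - r.position.x, indexed.loc[(15, i), "y"] - r.position.y)
                for i in range(3)
            ]
            assert min(errs) <= 30.0  # within one probe-grid spacing of truth

    def test_single_animal_trivial(self):
        scene = small_scene(n_frames=20)
        records, _ = run_scene(scene, n=1)
        assert len(records) == 20
        assert {r.track_id for r in records} == {0}

    def test_no_initialization_errors_at_stream_end(self):
        scene = small_scene(n_frames=5)
        truth = simulate_truth(scene)
        frames, _ = generate_scene(scene)
        with pytest.raises(RuntimeError, match="cannot initialize"):
            track_video(frames, TruthDetector(scene, truth), 3)

    def test_stale_flag_after_long_coast(self):
        scene = small_scene(n_frames=30, detection_noise=0.0)
        truth = simulate_truth(scene)
        det = SuppressWindow(TruthDetector(scene, truth), 5, 30)
        frames, _ = generate_scene(scene)
        cfg = TrackerConfig(max_coast=10)
        records = track_video(frames, det, 1, cfg)
        assert any(r.stale for r in records if r.frame_index > 16)
        assert not any(r.stale for r in records if r.frame_index < 15)

    def test_ninepoint_correction_reduces_fill_error_on_turns(self):
        scene = ArenaScene(width=512, height=400, n_animals=2, n_frames=80, speed=6.0,
                           turn_rate=0.08, heading_jitter=0.0, noise_sigma=3.0,
                           detection_noise=1.0, min_separation=150, seed=5)
        truth = simulate_truth(scene)
        errs = {}
        for corr in (True, False):
            det = SuppressWindow(TruthDetector(scene, truth), 40, 48)
            frames, _ = generate_scene(scene)
            records = track_video(frames, det, 2, TrackerConfig(correct_filled=corr))
            errs[corr] = position_errors(records, truth)[SOURCE_FILLED]
        assert errs[True] < errs[False]


class TestExplorationMap:
    def test_single_point_single_cell(self):
        records = [TrackRecord(t, 0, Point2D(55.0, 44.0), SOURCE_DETECTED) for t in range(7)]
        grid = exploration_map(records, (0, 0, 400, 300))
        assert grid.total == 7
        assert (grid.counts > 0).sum() == 1

    def test_uniform_cell_centers_uniform_counts(self):
        arena = (0.0, 0.0, 400.0, 300.0)
        records = []
        t = 0
        for row in range(30):
            for col in range(40):
                records.append(TrackRecord(t, 0, Point2D(col * 10 + 5.0, row * 10 + 5.0), SOURCE_DETECTED))
                t += 1
        grid = exploration_map(records, arena)
        assert (grid.counts == 1).all()

    def test_random_walk_conserves_total(self, rng):
        x, y = 200.0, 150.0
        records = []
        for t in range(1000):
            x = float(np.clip(x + rng.normal(0, 5), 0, 400))
            y = float(np.clip(y + rng.normal(0, 5), 0, 300))
            records.append(TrackRecord(t, 0, Point2D(x, y), SOURCE_DETECTED))
        grid = exploration_map(records, (0, 0, 400, 300))
        assert grid.total == 1000

    def test_outside_arena_names_record(self):
        records = [TrackRecord(3, 7, Point2D(500.0, 10.0), SOURCE_DETECTED)]
        with pytest.raises(ValueError, match="frame 3, id 7"):
            exploration_map(records, (0, 0, 400, 300))

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            exploration_map([], (0, 0, 400, 300))


class TestPlotOutputs:
    def test_empty_records_rejected(self, tmp_path):
        grid = exploration_map([TrackRecord(0, 0, Point2D(1, 1), SOURCE_DETECTED)], (0, 0, 10, 10))
        with pytest.raises(ValueError):
            plot_outputs([], grid, tmp_path)

    def test_three_track_outputs_roundtrip(self, tmp_path):
        scene = small_scene(width=400, height=300, n_animals=3, n_frames=15, min_separation=80, seed=8)
        records, _ = run_scene(scene)
        grid = exploration_map(records, (0, 0, 400, 300))
        paths = plot_outputs(records, grid, tmp_path)
        for p in paths.values():
            assert p.exists() and p.stat().st_size > 0
        df = read_records_csv(paths["csv"])
        assert sorted(df["track_id"].unique()) == [0, 1, 2]

    def test_stationary_track_single_hot_cell(self, tmp_path):
        records = [TrackRecord(t, 0, Point2D(100.0, 100.0), SOURCE_DETECTED) for t in range(20)]
        grid = exploration_map(records, (0, 0, 400, 300))
        paths = plot_outputs(records, grid, tmp_path)
        assert (grid.counts == 20).sum() == 1 and grid.total == 20
        assert paths["heatmap"].exists()


def test_detection_tally_buckets():
    tally = detection_tally([0, 1, 3, 3, 4, 5, 2], n_objects=3)
    assert tally == {"0": 1, "1": 1, "2": 1, "3": 2, ">3": 2}
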