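"""Hungarian identity assignment and prediction-augmented costs."""

import itertools
import math

import numpy as np
import pytest

from rodtrack import KalmanParams, Point2D, associate, cost_matrix, init_track, predict, solve_assignment, update
from rodtrack import TrackerConfig, TruthDetector, crossing_scene, generate_scene, simulate_truth, track_video
from rodtrack.tracker import count_id_switches


def brute_force_min_cost(cost):
    """Exhaustive minimum assignment cost over all permutations."""
    rows, cols = cost.shape
    if rows <= cols:
        return min(sum(cost[i, p[i]] for i in range(rows)) for p in itertools.permutations(range(cols), rows))
    return min(sum(cost[p[j], j] for j in range(cols)) for p in itertools.permutations(range(rows), cols))


class TestCostMatrix:
    def test_coincident_points_zero_diagonal(self):
        pts = [Point2D(1, 2), Point2D(3, 4)]
        c = cost_matrix(pts, pts)
        assert np.allclose(np.diag(c), 0.0)

    def test_three_four_five(self):
        c = cost_matrix([Point2D(0, 0)], [Point2D(3, 4)])
        assert c.tolist() == [[5.0]]

    def test_elementwise_hypot(self, rng):
        tracks = [Point2D(*rng.uniform(0, 100, 2)) for _ in range(3)]
        dets = [Point2D(*rng.uniform(0, 100, 2)) for _ in range(3)]
        c = cost_matrix(tracks, dets)
        for i, t in enumerate(tracks):
            for j, d in enumerate(dets):
                assert c[i, j] == pytest.approx(math.hypot(t.x - d.x, t.y - d.y), abs=1e-12)


class TestSolveAssignment:
    def test_identity_dominant(self):
        assert solve_assignment(np.array([[0.0, 5.0], [5.0, 0.0]])) == [(0, 0), (1, 1)]

    def test_anti_diagonal(self):
        assert solve_assignment(np.array([[5.0, 0.0], [0.0, 5.0]])) == [(0, 1), (1, 0)]

    def test_empty(self):
        assert solve_assignment(np.zeros((0, 0))) == []

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            solve_assignment(np.array([[np.inf]]))

    def test_matches_exhaustive_minimum(self, rng):
        for _ in range(40):
            n, m = rng.integers(2, 7, 2)
            cost = rng.uniform(0, 100, (int(n), int(m)))
            pairs = solve_assignment(cost)
            assert len(pairs) == min(n, m)
            total = sum(cost[i, j] for i, j in pairs)
            assert total == pytest.approx(brute_force_min_cost(cost), abs=1e-9)


def settled_track(tid, x, y, vx, vy, n_warm=8):
    """A track whose filter has converged onto an exact trajectory."""
    p = KalmanParams(r_pos=1e-9)
    t = init_track(tid, Point2D(x - n_warm * vx, y - n_warm * vy), p)
    for k in range(1, n_warm + 1):
        t = update(predict(t, params=p), Point2D(x - (n_warm - k) * vx, y - (n_warm - k) * vy), p)
    return t


class TestAssociate:
    def test_identity_when_stationary(self):
        tracks = [settled_track(0, 10, 10, 0, 0), settled_track(1, 200, 200, 0, 0)]
        dets = [Point2D(10, 10), Point2D(200, 200)]
        for mode in ("last_position", "kalman_predicted"):
            a = associate(tracks, dets, mode=mode)
            assert a.matches == [(0, 0), (1, 1)]
            assert a.unmatched_tracks == [] and a.unmatched_detections == []

    def test_crossing_modes_disagree(self):
        # two animals heading toward each other swap proximal positions
        a_track = settled_track(0, 502, 380, 8, 0)
        b_track = settled_track(1, 510, 380, -8, 0)
        dets = [Point2D(510, 380), Point2D(502, 380)]  # next-frame true positions
        swap = associate([a_track, b_track], dets, mode="last_position")
        keep = associate([a_track, b_track], dets, mode="kalman_predicted")
        assert swap.matches == [(0, 1), (1, 0)]  # identity swap: the failure mode
        assert keep.matches == [(0, 0), (1, 1)]

    def test_rectangular_more_tracks_than_detections(self):
        tracks = [settled_track(i, 100 * i + 10, 50, 0, 0) for i in range(3)]
        dets = [Point2D(10, 50), Point2D(210, 50)]
        a = associate(tracks, dets)
        assert len(a.matches) == 2
        assert a.unmatched_tracks == [1]
        assert a.unmatched_detections == []

    def test_gate_rejects_far_detection(self):
        tracks = [settled_track(0, 10, 10, 0, 0)]
        a = associate(tracks, [Point2D(900, 900)], gate=150.0)
        assert a.matches == [] and a.unmatched_tracks == [0] and a.unmatched_detections == [0]

    def test_permutation_equivariant(self, rng):
        tracks = [settled_track(i, *rng.uniform(50, 400, 2), 0, 0) for i in range(4)]
        dets = [Point2D(t.state[0] + rng.normal(0, 3), t.state[1] + rng.normal(0, 3)) for t in tracks]
        base = associate(tracks, dets)
        perm = [2, 0, 3, 1]
        shuffled = [dets[j] for j in perm]
        out = associate(tracks, shuffled)
        remapped = sorted((ti, perm.index(dj)) for ti, dj in base.matches)
        assert sorted(out.matches) == remapped

    def test_empty_sides(self):
        a = associate([], [Point2D(0, 0)])
        assert a.matches == [] and a.unmatched_detections == [0]


class TestCrossingBenchmark:
    def test_no_id_switches_with_prediction_on_three_animals(self):
        scene, _ = crossing_scene(n_frames=200, n_animals=3)
        truth = simulate_truth(scene)
        frames, _ = generate_scene(scene)
        records = track_video(frames, TruthDetector(scene, truth), 3, TrackerConfig(mode="kalman_predicted"))
        assert count_id_switches(records, truth) == 0
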