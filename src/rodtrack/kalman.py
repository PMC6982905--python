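"""Constant-velocity Kalman filter for per-animal position tracking.

State is ``(x, y, vx, vy)`` in pixels and pixels/frame.  The transition is
the linear constant-velocity model

    x_{t+1} = x_t + vx_t * dt,   y_{t+1} = y_t + vy_t * dt,
    vx_{t+1} = vx_t,             vy_{t+1} = vy_t,

with additive process noise, and the measurement is the position alone
(H = [[1,0,0,0],[0,1,0,0]]).  Predictions fill an animal's position on frames
where the detector misses it and feed the identity-assignment cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import Point2D

_H = np.array([[1.0, 0.0, 0.0, 0.0], [0.0, 1.0, 0.0, 0.0]])


@dataclass
class KalmanParams:
    """Noise and initialization settings, all in pixel units.

    Position is measured directly, so measurement noise ``r_pos`` is moderate;
    velocity is never observed and changes as the animal turns, so its process
    noise ``q_vel`` is an order of magnitude above ``q_pos``.
    """

    q_pos: float = 1.0
    q_vel: float = 10.0
    r_pos: float = 10.0
    p0_pos: float = 10.0
    p0_vel: float = 100.0
    dt: float = 1.0

    @property
    def Q(self) -> np.ndarray:
        return np.diag([self.q_pos, self.q_pos, self.q_vel, self.q_vel])

    @property
    def R(self) -> np.ndarray:
        return np.diag([self.r_pos, self.r_pos])


@dataclass
class TrackState:
    """One animal's filter state plus identity and provenance bookkeeping."""

    id: int
    state: np.ndarray  # (x, y, vx, vy)
    covariance: np.ndarray  # 4x4 PSD
    frames_since_detection: int = 0
    source_last: str = "detected"

    @property
    def position(self) -> Point2D:
        return Point2D(float(self.state[0]), float(self.state[1]))

    @property
    def velocity(self) -> tuple:
        return float(self.state[2]), float(self.state[3])


def init_track(track_id: int, position: Point2D, params: KalmanParams | None = None) -> TrackState:
    """Start a track at a first detection with zero velocity and broad
    velocity uncertainty."""
    p = params or KalmanParams()
    state = np.array([position.x, position.y, 0.0, 0.0])
    cov = np.diag([p.p0_pos, p.p0_pos, p.p0_vel, p.p0_vel])
    return TrackState(id=track_id, state=state, covariance=cov)


def transition_matrix(dt: float) -> np.ndarray:
    F = np.eye(4)
    F[0, 2] = dt
    F[1, 3] = dt
    return F


def predict(track: TrackState, dt: float | None = None, params: KalmanParams | None = None) -> TrackState:
    """One-step prediction: position advances by velocity*dt, velocity held."""
    p = params or KalmanParams()
    if dt is None:
        dt = p.dt
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    F = transition_matrix(dt)
    state = F @ track.state
    cov = F @ track.covariance @ F.T + p.Q
    cov = 0.5 * (cov + cov.T)
    return replace(track, state=state, covariance=cov)


def update(track: TrackState, measurement: Point2D, params: KalmanParams | None = None) -> TrackState:
    """Standard Kalman measurement update with a position-only observation.

    Uses the Joseph-form covariance update, which keeps the covariance
    symmetric positive-semidefinite under arbitrary predict/update
    interleavings.
    """
    p = params or KalmanParams()
    z = np.array([measurement.x, measurement.y])
    if not np.all(np.isfinite(z)):
        raise ValueError(f"non-finite measurement {z}")
    P = track.covariance
    S = _H @ P @ _H.T + p.R
    K = P @ _H.T @ np.linalg.inv(S)
    state = track.state + K @ (z - _H @ track.state)
    IKH = np.eye(4) - K @ _H
    cov = IKH @ P @ IKH.T + K @ p.R @ K.T
    cov = 0.5 * (cov + cov.T)
    return replace(track, state=state, covariance=cov)
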