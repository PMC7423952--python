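"""Tracking-by-detection with Hungarian assignment and Kalman coasting.

Each animal receives a virtual identity (vID).  Per frame: existing tracks
predict their box via a constant-velocity Kalman filter on the centroid;
predictions are matched to detections by minimum ``1 - IoU`` cost with a
gate and an explicit cost of non-assignment (Munkres/Hungarian, via
``scipy.optimize.linear_sum_assignment``); matched tracks update, unmatched
detections spawn tentative tracks, unmatched tracks coast.  Tentative tracks
confirm after ``M`` consecutive hits and are deleted on their first miss;
confirmed tracks are deleted after more than ``L`` consecutive misses.
Only tracks that were ever confirmed are returned as valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .detections import BehaviourClass, Detection
from .geometry import BoundingBox, centroid, iou

__all__ = [
    "KalmanState",
    "TrackStatus",
    "Track",
    "TrackerConfig",
    "TrackSet",
    "Tracker",
    "assignment_cost",
    "solve_assignment",
    "track_sequence",
    "FORBIDDEN",
]

#: sentinel cost for gated (disallowed) track-detection pairs
FORBIDDEN = float("inf")


class KalmanState:
    """Constant-velocity Kalman filter on the box centroid.

    State is ``(cx, cy, vx, vy)`` in pixels and pixels/frame; only the
    position is observed.  The covariance stays symmetric positive
    semi-definite by construction (symmetrised after each update).
    """

    F = np.array([[1, 0, 1, 0],
                  [0, 1, 0, 1],
                  [0, 0, 1, 0],
                  [0, 0, 0, 1]], dtype=float)
    H = np.array([[1, 0, 0, 0],
                  [0, 1, 0, 0]], dtype=float)

    def __init__(self, cx: float, cy: float, process_noise: float = 1.0,
                 measurement_noise: float = 1.0):
        self.x = np.array([cx, cy, 0.0, 0.0])
        # velocity is unobserved at birth: generous variance lets the first
        # updates pin it down quickly
        self.P = np.diag([measurement_noise, measurement_noise, 100.0, 100.0])
        q = process_noise
        self.Q = np.diag([0.25 * q, 0.25 * q, q, q])
        self.R = np.eye(2) * measurement_noise

    def predict(self) -> tuple[float, float]:
        self.x = self.F @ self.x
        self.P = self.F @ self.P @ self.F.T + self.Q
        self.P = 0.5 * (self.P + self.P.T)
        return float(self.x[0]), float(self.x[1])

    def update(self, cx: float, cy: float) -> None:
        z = np.array([cx, cy])
        y = z - self.H @ self.x
        S = self.H @ self.P @ self.H.T + self.R
        K = self.P @ self.H.T @ np.linalg.inv(S)
        self.x = self.x + K @ y
        I_KH = np.eye(4) - K @ self.H
        # Joseph form keeps P symmetric PSD
        self.P = I_KH @ self.P @ I_KH.T + K @ self.R @ K.T
        self.P = 0.5 * (self.P + self.P.T)

    @property
    def position(self) -> tuple[float, float]:
        return float(self.x[0]), float(self.x[1])

    @property
    def velocity(self) -> tuple[float, float]:
        return float(self.x[2]), float(self.x[3])


class TrackStatus(str, Enum):
    TENTATIVE = "tentative"
    CONFIRMED = "confirmed"
    DELETED = "deleted"


@dataclass
class TrackSample:
    frame: int
    box: BoundingBox
    cls: BehaviourClass
    source: str  # "detected" | "coasted"
    score: float = 1.0


@dataclass
class Track:
    """One virtual identity with Kalman state, lifecycle and history."""

    vid: int
    status: TrackStatus
    kalman: KalmanState
    last_box_shape: tuple[float, float]
    consecutive_hits: int = 0
    consecutive_misses: int = 0
    ever_confirmed: bool = False
    history: list[TrackSample] = field(default_factory=list)
    _predicted_box: BoundingBox | None = None

    def predict(self) -> BoundingBox:
        """One-step prediction: centroid advanced by the model, shape carried."""
        cx, cy = self.kalman.predict()
        w, h = self.last_box_shape
        self._predicted_box = BoundingBox(cx - w / 2.0, cy - h / 2.0, w, h)
        return self._predicted_box


@dataclass(frozen=True)
class TrackerConfig:
    """Gating, lifecycle and noise parameters for the tracker."""

    gate_iou_min: float = 0.3
    cost_of_non_assignment: float = 0.7
    confirm_hits: int = 3       # M: consecutive hits to confirm a tentative track
    max_coast: int = 10         # L: coasted frames before a confirmed track dies
    process_noise: float = 1.0
    measurement_noise: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.gate_iou_min < 1.0):
            raise ValueError(f"gate_iou_min must be in [0, 1), got {self.gate_iou_min}")
        if self.confirm_hits < 1:
            raise ValueError(f"confirm_hits must be >= 1, got {self.confirm_hits}")
        if self.max_coast < 0:
            raise ValueError(f"max_coast must be >= 0, got {self.max_coast}")


@dataclass
class TrackSet:
    """Valid (ever-confirmed) tracks plus a lifecycle audit log."""

    tracks: list[Track]
    events: list[tuple[int, int, str]]  # (frame, vid, event)

    def by_vid(self) -> dict[int, Track]:
        return {t.vid: t for t in self.tracks}

    def to_detections(self) -> list[tuple[int, Detection]]:
        """Flatten to (vid, Detection) pairs for evaluation/serialisation."""
        out = []
        for t in self.tracks:
            for s in t.history:
                out.append((t.vid, Detection(frame=s.frame, box=s.box, cls=s.cls, score=s.score)))
        return out


def assignment_cost(predicted: Sequence[BoundingBox], detections: Sequence[Detection],
                    gate_iou_min: float) -> np.ndarray:
    """Cost matrix ``1 - IoU``; pairs below the IoU gate are FORBIDDEN."""
    cost = np.full((len(predicted), len(detections)), FORBIDDEN)
    for i, p in enumerate(predicted):
        for j, d in enumerate(detections):
            ov = iou(p, d.box)
            if ov >= gate_iou_min and ov > 0.0:
                cost[i, j] = 1.0 - ov
    return cost


def solve_assignment(
    cost: np.ndarray, cost_of_non_assignment: float
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Globally optimal assignment allowing rows/columns to stay unassigned.

    The matrix is augmented with per-row and per-column dummy nodes priced at
    ``cost_of_non_assignment``, so the solution minimises total cost
    including the price of leaving tracks/detections unmatched.  Returns
    ``(matches, unmatched_rows, unmatched_cols)``.
    """
    n, m = cost.shape
    if n == 0 or m == 0:
        return [], list(range(n)), list(range(m))
    big = 1e9
    padded = np.full((n + m, m + n), 0.0)
    core = np.where(np.isfinite(cost), cost, big)
    padded[:n, :m] = core
    padded[:n, m:] = big
    padded[n:, :m] = big
    padded[np.arange(n), m + np.arange(n)] = cost_of_non_assignment
    padded[n + np.arange(m), np.arange(m)] = cost_of_non_assignment
    rows, cols = linear_sum_assignment(padded)
    matches, un_rows, un_cols = [], [], []
    matched_cols: set[int] = set()
    for r, c in zip(rows, cols):
        if r < n and c < m and np.isfinite(cost[r, c]):
            matches.append((r, c))
            matched_cols.add(c)
        elif r < n and (c >= m or not np.isfinite(cost[r, c])):
            un_rows.append(r)
    un_rows = sorted(set(range(n)) - {r for r, _ in matches})
    un_cols = sorted(set(range(m)) - matched_cols)
    return matches, un_rows, un_cols


class Tracker:
    """Stateful tracker; call :meth:`step` once per recorded frame, in order."""

    def __init__(self, config: TrackerConfig | None = None):
        self.config = config or TrackerConfig()
        self.tracks: list[Track] = []
        self.finished: list[Track] = []
        self.events: list[tuple[int, int, str]] = []
        self._next_vid = 1
        self._last_frame: int | None = None

    def step(self, detections: Sequence[Detection], frame: int) -> None:
        cfg = self.config
        if self._last_frame is not None and frame <= self._last_frame:
            raise ValueError(
                f"frames must be processed in increasing order: got {frame} after {self._last_frame}"
            )
        self._last_frame = frame

        predicted = [t.predict() for t in self.tracks]
        cost = assignment_cost(predicted, detections, cfg.gate_iou_min)
        matches, un_tracks, un_dets = solve_assignment(cost, cfg.cost_of_non_assignment)

        for ti, dj in matches:
            t = self.tracks[ti]
            d = detections[dj]
            c = centroid(d.box)
            t.kalman.update(c.cx, c.cy)
            t.last_box_shape = d.box.shape()
            t.consecutive_hits += 1
            t.consecutive_misses = 0
            t.history.append(TrackSample(frame, d.box, d.cls, "detected", d.score))
            if t.status is TrackStatus.TENTATIVE and t.consecutive_hits >= cfg.confirm_hits:
                t.status = TrackStatus.CONFIRMED
                t.ever_confirmed = True
                self.events.append((frame, t.vid, "confirmed"))

        doomed: list[Track] = []
        for ti in un_tracks:
            t = self.tracks[ti]
            if t.status is TrackStatus.TENTATIVE:
                # a tentative track missing once is presumed a false detection
                t.status = TrackStatus.DELETED
                self.events.append((frame, t.vid, "deleted_tentative"))
                doomed.append(t)
                continue
            t.consecutive_misses += 1
            t.consecutive_hits = 0
            if t.consecutive_misses > cfg.max_coast:
                t.status = TrackStatus.DELETED
                self.events.append((frame, t.vid, "deleted_lost"))
                doomed.append(t)
            else:
                box = t._predicted_box if t._predicted_box is not None else None
                last_cls = t.history[-1].cls if t.history else BehaviourClass.STANDING
                if box is not None:
                    t.history.append(TrackSample(frame, box, last_cls, "coasted", 0.0))

        for t in doomed:
            self.tracks.remove(t)
            self.finished.append(t)

        for dj in un_dets:
            d = detections[dj]
            c = centroid(d.box)
            t = Track(
                vid=self._next_vid,
                status=TrackStatus.TENTATIVE,
                kalman=KalmanState(c.cx, c.cy, self.config.process_noise,
                                   self.config.measurement_noise),
                last_box_shape=d.box.shape(),
                consecutive_hits=1,
            )
            t.history.append(TrackSample(frame, d.box, d.cls, "detected", d.score))
            if self.config.confirm_hits <= 1:
                t.status = TrackStatus.CONFIRMED
                t.ever_confirmed = True
                self.events.append((frame, t.vid, "confirmed"))
            self._next_vid += 1
            self.tracks.append(t)
            self.events.append((frame, t.vid, "created"))

    def result(self) -> TrackSet:
        """Valid tracks only (ever confirmed), trailing coasted samples trimmed."""
        valid = [t for t in self.tracks + self.finished if t.ever_confirmed]
        for t in valid:
            while t.history and t.history[-1].source == "coasted":
                t.history.pop()
        valid.sort(key=lambda t: t.vid)
        return TrackSet(tracks=valid, events=list(self.events))


def track_sequence(
    detections_by_frame: Mapping[int, Sequence[Detection]] | Iterable[Detection],
    config: TrackerConfig | None = None,
) -> TrackSet:
    """Fold :meth:`Tracker.step` over frames in increasing order."""
    if not isinstance(detections_by_frame, Mapping):
        from .detections import group_by_frame

        detections_by_frame = group_by_frame(detections_by_frame)
    tracker = Tracker(config)
    for frame in sorted(detections_by_frame):
        tracker.step(detections_by_frame[frame], frame)
    return tracker.result()
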