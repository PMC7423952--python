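"""Seeded synthetic pen generator and detector-degradation channel.

The world model: each animal is a rigid box whose behaviour follows a
five-state Markov chain.  The centroid moves (random-heading walk with wall
reflection) only while standing; drinking is entered only within a
configured radius of a drinker and snaps the box onto it; lying and sitting
animals are stationary.  Box shape depends on posture (lateral lying is
elongated, sitting compact) so anchor clustering has structure to find.
Overlap between animals is allowed — it stresses the tracker's gating.

Two independent RNG streams are used: the world stream (``PenConfig.seed``)
and the noise stream (``NoiseConfig.seed``), so one world can be degraded
at several noise levels for paired comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .detections import Annotation, BehaviourClass, Detection, FrameSequence
from .geometry import BoundingBox, Point, centroid

__all__ = [
    "PenConfig",
    "NoiseConfig",
    "SimOutput",
    "simulate",
    "degrade",
    "feeding_disruption_schedule",
    "behaviour_transition_matrix",
    "stationary_distribution",
]

_B = list(BehaviourClass)
_BIDX = {b: i for i, b in enumerate(_B)}

#: posture-dependent multipliers applied to an animal's base (width, height)
_SHAPE_BY_POSTURE: dict[BehaviourClass, tuple[float, float]] = {
    BehaviourClass.STANDING: (1.0, 1.0),
    BehaviourClass.SITTING: (0.75, 0.75),
    BehaviourClass.LATERAL_LYING: (1.6, 0.9),
    BehaviourClass.STERNAL_LYING: (1.2, 1.0),
    BehaviourClass.DRINKING: (1.0, 1.0),
}


def behaviour_transition_matrix(
    stationary: Sequence[float] | dict[BehaviourClass, float] | None = None,
    persistence: float = 0.9,
) -> np.ndarray:
    """Row-stochastic 5x5 chain with the given stationary distribution.

    Built as ``P = a*I + (1-a)*1 pi^T`` (a "lazy" chain): each step either
    stays put with probability ``a`` or resamples from ``pi``, whose
    stationary distribution is exactly ``pi``.
    """
    if stationary is None:
        pi = np.array([0.25, 0.10, 0.30, 0.30, 0.05])
    elif isinstance(stationary, dict):
        pi = np.array([stationary.get(b, 0.0) for b in _B], dtype=float)
    else:
        pi = np.asarray(stationary, dtype=float)
    if pi.shape != (5,) or (pi < 0).any() or not math.isclose(pi.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("stationary distribution must be 5 non-negative values summing to 1")
    if not (0.0 <= persistence < 1.0):
        raise ValueError("persistence must be in [0, 1)")
    return persistence * np.eye(5) + (1.0 - persistence) * np.outer(np.ones(5), pi)


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Left eigenvector of the chain for eigenvalue 1, normalised to sum 1."""
    vals, vecs = np.linalg.eig(transition.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


@dataclass(frozen=True)
class PenConfig:
    """World parameters: pen geometry, population, behaviour dynamics."""

    width: float = 640.0
    height: float = 360.0
    fps: float = 25.0
    n_pigs: int = 15
    drinkers: tuple[Point, ...] = (
        Point(30.0, 60.0), Point(30.0, 140.0), Point(30.0, 220.0), Point(30.0, 300.0),
    )
    drinker_radius: float = 40.0
    box_size_range: tuple[float, float] = (40.0, 70.0)  # base width range, px
    box_aspect: float = 0.45                             # base height = width * aspect
    transition: np.ndarray = field(default_factory=behaviour_transition_matrix)
    speed_range: tuple[float, float] = (1.0, 5.0)        # standing walk, px/frame
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.transition, dtype=float)
        if t.shape != (5, 5) or (t < 0).any() or not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition must be a 5x5 row-stochastic matrix")
        object.__setattr__(self, "transition", t)
        if self.n_pigs < 1:
            raise ValueError("n_pigs must be >= 1")
        for d in self.drinkers:
            if not (0 <= d.cx <= self.width and 0 <= d.cy <= self.height):
                raise ValueError(f"drinker {d} lies outside the pen")
        drink_i = _BIDX[BehaviourClass.DRINKING]
        if not self.drinkers:
            into_drinking = np.delete(t[:, drink_i], drink_i).max()
            if into_drinking > 0 or stationary_distribution(t)[drink_i] > 1e-12:
                raise ValueError("drinking has positive probability but the pen has no drinkers")


@dataclass(frozen=True)
class NoiseConfig:
    """Detector/recorder degradation parameters."""

    jitter_sigma: float = 0.0      # Gaussian px noise on box corners
    miss_rate: float = 0.0         # per-box drop probability
    fp_rate: float = 0.0           # expected false positives per frame (Poisson)
    class_confusion: float = 0.0   # probability a surviving box's class flips
    frame_drop_rate: float = 0.0   # whole-frame deletion probability
    tp_score: tuple[float, float] = (0.85, 0.08)   # mean, sd of true-box scores
    fp_score: tuple[float, float] = (0.40, 0.15)   # mean, sd of false-box scores
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("miss_rate", "class_confusion", "frame_drop_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.jitter_sigma < 0 or self.fp_rate < 0:
            raise ValueError("jitter_sigma and fp_rate must be >= 0")


@dataclass(frozen=True)
class SimOutput:
    """Ground truth plus the bookkeeping needed as recovery targets."""

    config: PenConfig
    frames: FrameSequence
    annotations: tuple[Annotation, ...]
    path_lengths: dict[int, float]                      # per pig, px
    dwell_fractions: dict[int, dict[BehaviourClass, float]]

    def annotations_by_frame(self) -> dict[int, list[Annotation]]:
        out: dict[int, list[Annotation]] = {f: [] for f in self.frames.frames}
        for a in self.annotations:
            out[a.frame].append(a)
        return out


def _posture_box(cx: float, cy: float, base_w: float, base_h: float,
                 posture: BehaviourClass, pen: PenConfig) -> BoundingBox:
    mw, mh = _SHAPE_BY_POSTURE[posture]
    w, h = base_w * mw, base_h * mh
    x = min(max(cx - w / 2.0, 0.0), pen.width - w)
    y = min(max(cy - h / 2.0, 0.0), pen.height - h)
    return BoundingBox(x, y, w, h)


def _reflect(v: float, lo: float, hi: float) -> float:
    span = hi - lo
    if span <= 0:
        return lo
    v = (v - lo) % (2 * span)
    return lo + (span - abs(v - span))


def simulate(pen: PenConfig, n_frames: int) -> SimOutput:
    """Generate ``n_frames`` of ground truth, deterministic per seed."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(pen.seed)
    n = pen.n_pigs
    base_w = rng.uniform(*pen.box_size_range, size=n)
    base_h = base_w * pen.box_aspect
    margin_x = base_w.max()
    margin_y = base_h.max()
    cx = rng.uniform(margin_x, pen.width - margin_x, size=n)
    cy = rng.uniform(margin_y, pen.height - margin_y, size=n)
    heading = rng.uniform(0, 2 * np.pi, size=n)
    speed = rng.uniform(*pen.speed_range, size=n)
    pi0 = stationary_distribution(pen.transition)
    state = rng.choice(5, size=n, p=pi0)
    drink_i = _BIDX[BehaviourClass.DRINKING]
    stand_i = _BIDX[BehaviourClass.STANDING]
    # a pig cannot start out drinking away from every drinker
    for p in range(n):
        if state[p] == drink_i:
            near = pen.drinkers and any(
                math.hypot(d.cx - cx[p], d.cy - cy[p]) <= pen.drinker_radius
                for d in pen.drinkers
            )
            if not near:
                state[p] = stand_i

    annotations: list[Annotation] = []
    path_lengths = {pid: 0.0 for pid in range(n)}
    prev_centroid: dict[int, Point | None] = {pid: None for pid in range(n)}
    dwell = {pid: {b: 0 for b in _B} for pid in range(n)}
    drinker_xy = np.array([[d.cx, d.cy] for d in pen.drinkers]) if pen.drinkers else None

    for f in range(n_frames):
        for p in range(n):
            # behaviour transition (after the first frame)
            if f > 0:
                nxt = int(rng.choice(5, p=pen.transition[state[p]]))
                if nxt == drink_i and state[p] != drink_i:
                    near = (
                        drinker_xy is not None
                        and np.min(np.hypot(drinker_xy[:, 0] - cx[p],
                                            drinker_xy[:, 1] - cy[p])) <= pen.drinker_radius
                    )
                    if not near:
                        nxt = state[p]  # cannot start drinking away from a drinker
                if nxt != state[p] and _B[nxt] is BehaviourClass.STANDING:
                    heading[p] = rng.uniform(0, 2 * np.pi)
                    speed[p] = rng.uniform(*pen.speed_range)
                state[p] = nxt
            beh = _B[state[p]]
            if beh is BehaviourClass.STANDING and f > 0:
                heading[p] += rng.normal(0.0, 0.15)
                nx = cx[p] + speed[p] * math.cos(heading[p])
                ny = cy[p] + speed[p] * math.sin(heading[p])
                # margin = half the widest posture box, so boxes stay in-pen
                mx, my = 0.8 * base_w[p], 0.5 * base_h[p]
                rx = _reflect(nx, mx, pen.width - mx)
                ry = _reflect(ny, my, pen.height - my)
                cx[p], cy[p] = rx, ry
            dwell[p][beh] += 1
            box = _posture_box(cx[p], cy[p], base_w[p], base_h[p], beh, pen)
            annotations.append(Annotation(frame=f, box=box, cls=beh, gt_id=p))
            # path length is the observable trajectory: emitted box centroids
            c = centroid(box)
            if prev_centroid[p] is not None:
                path_lengths[p] += c.distance_to(prev_centroid[p])
            prev_centroid[p] = c
    frames = FrameSequence(
        frames=tuple(range(n_frames)),
        timestamps=tuple(f / pen.fps for f in range(n_frames)),
        fps=pen.fps,
    )
    dwell_frac = {
        pid: {b: c / n_frames for b, c in counts.items()} for pid, counts in dwell.items()
    }
    return SimOutput(config=pen, frames=frames, annotations=tuple(annotations),
                     path_lengths=path_lengths, dwell_fractions=dwell_frac)


def degrade(sim: SimOutput, noise: NoiseConfig) -> tuple[list[Detection], FrameSequence]:
    """Apply detector/recorder noise to ground truth; deterministic per seed."""
    rng = np.random.default_rng(noise.seed)
    pen = sim.config
    by_frame = sim.annotations_by_frame()
    kept_frames: list[int] = []
    kept_stamps: list[float] = []
    detections: list[Detection] = []
    others = {b: [o for o in _B if o != b] for b in _B}
    for f, t in zip(sim.frames.frames, sim.frames.timestamps):
        if rng.random() < noise.frame_drop_rate:
            continue
        kept_frames.append(f)
        kept_stamps.append(t)
        for a in by_frame.get(f, []):
            if rng.random() < noise.miss_rate:
                continue
            box = a.box
            if noise.jitter_sigma > 0:
                x1 = box.x + rng.normal(0, noise.jitter_sigma)
                y1 = box.y + rng.normal(0, noise.jitter_sigma)
                x2 = box.x2 + rng.normal(0, noise.jitter_sigma)
                y2 = box.y2 + rng.normal(0, noise.jitter_sigma)
                x1 = min(max(x1, 0.0), pen.width - 1.0)
                y1 = min(max(y1, 0.0), pen.height - 1.0)
                x2 = min(max(x2, x1 + 1.0), pen.width)
                y2 = min(max(y2, y1 + 1.0), pen.height)
                box = BoundingBox(x1, y1, x2 - x1, y2 - y1)
            cls = a.cls
            if rng.random() < noise.class_confusion:
                cls = others[cls][int(rng.integers(4))]
            score = float(np.clip(rng.normal(*noise.tp_score), 0.0, 1.0))
            detections.append(Detection(frame=f, box=box, cls=cls, score=score))
        for _ in range(int(rng.poisson(noise.fp_rate))):
            w = rng.uniform(*pen.box_size_range)
            h = w * pen.box_aspect
            x = rng.uniform(0, pen.width - w)
            y = rng.uniform(0, pen.height - h)
            cls = _B[int(rng.integers(5))]
            score = float(np.clip(rng.normal(*noise.fp_score), 0.0, 1.0))
            detections.append(Detection(frame=f, box=BoundingBox(x, y, w, h),
                                        cls=cls, score=score))
    seq = FrameSequence(frames=tuple(kept_frames), timestamps=tuple(kept_stamps),
                        fps=sim.frames.fps)
    return detections, seq


def feeding_disruption_schedule(
    pen: PenConfig,
    days: int,
    disrupted_days: Sequence[int],
    effects: dict[BehaviourClass, float],
) -> list[PenConfig]:
    """Per-day configs with behaviour budgets shifted on disrupted days.

    ``effects`` multiplies the stationary mass of each behaviour (e.g.
    ``{STANDING: 0.5}`` halves standing) and the result is renormalised into
    a valid stationary distribution; the chain is rebuilt around it with the
    original persistence.  Day seeds differ so days are independent draws.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    bad = [d for d in disrupted_days if not (0 <= d < days)]
    if bad:
        raise ValueError(f"disrupted day indices out of range: {bad}")
    for b, e in effects.items():
        if e < 0:
            raise ValueError(f"effect for {b.value} must be >= 0, got {e}")
    pi = stationary_distribution(pen.transition)
    # recover persistence a from P = a*I + (1-a)*1 pi^T exactly when possible
    off_mass = 1.0 - np.diag(pen.transition)
    with np.errstate(divide="ignore", invalid="ignore"):
        a_est = 1.0 - np.where(1 - pi > 0, off_mass / (1 - pi), 0.0)
    persistence = float(np.clip(np.nanmean(a_est), 0.0, 0.99))
    shifted = pi.copy()
    for b, e in effects.items():
        shifted[_BIDX[b]] *= e
    if shifted.sum() <= 0:
        raise ValueError("effects remove all behaviour mass; no valid distribution exists")
    shifted = shifted / shifted.sum()
    disrupted_cfg_t = behaviour_transition_matrix(shifted, persistence)
    out: list[PenConfig] = []
    disrupted = set(disrupted_days)
    for d in range(days):
        t = disrupted_cfg_t if d in disrupted else pen.transition
        out.append(replace(pen, transition=t, seed=pen.seed + 1000 * (d + 1)))
    return out
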