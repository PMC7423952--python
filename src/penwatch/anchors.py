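"""Anchor-box estimation by K-medoids clustering of box shapes.

Clustering operates on ``(width, height)`` shapes only — anchors are
shape/scale priors, not locations.  The dissimilarity is ``1 - shape_iou``,
which is symmetric and bounded in ``[0, 1]`` but is not assumed to satisfy
the triangle inequality.  The optimiser is PAM-style swap refinement from a
seeded greedy farthest-point initialisation, with a best-of-restarts outer
loop for determinism and quality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .geometry import BoundingBox, shape_iou

__all__ = [
    "AnchorSet",
    "AnchorSweep",
    "shape_distance",
    "kmedoids_anchors",
    "mean_iou_quality",
    "anchor_sweep",
    "shape_scatter",
]

Shape = tuple[float, float]


def shape_distance(a: Shape, b: Shape) -> float:
    """``1 - shape_iou``; 0 for identical shapes, approaching 1 for dissimilar ones."""
    return 1.0 - shape_iou(a, b)


@dataclass(frozen=True)
class AnchorSet:
    """Result of one K-medoids anchor estimation.

    Every anchor is the shape of some input box (medoid property) and the
    anchors are distinct as shapes.
    """

    k: int
    anchors: tuple[Shape, ...]
    mean_iou: float
    seed: int
    restarts: int

    def __post_init__(self) -> None:
        if self.k != len(self.anchors):
            raise ValueError("k must equal the number of anchors")
        if len(set(self.anchors)) != len(self.anchors):
            raise ValueError("anchors must be distinct shapes")


@dataclass(frozen=True)
class AnchorSweep:
    """Quality trade-off curve over anchor counts."""

    k_values: tuple[int, ...]
    mean_ious: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.k_values) != len(self.mean_ious):
            raise ValueError("k_values and mean_ious must have equal length")
        if any(b <= a for a, b in zip(self.k_values, self.k_values[1:])):
            raise ValueError("k_values must be strictly increasing")


def _unique_shapes(boxes: Sequence[BoundingBox]) -> tuple[list[Shape], np.ndarray]:
    """Distinct shapes with multiplicities, in first-appearance order."""
    counts: dict[Shape, int] = {}
    for b in boxes:
        s = b.shape()
        counts[s] = counts.get(s, 0) + 1
    shapes = list(counts)
    return shapes, np.array([counts[s] for s in shapes], dtype=float)


def _distance_matrix(shapes: Sequence[Shape]) -> np.ndarray:
    w = np.array([s[0] for s in shapes], dtype=float)
    h = np.array([s[1] for s in shapes], dtype=float)
    inter = np.minimum.outer(w, w) * np.minimum.outer(h, h)
    union = np.add.outer(w * h, w * h) - inter
    return 1.0 - inter / union


def _total_cost(dmat: np.ndarray, weights: np.ndarray, medoids: Sequence[int]) -> float:
    return float(weights @ dmat[:, list(medoids)].min(axis=1))


def _greedy_init(dmat: np.ndarray, weights: np.ndarray, k: int, rng: np.random.Generator) -> list[int]:
    """Farthest-point seeding: random first medoid, then maximise distance to the set."""
    n = dmat.shape[0]
    first = int(rng.integers(n))
    medoids = [first]
    nearest = dmat[:, first].copy()
    while len(medoids) < k:
        gain = weights * nearest
        gain[medoids] = -1.0
        nxt = int(np.argmax(gain))
        medoids.append(nxt)
        nearest = np.minimum(nearest, dmat[:, nxt])
    return medoids


def _pam_refine(dmat: np.ndarray, weights: np.ndarray, medoids: list[int]) -> list[int]:
    """Swap refinement: replace a medoid with a non-medoid while total cost drops."""
    n = dmat.shape[0]
    medoids = list(medoids)
    best_cost = _total_cost(dmat, weights, medoids)
    improved = True
    while improved:
        improved = False
        in_set = set(medoids)
        for mi in range(len(medoids)):
            for cand in range(n):
                if cand in in_set:
                    continue
                trial = medoids.copy()
                trial[mi] = cand
                c = _total_cost(dmat, weights, trial)
                if c < best_cost - 1e-12:
                    medoids = trial
                    best_cost = c
                    in_set = set(medoids)
                    improved = True
    return medoids


def _run_kmedoids(
    dmat: np.ndarray,
    weights: np.ndarray,
    shapes: Sequence[Shape],
    k: int,
    seed: int,
    restarts: int,
    warm_starts: Sequence[Sequence[int]] = (),
) -> tuple[list[int], float]:
    best: tuple[float, tuple[Shape, ...], list[int]] | None = None
    starts: list[list[int]] = [list(ws) for ws in warm_starts]
    rng = np.random.default_rng(seed)
    for _ in range(max(1, restarts)):
        starts.append(_greedy_init(dmat, weights, k, rng))
    for init in starts:
        medoids = _pam_refine(dmat, weights, list(init))
        cost = _total_cost(dmat, weights, medoids)
        key_anchors = tuple(sorted(shapes[i] for i in medoids))
        cand = (cost, key_anchors, medoids)
        if best is None or cand[:2] < best[:2]:
            best = cand
    assert best is not None
    return best[2], best[0]


def kmedoids_anchors(
    boxes: Sequence[BoundingBox], k: int, seed: int = 0, restarts: int = 20
) -> AnchorSet:
    """Cluster box shapes into ``k`` medoid anchors minimising total shape distance.

    Deterministic for fixed ``(boxes, k, seed, restarts)``; ties between
    restarts are broken by total cost then lexicographic anchor order.
    """
    if not boxes:
        raise ValueError("cannot estimate anchors from an empty box list")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    shapes, weights = _unique_shapes(boxes)
    if k > len(shapes):
        raise ValueError(f"k={k} exceeds the {len(shapes)} distinct box shapes")
    dmat = _distance_matrix(shapes)
    medoids, cost = _run_kmedoids(dmat, weights, shapes, k, seed, restarts)
    anchors = tuple(sorted(shapes[i] for i in medoids))
    n_boxes = weights.sum()
    return AnchorSet(k=k, anchors=anchors, mean_iou=1.0 - cost / n_boxes, seed=seed, restarts=restarts)


def mean_iou_quality(anchors: AnchorSet | Sequence[Shape], boxes: Sequence[BoundingBox]) -> float:
    """Mean over boxes of the best shape IoU against any anchor (higher is better)."""
    shapes = anchors.anchors if isinstance(anchors, AnchorSet) else tuple(anchors)
    if not shapes:
        raise ValueError("anchor set is empty")
    if not boxes:
        raise ValueError("cannot score quality on an empty box list")
    return float(
        np.mean([max(shape_iou(b.shape(), a) for a in shapes) for b in boxes])
    )


def anchor_sweep(
    boxes: Sequence[BoundingBox], k_max: int = 15, seed: int = 0, restarts: int = 20
) -> AnchorSweep:
    """Quality curve for k = 1..k_max (capped at the number of distinct shapes).

    Each k's restarts include the previous k's medoids plus one farthest
    point as a warm start, which makes the curve non-decreasing in k.
    """
    if k_max < 1:
        raise ValueError(f"k_max must be >= 1, got {k_max}")
    if not boxes:
        raise ValueError("cannot sweep anchors over an empty box list")
    shapes, weights = _unique_shapes(boxes)
    dmat = _distance_matrix(shapes)
    n_boxes = weights.sum()
    k_cap = min(k_max, len(shapes))
    ks: list[int] = []
    quals: list[float] = []
    prev: list[int] | None = None
    for k in range(1, k_cap + 1):
        warm: list[list[int]] = []
        if prev is not None:
            nearest = dmat[:, prev].min(axis=1)
            gain = weights * nearest
            gain[prev] = -1.0
            warm.append(prev + [int(np.argmax(gain))])
        medoids, cost = _run_kmedoids(dmat, weights, shapes, k, seed + k, restarts, warm_starts=warm)
        ks.append(k)
        quals.append(1.0 - cost / n_boxes)
        prev = medoids
    return AnchorSweep(k_values=tuple(ks), mean_ious=tuple(quals))


def shape_scatter(boxes: Sequence[BoundingBox]) -> list[tuple[float, float]]:
    """``(aspect_ratio, area)`` per box, for plotting/inspection."""
    return [(b.aspect_ratio, b.area) for b in boxes]
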