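"""Axis-aligned bounding-box primitives and overlap measures.

Boxes use the ``[x, y, width, height]`` convention with the origin at the
image upper-left corner, ``y`` growing downward and continuous (sub-pixel)
coordinates: a box covers the closed region ``[x, x + width] x [y, y + height]``.
Every overlap computation in the toolkit (anchor clustering, track gating,
detection/tracking evaluation) goes through :func:`iou` or :func:`shape_iou`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["BoundingBox", "Point", "iou", "centroid", "shape_iou"]


@dataclass(frozen=True)
class Point:
    """A 2-D point in pixel coordinates (centroid carrier)."""

    cx: float
    cy: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "cx", float(self.cx))
        object.__setattr__(self, "cy", float(self.cy))
        if not (math.isfinite(self.cx) and math.isfinite(self.cy)):
            raise ValueError(f"point coordinates must be finite, got ({self.cx}, {self.cy})")

    def distance_to(self, other: "Point") -> float:
        return math.hypot(self.cx - other.cx, self.cy - other.cy)


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box; ``(x, y)`` is the upper-left corner.

    Zero or negative extents are rejected at construction so that all
    downstream geometry is total on constructed boxes.
    """

    x: float
    y: float
    width: float
    height: float

    def __post_init__(self) -> None:
        for name in ("x", "y", "width", "height"):
            v = float(getattr(self, name))
            object.__setattr__(self, name, v)
            if not math.isfinite(v):
                raise ValueError(f"box field {name!r} must be finite, got {v}")
        if self.width <= 0 or self.height <= 0:
            raise ValueError(
                f"box extents must be positive, got width={self.width}, height={self.height}"
            )

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def aspect_ratio(self) -> float:
        return self.width / self.height

    @property
    def x2(self) -> float:
        return self.x + self.width

    @property
    def y2(self) -> float:
        return self.y + self.height

    def shape(self) -> tuple[float, float]:
        return (self.width, self.height)

    def shifted(self, dx: float, dy: float) -> "BoundingBox":
        return BoundingBox(self.x + dx, self.y + dy, self.width, self.height)


def centroid(box: BoundingBox) -> Point:
    """Centre point of the box (where the diagonals intersect)."""
    return Point(box.x + box.width / 2.0, box.y + box.height / 2.0)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes on continuous coordinates.

    Symmetric, in ``[0, 1]``; boxes that merely touch along an edge have
    intersection area 0 and therefore IoU 0.
    """
    ix = min(a.x2, b.x2) - max(a.x, b.x)
    iy = min(a.y2, b.y2) - max(a.y, b.y)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


def shape_iou(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Position-free IoU of two box shapes co-aligned at a shared corner.

    Aligning the boxes at a common upper-left corner maximises their overlap,
    so ``shape_iou`` upper-bounds :func:`iou` at any placement of the same
    shapes.
    """
    wa, ha = a
    wb, hb = b
    if wa <= 0 or ha <= 0 or wb <= 0 or hb <= 0:
        raise ValueError(f"shape extents must be positive, got {a} and {b}")
    inter = min(wa, wb) * min(ha, hb)
    union = wa * ha + wb * hb - inter
    return inter / union
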