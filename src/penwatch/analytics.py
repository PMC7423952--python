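"""Group-level behaviour indices and individual animal profiles.

The group-level index for a behaviour over a window of ``N`` recorded frames
is the mean number of animals exhibiting that behaviour per frame —
``sum_k NBF_k / N`` — which stays comparable across windows even when the
recorder drops frames, because ``N`` counts recorded frames only.

Individual profiles need tracks: per-sample (time, centroid, behaviour),
a time budget over behaviours, and locomotion (total centroid path length,
mean speed over true timestamps).  Coasted (prediction-only) samples keep
the trajectory continuous but are excluded from time budgets by default,
since indices count detected behaviours.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .detections import Annotation, BehaviourClass, Detection, FrameSequence, group_by_frame
from .geometry import Point, centroid
from .tracking import Track

__all__ = [
    "Window",
    "BehaviourIndexSeries",
    "IndividualProfile",
    "BaselineSpec",
    "behaviour_index",
    "index_series",
    "percent_change",
    "build_profile",
    "total_distance",
    "mean_speed",
]


@dataclass(frozen=True)
class Window:
    """A labelled contiguous range of frame indices, inclusive of both ends."""

    label: str
    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if self.end_frame < self.start_frame:
            raise ValueError(f"window {self.label!r}: end < start")

    def contains(self, frame: int) -> bool:
        return self.start_frame <= frame <= self.end_frame


@dataclass(frozen=True)
class BehaviourIndexSeries:
    """Per-window behaviour indices: mean animals per recorded frame."""

    window: Window
    indices: Mapping[BehaviourClass, float]
    n_frames: int


@dataclass(frozen=True)
class BaselineSpec:
    """Which windows form the baseline for percent-change comparison.

    ``pre_days`` uses only windows preceding the comparison period;
    ``pre_and_post_mean`` averages control windows on both sides.
    """

    baseline_labels: tuple[str, ...]
    comparison_labels: tuple[str, ...]
    mode: str = "pre_days"

    def __post_init__(self) -> None:
        if self.mode not in ("pre_days", "pre_and_post_mean"):
            raise ValueError(f"unknown baseline mode {self.mode!r}")
        if set(self.baseline_labels) & set(self.comparison_labels):
            raise ValueError("baseline and comparison windows must be disjoint")


def behaviour_index(per_frame_counts: Sequence[int]) -> float:
    """Mean count per recorded frame; undefined (error) on zero frames."""
    n = len(per_frame_counts)
    if n == 0:
        raise ValueError("behaviour index is undefined over zero recorded frames")
    return sum(per_frame_counts) / n


def index_series(
    records: Iterable[Detection | Annotation],
    windows: Sequence[Window],
    recorded_frames: Sequence[int] | None = None,
) -> list[BehaviourIndexSeries]:
    """Behaviour indices per window, counted frame-wise from detections.

    No tracking is needed at group level.  ``recorded_frames`` lists the
    frames the recorder actually kept (so empty frames still count toward
    ``N``); if omitted, frames carrying at least one record are used.
    Windows with zero recorded frames are omitted from the output.
    """
    for i, w in enumerate(windows):
        for other in windows[i + 1:]:
            if w.start_frame <= other.end_frame and other.start_frame <= w.end_frame:
                raise ValueError(f"windows {w.label!r} and {other.label!r} overlap")
    by_frame = group_by_frame(records)
    frames = sorted(recorded_frames) if recorded_frames is not None else sorted(by_frame)
    out: list[BehaviourIndexSeries] = []
    for w in windows:
        in_window = [f for f in frames if w.contains(f)]
        if not in_window:
            continue
        counts = {b: 0 for b in BehaviourClass}
        for f in in_window:
            for r in by_frame.get(f, []):
                counts[r.cls] += 1
        n = len(in_window)
        out.append(BehaviourIndexSeries(
            window=w,
            indices={b: counts[b] / n for b in BehaviourClass},
            n_frames=n,
        ))
    return out


def percent_change(index: float, baseline: float) -> float:
    """Signed percent change of ``index`` relative to ``baseline``."""
    if baseline == 0:
        raise ValueError("percent change is undefined for a zero baseline")
    return 100.0 * (index - baseline) / baseline


@dataclass(frozen=True)
class IndividualProfile:
    """Per-animal trajectory, time budget and locomotion summary."""

    vid: int
    samples: tuple[tuple[float, Point, BehaviourClass], ...]  # (time s, centroid, behaviour)
    time_budget: Mapping[BehaviourClass, float]
    total_distance: float       # pixels, or metres when a scale was applied
    mean_speed: float | None    # per second; None when elapsed time is zero
    unit: str = "px"


def build_profile(
    track: Track,
    timestamps: FrameSequence | Mapping[int, float],
    scale: float | None = None,
    include_coasted_in_budget: bool = False,
) -> IndividualProfile:
    """Profile a single track: trajectory, time budget, distance and speed.

    ``scale`` converts pixels to metres when the pen calibration is known.
    Coasted samples contribute to the trajectory (continuity) but not to the
    time budget unless requested.
    """
    if not track.history:
        raise ValueError(f"track vid={track.vid} has an empty history")
    stamps = timestamps.as_dict() if isinstance(timestamps, FrameSequence) else dict(timestamps)
    s = 1.0 if scale is None else scale
    samples: list[tuple[float, Point, BehaviourClass]] = []
    budget_counts: dict[BehaviourClass, int] = {b: 0 for b in BehaviourClass}
    n_budget = 0
    for sample in track.history:
        t = stamps[sample.frame]
        c = centroid(sample.box)
        samples.append((t, Point(c.cx * s, c.cy * s), sample.cls))
        if sample.source == "detected" or include_coasted_in_budget:
            budget_counts[sample.cls] += 1
            n_budget += 1
    if n_budget == 0:
        raise ValueError(f"track vid={track.vid} has no detected samples to budget")
    budget = {b: budget_counts[b] / n_budget for b in BehaviourClass}
    dist = _path_length(samples)
    elapsed = samples[-1][0] - samples[0][0]
    speed = dist / elapsed if elapsed > 0 else None
    return IndividualProfile(
        vid=track.vid,
        samples=tuple(samples),
        time_budget=budget,
        total_distance=dist,
        mean_speed=speed,
        unit="px" if scale is None else "m",
    )


def _path_length(samples: Sequence[tuple[float, Point, BehaviourClass]]) -> float:
    return sum(
        samples[i][1].distance_to(samples[i + 1][1]) for i in range(len(samples) - 1)
    )


def total_distance(profile: IndividualProfile) -> float:
    """Sum of Euclidean centroid displacements between consecutive samples."""
    return profile.total_distance


def mean_speed(profile: IndividualProfile) -> float:
    """Total distance over elapsed wall-clock time (dropped frames do not inflate it)."""
    if profile.mean_speed is None:
        raise ValueError("mean speed is undefined over zero elapsed time")
    return profile.mean_speed
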