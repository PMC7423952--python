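"""Wire format for per-frame detections and ground-truth annotations.

CSV is the primary format (header
``frame,x,y,width,height,class,score[,track_id]``), with a JSON-lines
alternative carrying the same field names.  Parsing is strict: unknown
behaviour classes, out-of-range scores and malformed rows are rejected with
the offending line number.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .geometry import BoundingBox

__all__ = [
    "BehaviourClass",
    "BEHAVIOURS",
    "POSTURE_BEHAVIOURS",
    "Detection",
    "Annotation",
    "FrameSequence",
    "ParseError",
    "read_detections",
    "write_detections",
    "read_annotations",
    "write_annotations",
    "read_frame_sequence",
    "write_frame_sequence",
    "group_by_frame",
    "identity_detector",
]


class BehaviourClass(str, Enum):
    """The closed five-behaviour vocabulary; mutually exclusive per animal per frame."""

    STANDING = "standing"
    SITTING = "sitting"
    LATERAL_LYING = "lateral_lying"
    STERNAL_LYING = "sternal_lying"
    DRINKING = "drinking"


BEHAVIOURS: tuple[BehaviourClass, ...] = tuple(BehaviourClass)
#: vocabulary subset for scenarios where drinkers sit outside the field of view
POSTURE_BEHAVIOURS: tuple[BehaviourClass, ...] = tuple(
    b for b in BehaviourClass if b is not BehaviourClass.DRINKING
)


class ParseError(ValueError):
    """Malformed row in a detections/annotations file; carries the line number."""

    def __init__(self, path: str | Path, line: int, message: str):
        super().__init__(f"{path}:{line}: {message}")
        self.path = str(path)
        self.line = line


@dataclass(frozen=True)
class Detection:
    """One detector output: frame index, box, behaviour class and confidence."""

    frame: int
    box: BoundingBox
    cls: BehaviourClass
    score: float

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValueError(f"frame index must be >= 0, got {self.frame}")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must be in [0, 1], got {self.score}")


@dataclass(frozen=True)
class Annotation:
    """Ground-truth record; ``gt_id`` is the stable animal identity when known."""

    frame: int
    box: BoundingBox
    cls: BehaviourClass
    gt_id: int | None = None

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise ValueError(f"frame index must be >= 0, got {self.frame}")


@dataclass(frozen=True)
class FrameSequence:
    """Recorded frame indices (gaps allowed) with wall-clock timestamps.

    Dropped frames simply do not appear; surviving timestamps keep their true
    spacing so speeds computed downstream are not inflated.
    """

    frames: tuple[int, ...]
    timestamps: tuple[float, ...]
    fps: float = 25.0

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.timestamps):
            raise ValueError("frames and timestamps must have equal length")
        if any(b <= a for a, b in zip(self.frames, self.frames[1:])):
            raise ValueError("frame indices must be strictly increasing")
        if any(b < a for a, b in zip(self.timestamps, self.timestamps[1:])):
            raise ValueError("timestamps must be non-decreasing")

    def timestamp_of(self, frame: int) -> float:
        i = self.frames.index(frame)
        return self.timestamps[i]

    def as_dict(self) -> dict[int, float]:
        return dict(zip(self.frames, self.timestamps))


#: contract for pluggable detectors: recorded frames in, detections per frame out
DetectorContract = Callable[[FrameSequence], dict[int, list[Detection]]]

_DET_FIELDS = ["frame", "x", "y", "width", "height", "class", "score"]
_ANN_FIELDS = ["frame", "x", "y", "width", "height", "class", "gt_id"]
SCHEMA_VERSION = "penwatch-v1"


def _parse_class(raw: str, path: str | Path, line: int) -> BehaviourClass:
    try:
        return BehaviourClass(raw)
    except ValueError:
        valid = ", ".join(b.value for b in BehaviourClass)
        raise ParseError(path, line, f"unknown behaviour class {raw!r} (expected one of: {valid})")


def _parse_float(raw: str, name: str, path: str | Path, line: int) -> float:
    try:
        v = float(raw)
    except ValueError:
        raise ParseError(path, line, f"field {name!r} is not a number: {raw!r}")
    if not math.isfinite(v):
        raise ParseError(path, line, f"field {name!r} must be finite, got {raw!r}")
    return v


def _parse_int(raw: str, name: str, path: str | Path, line: int) -> int:
    try:
        return int(raw)
    except ValueError:
        raise ParseError(path, line, f"field {name!r} is not an integer: {raw!r}")


def _open_rows(path: str | Path) -> tuple[list[dict[str, str]], list[int]]:
    """Rows from CSV or JSON-lines, with their 1-based line numbers."""
    path = Path(path)
    text = path.read_text()
    rows: list[dict[str, str]] = []
    lines: list[int] = []
    if path.suffix in {".jsonl", ".ndjson"}:
        for i, raw in enumerate(text.splitlines(), start=1):
            if not raw.strip() or raw.startswith("#"):
                continue
            try:
                obj = json.loads(raw)
            except json.JSONDecodeError as e:
                raise ParseError(path, i, f"invalid JSON: {e}")
            rows.append({k: str(v) for k, v in obj.items()})
            lines.append(i)
    else:
        content = [ln for ln in text.splitlines() if not ln.startswith("#")]
        n_comment_header = len(text.splitlines()) - len(content)
        reader = csv.DictReader(content)
        for i, row in enumerate(reader, start=2 + n_comment_header):
            if None in row or any(v is None for v in row.values()):
                raise ParseError(path, i, "wrong number of fields")
            rows.append(row)
            lines.append(i)
    return rows, lines


def read_detections(path: str | Path) -> list[Detection]:
    """Read and validate detections, returned sorted by frame (stable)."""
    rows, lines = _open_rows(path)
    out: list[Detection] = []
    for row, ln in zip(rows, lines):
        missing = [f for f in _DET_FIELDS if f not in row]
        if missing:
            raise ParseError(path, ln, f"missing fields: {missing}")
        frame = _parse_int(row["frame"], "frame", path, ln)
        box = _parse_box(row, path, ln)
        cls = _parse_class(row["class"], path, ln)
        score = _parse_float(row["score"], "score", path, ln)
        try:
            out.append(Detection(frame=frame, box=box, cls=cls, score=score))
        except ValueError as e:
            raise ParseError(path, ln, str(e))
    out.sort(key=lambda d: d.frame)
    return out


def _parse_box(row: dict[str, str], path: str | Path, ln: int) -> BoundingBox:
    vals = {f: _parse_float(row[f], f, path, ln) for f in ("x", "y", "width", "height")}
    try:
        return BoundingBox(**vals)
    except ValueError as e:
        raise ParseError(path, ln, str(e))


def write_detections(path: str | Path, detections: Iterable[Detection]) -> None:
    path = Path(path)
    if path.suffix in {".jsonl", ".ndjson"}:
        with path.open("w", newline="") as fh:
            for d in detections:
                fh.write(json.dumps({
                    "frame": d.frame, "x": d.box.x, "y": d.box.y,
                    "width": d.box.width, "height": d.box.height,
                    "class": d.cls.value, "score": d.score,
                }) + "\n")
        return
    with path.open("w", newline="") as fh:
        fh.write(f"# schema: {SCHEMA_VERSION} detections\n")
        w = csv.writer(fh)
        w.writerow(_DET_FIELDS)
        for d in detections:
            w.writerow([d.frame, repr(d.box.x), repr(d.box.y), repr(d.box.width),
                        repr(d.box.height), d.cls.value, repr(d.score)])


def read_annotations(path: str | Path) -> list[Annotation]:
    """Read and validate ground-truth annotations, sorted by frame."""
    rows, lines = _open_rows(path)
    out: list[Annotation] = []
    for row, ln in zip(rows, lines):
        missing = [f for f in _ANN_FIELDS[:-1] if f not in row]
        if missing:
            raise ParseError(path, ln, f"missing fields: {missing}")
        frame = _parse_int(row["frame"], "frame", path, ln)
        box = _parse_box(row, path, ln)
        cls = _parse_class(row["class"], path, ln)
        raw_id = row.get("gt_id", "")
        gt_id = None if raw_id in ("", "None", None) else _parse_int(raw_id, "gt_id", path, ln)
        try:
            out.append(Annotation(frame=frame, box=box, cls=cls, gt_id=gt_id))
        except ValueError as e:
            raise ParseError(path, ln, str(e))
    out.sort(key=lambda a: a.frame)
    return out


def write_annotations(path: str | Path, annotations: Iterable[Annotation]) -> None:
    path = Path(path)
    if path.suffix in {".jsonl", ".ndjson"}:
        with path.open("w", newline="") as fh:
            for a in annotations:
                fh.write(json.dumps({
                    "frame": a.frame, "x": a.box.x, "y": a.box.y,
                    "width": a.box.width, "height": a.box.height,
                    "class": a.cls.value, "gt_id": a.gt_id,
                }) + "\n")
        return
    with path.open("w", newline="") as fh:
        fh.write(f"# schema: {SCHEMA_VERSION} annotations\n")
        w = csv.writer(fh)
        w.writerow(_ANN_FIELDS)
        for a in annotations:
            w.writerow([a.frame, repr(a.box.x), repr(a.box.y), repr(a.box.width),
                        repr(a.box.height), a.cls.value,
                        "" if a.gt_id is None else a.gt_id])


def read_frame_sequence(path: str | Path) -> FrameSequence:
    rows, lines = _open_rows(path)
    frames: list[int] = []
    stamps: list[float] = []
    fps = 25.0
    for row, ln in zip(rows, lines):
        frames.append(_parse_int(row["frame"], "frame", path, ln))
        stamps.append(_parse_float(row["timestamp"], "timestamp", path, ln))
        if "fps" in row and row["fps"]:
            fps = _parse_float(row["fps"], "fps", path, ln)
    return FrameSequence(frames=tuple(frames), timestamps=tuple(stamps), fps=fps)


def write_frame_sequence(path: str | Path, seq: FrameSequence) -> None:
    with Path(path).open("w", newline="") as fh:
        fh.write(f"# schema: {SCHEMA_VERSION} frames\n")
        w = csv.writer(fh)
        w.writerow(["frame", "timestamp", "fps"])
        for f, t in zip(seq.frames, seq.timestamps):
            w.writerow([f, repr(t), repr(seq.fps)])


def group_by_frame(records: Iterable[Detection | Annotation]) -> dict[int, list]:
    """Frame index -> records, preserving input order within a frame."""
    out: dict[int, list] = {}
    for r in records:
        out.setdefault(r.frame, []).append(r)
    return dict(sorted(out.items()))


def identity_detector(annotations: Sequence[Annotation]) -> DetectorContract:
    """Reference detector: echoes the ground truth with score 1.0.

    Satisfies the detector contract; frames with no annotations yield an
    empty list rather than failing.
    """
    by_frame = group_by_frame(annotations)

    def detect(frames: FrameSequence) -> dict[int, list[Detection]]:
        return {
            f: [Detection(frame=f, box=a.box, cls=a.cls, score=1.0)
                for a in by_frame.get(f, [])]
            for f in frames.frames
        }

    return detect
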