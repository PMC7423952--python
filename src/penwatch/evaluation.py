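"""Detection and tracking evaluation: AP/mAP, log-average miss rate, MOTA/MOTP.

Detection matching is per frame and per class: detections sorted by
descending score are greedily matched to the unmatched ground truth of
highest IoU above the threshold; the remainder are false positives /
negatives.  AP is the area under the all-points-interpolated
precision-recall curve.  The miss-rate characteristic samples
``1 - recall`` at 9 log-spaced false-positives-per-image reference points.

Tracking metrics follow the CLEAR-MOT convention: per frame, ground truths
and predictions are matched by Hungarian assignment maximising total IoU
(with persistence — a prior pairing is kept while it still clears the
threshold); identity switches are counted when a ground truth's matched
predicted identity changes.  MOTA = 1 - (FN + FP + IDSW)/GT; MOTP here is
the mean IoU of matched pairs (higher is better), with ``1 - IoU`` exposed
as an alternative distance convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .detections import Annotation, BehaviourClass, Detection, group_by_frame
from .geometry import BoundingBox, iou

__all__ = [
    "MatchingResult",
    "PRCurve",
    "MissRateCurve",
    "MOTReport",
    "match_frame",
    "average_precision",
    "mean_average_precision",
    "log_average_miss_rate",
    "mota",
    "motp",
    "evaluate_tracking",
    "locomotion_mse",
]


@dataclass
class MatchingResult:
    """Per-frame TP/FP/FN counts plus records for curve construction."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    matched_ious: list[float] = field(default_factory=list)
    #: (score, is_tp) per detection — input to PR / miss-rate curves
    detection_records: list[tuple[float, bool]] = field(default_factory=list)


@dataclass(frozen=True)
class PRCurve:
    recalls: tuple[float, ...]
    precisions: tuple[float, ...]
    ap: float


@dataclass(frozen=True)
class MissRateCurve:
    fppi: tuple[float, ...]
    miss_rates: tuple[float, ...]
    lamr: float


@dataclass(frozen=True)
class MOTReport:
    mota: float
    motp: float
    fn: int
    fp: int
    idsw: int
    gt_total: int
    tp: int

    @property
    def true_positive_rate(self) -> float:
        return self.tp / self.gt_total if self.gt_total else float("nan")


def match_frame(
    detections: Sequence[Detection],
    ground_truths: Sequence[Annotation],
    iou_min: float = 0.5,
) -> MatchingResult:
    """Greedy score-ordered matching within one frame (single class assumed)."""
    res = MatchingResult()
    order = sorted(range(len(detections)), key=lambda i: -detections[i].score)
    taken = [False] * len(ground_truths)
    for i in order:
        d = detections[i]
        best_j, best_iou = -1, iou_min
        for j, g in enumerate(ground_truths):
            if taken[j]:
                continue
            ov = iou(d.box, g.box)
            if ov >= best_iou and ov > 0:
                best_j, best_iou = j, ov
        if best_j >= 0:
            taken[best_j] = True
            res.tp += 1
            res.matched_ious.append(best_iou)
            res.detection_records.append((d.score, True))
        else:
            res.fp += 1
            res.detection_records.append((d.score, False))
    res.fn = taken.count(False)
    return res


def _class_records(
    detections: Sequence[Detection],
    ground_truths: Sequence[Annotation],
    cls: BehaviourClass,
    iou_min: float,
) -> tuple[list[tuple[float, bool]], int, int]:
    """Score-labelled detection records for one class across all frames."""
    dets = [d for d in detections if d.cls == cls]
    gts = [g for g in ground_truths if g.cls == cls]
    n_gt = len(gts)
    d_by_frame = group_by_frame(dets)
    g_by_frame = group_by_frame(gts)
    frames = set(d_by_frame) | set(g_by_frame)
    records: list[tuple[float, bool]] = []
    for f in sorted(frames):
        r = match_frame(d_by_frame.get(f, []), g_by_frame.get(f, []), iou_min)
        records.extend(r.detection_records)
    n_frames = len({g.frame for g in ground_truths} | {d.frame for d in detections})
    return records, n_gt, n_frames


def average_precision(
    detections: Sequence[Detection],
    ground_truths: Sequence[Annotation],
    cls: BehaviourClass,
    iou_min: float = 0.5,
) -> PRCurve:
    """All-points AP for one class; error when the class has no ground truth."""
    records, n_gt, _ = _class_records(detections, ground_truths, cls, iou_min)
    if n_gt == 0:
        raise ValueError(f"AP undefined: no ground truths of class {cls.value!r}")
    records.sort(key=lambda r: -r[0])
    tp_cum = 0
    recalls: list[float] = []
    precisions: list[float] = []
    for i, (_, is_tp) in enumerate(records, start=1):
        tp_cum += int(is_tp)
        recalls.append(tp_cum / n_gt)
        precisions.append(tp_cum / i)
    # all-points interpolation: integrate the precision envelope over recall
    ap = 0.0
    prev_r = 0.0
    env = precisions.copy()
    for i in range(len(env) - 2, -1, -1):
        env[i] = max(env[i], env[i + 1])
    for r, p in zip(recalls, env):
        ap += (r - prev_r) * p
        prev_r = r
    return PRCurve(recalls=tuple(recalls), precisions=tuple(precisions), ap=ap)


def mean_average_precision(
    detections: Sequence[Detection],
    ground_truths: Sequence[Annotation],
    iou_min: float = 0.5,
    classes: Sequence[BehaviourClass] | None = None,
) -> tuple[float, dict[BehaviourClass, float]]:
    """Mean AP across classes with ground truth; empty classes are skipped."""
    classes = tuple(classes) if classes is not None else tuple(BehaviourClass)
    per_class: dict[BehaviourClass, float] = {}
    for cls in classes:
        try:
            per_class[cls] = average_precision(detections, ground_truths, cls, iou_min).ap
        except ValueError:
            continue
    if not per_class:
        raise ValueError("mAP undefined: no class has ground truths")
    return float(np.mean(list(per_class.values()))), per_class


def log_average_miss_rate(
    detections: Sequence[Detection],
    ground_truths: Sequence[Annotation],
    cls: BehaviourClass,
    iou_min: float = 0.5,
    fppi_range: tuple[float, float] = (1e-2, 1.0),
    n_points: int = 9,
    floor: float = 1e-10,
) -> MissRateCurve:
    """Log-average miss rate over log-spaced FPPI reference points.

    At each reference FPPI the lowest achievable miss rate at or below that
    FPPI is taken (1.0 if unreachable); the LAMR is the geometric mean of
    the miss rates clipped below at ``floor``.
    """
    records, n_gt, n_frames = _class_records(detections, ground_truths, cls, iou_min)
    if n_gt == 0:
        raise ValueError(f"LAMR undefined: no ground truths of class {cls.value!r}")
    records.sort(key=lambda r: -r[0])
    fppi_pts: list[float] = [0.0]
    miss_pts: list[float] = [1.0]  # threshold above every score: nothing detected
    tp_cum = fp_cum = 0
    for _, is_tp in records:
        tp_cum += int(is_tp)
        fp_cum += int(not is_tp)
        fppi_pts.append(fp_cum / max(n_frames, 1))
        miss_pts.append(1.0 - tp_cum / n_gt)
    refs = np.logspace(np.log10(fppi_range[0]), np.log10(fppi_range[1]), n_points)
    sampled: list[float] = []
    for ref in refs:
        feasible = [m for f, m in zip(fppi_pts, miss_pts) if f <= ref]
        sampled.append(min(feasible) if feasible else 1.0)
    lamr = float(np.exp(np.mean(np.log(np.clip(sampled, floor, None)))))
    return MissRateCurve(fppi=tuple(fppi_pts), miss_rates=tuple(miss_pts), lamr=lamr)


TrackRecord = tuple[int, Detection]  # (identity, per-frame record)


def _frames_of(records: Sequence[TrackRecord]) -> dict[int, list[tuple[int, BoundingBox]]]:
    out: dict[int, list[tuple[int, BoundingBox]]] = {}
    for ident, det in records:
        out.setdefault(det.frame, []).append((ident, det.box))
    return out


def evaluate_tracking(
    gt_records: Sequence[TrackRecord],
    pred_records: Sequence[TrackRecord],
    iou_min: float = 0.5,
    motp_distance: bool = False,
) -> MOTReport:
    """CLEAR-MOT accounting over identity-carrying track records.

    ``motp_distance=True`` reports MOTP as mean ``1 - IoU`` (a distance)
    instead of mean IoU.
    """
    gt_by_frame = _frames_of(gt_records)
    pr_by_frame = _frames_of(pred_records)
    gt_total = sum(len(v) for v in gt_by_frame.values())
    if gt_total == 0:
        raise ValueError("MOTA undefined: no ground-truth records")
    fn = fp = idsw = tp = 0
    iou_sum = 0.0
    last_match: dict[int, int] = {}  # gt identity -> predicted identity
    prev_pairs: dict[int, int] = {}
    for frame in sorted(set(gt_by_frame) | set(pr_by_frame)):
        gts = gt_by_frame.get(frame, [])
        prs = pr_by_frame.get(frame, [])
        pairs: dict[int, int] = {}
        used_gt: set[int] = set()
        used_pr: set[int] = set()
        # persistence: keep last frame's pairing while it still clears the gate
        pr_index = {ident: i for i, (ident, _) in enumerate(prs)}
        gt_index = {ident: i for i, (ident, _) in enumerate(gts)}
        for g_ident, p_ident in prev_pairs.items():
            gi = gt_index.get(g_ident)
            pi = pr_index.get(p_ident)
            if gi is None or pi is None:
                continue
            ov = iou(gts[gi][1], prs[pi][1])
            if ov >= iou_min and ov > 0:
                pairs[g_ident] = p_ident
                used_gt.add(gi)
                used_pr.add(pi)
                tp += 1
                iou_sum += ov
        # Hungarian on the remainder, maximising total IoU
        free_gt = [i for i in range(len(gts)) if i not in used_gt]
        free_pr = [i for i in range(len(prs)) if i not in used_pr]
        if free_gt and free_pr:
            mat = np.zeros((len(free_gt), len(free_pr)))
            for a, gi in enumerate(free_gt):
                for b, pi in enumerate(free_pr):
                    ov = iou(gts[gi][1], prs[pi][1])
                    mat[a, b] = ov if (ov >= iou_min and ov > 0) else -1.0
            rows, cols = linear_sum_assignment(-mat)
            for a, b in zip(rows, cols):
                if mat[a, b] < 0:
                    continue
                gi, pi = free_gt[a], free_pr[b]
                pairs[gts[gi][0]] = prs[pi][0]
                used_gt.add(gi)
                used_pr.add(pi)
                tp += 1
                iou_sum += mat[a, b]
        fn += len(gts) - len(used_gt)
        fp += len(prs) - len(used_pr)
        for g_ident, p_ident in pairs.items():
            if g_ident in last_match and last_match[g_ident] != p_ident:
                idsw += 1
            last_match[g_ident] = p_ident
        prev_pairs = pairs
    mota_score = 1.0 - (fn + fp + idsw) / gt_total
    if tp == 0:
        raise ValueError("MOTP undefined: no true-positive matches")
    motp_score = iou_sum / tp
    if motp_distance:
        motp_score = 1.0 - motp_score
    return MOTReport(mota=mota_score, motp=motp_score, fn=fn, fp=fp,
                     idsw=idsw, gt_total=gt_total, tp=tp)


def mota(gt_records: Sequence[TrackRecord], pred_records: Sequence[TrackRecord],
         iou_min: float = 0.5) -> float:
    return evaluate_tracking(gt_records, pred_records, iou_min).mota


def motp(matched_ious: Sequence[float], distance: bool = False) -> float:
    """Mean localisation overlap of true-positive matches."""
    if not matched_ious:
        raise ValueError("MOTP undefined: no matched pairs")
    m = float(np.mean(matched_ious))
    return 1.0 - m if distance else m


def locomotion_mse(true_values: Sequence[float], estimated_values: Sequence[float]) -> float:
    """Mean squared error of paired per-animal locomotion summaries."""
    if len(true_values) != len(estimated_values):
        raise ValueError("locomotion MSE needs paired per-animal values")
    if len(true_values) == 0:
        raise ValueError("locomotion MSE undefined on empty input")
    t = np.asarray(true_values, dtype=float)
    e = np.asarray(estimated_values, dtype=float)
    return float(np.mean((t - e) ** 2))
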