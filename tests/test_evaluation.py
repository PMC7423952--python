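import itertools

import numpy as np
import pytest

from penwatch.detections import Annotation, BehaviourClass, Detection
from penwatch.evaluation import (
    average_precision,
    evaluate_tracking,
    locomotion_mse,
    log_average_miss_rate,
    match_frame,
    mean_average_precision,
    mota,
    motp,
)
from penwatch.geometry import BoundingBox, iou

S = BehaviourClass.STANDING


def det(frame, x, y, w=10.0, h=10.0, score=1.0, cls=S):
    return Detection(frame=frame, box=BoundingBox(x, y, w, h), cls=cls, score=score)


def ann(frame, x, y, w=10.0, h=10.0, cls=S, gt_id=None):
    return Annotation(frame=frame, box=BoundingBox(x, y, w, h), cls=cls, gt_id=gt_id)


class TestMatchFrame:
    def test_perfect(self):
        gts = [ann(0, 0, 0), ann(0, 50, 50)]
        dets = [det(0, 0, 0), det(0, 50, 50)]
        r = match_frame(dets, gts)
        assert (r.tp, r.fp, r.fn) == (2, 0, 0)

    def test_empty_detections(self):
        r = match_frame([], [ann(0, 0, 0)] * 3)
        assert (r.tp, r.fp, r.fn) == (0, 0, 3)

    def test_one_detection_two_gts_takes_higher_iou(self):
        # detection overlaps gt A with IoU 1.0 and gt B weakly; B becomes FN
        gt_a = ann(0, 0, 0)
        gt_b = ann(0, 6, 0)
        d = det(0, 0, 0)
        r = match_frame([d], [gt_a, gt_b])
        assert (r.tp, r.fn) == (1, 1)
        assert r.matched_ious == [1.0]
        # verified against exhaustive optimal matching on this 3-box case
        best = max(iou(d.box, gt_a.box), iou(d.box, gt_b.box))
        assert r.matched_ious[0] == best

    def test_tp_plus_fn_equals_gt(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            gts = [ann(0, float(rng.integers(0, 80)), float(rng.integers(0, 80)))
                   for _ in range(int(rng.integers(0, 5)))]
            dets = [det(0, float(rng.integers(0, 80)), float(rng.integers(0, 80)),
                        score=float(rng.uniform()))
                    for _ in range(int(rng.integers(0, 5)))]
            r = match_frame(dets, gts)
            assert r.tp + r.fn == len(gts)
            assert r.tp + r.fp == len(dets)


class TestAveragePrecision:
    def test_all_tp(self):
        gts = [ann(f, 0, 0) for f in range(5)]
        dets = [det(f, 0, 0, score=0.9) for f in range(5)]
        assert average_precision(dets, gts, S).ap == pytest.approx(1.0)

    def test_hand_built_half(self):
        # 1 GT; FP at score 0.9, TP at 0.8 -> precision at recall 1 is 1/2
        gts = [ann(0, 0, 0)]
        dets = [det(0, 200, 200, score=0.9), det(0, 0, 0, score=0.8)]
        curve = average_precision(dets, gts, S)
        assert curve.ap == pytest.approx(0.5)
        assert curve.recalls[-1] == 1.0

    def test_monotone_rescaling_invariance(self):
        gts = [ann(f, 0, 0) for f in range(4)]
        dets = [det(0, 0, 0, score=0.9), det(1, 200, 0, score=0.6),
                det(2, 0, 0, score=0.5), det(3, 0, 0, score=0.2)]
        ap1 = average_precision(dets, gts, S).ap
        rescaled = [Detection(frame=d.frame, box=d.box, cls=d.cls, score=d.score ** 3)
                    for d in dets]
        assert average_precision(rescaled, gts, S).ap == pytest.approx(ap1)

    def test_no_gt_of_class_errors(self):
        with pytest.raises(ValueError):
            average_precision([det(0, 0, 0)], [ann(0, 0, 0, cls=BehaviourClass.SITTING)], S)

    def test_dense_sampling_oracle_small_fixtures(self):
        # fixtures constructed so TP/FP flags are known a priori (each hit
        # exactly overlaps its own isolated GT, at most one hit per GT);
        # the oracle integrates interpolated precision over a dense recall grid
        rng = np.random.default_rng(7)
        for _ in range(20):
            n_gt = int(rng.integers(1, 6))
            gts = [ann(f, 0, 0) for f in range(n_gt)]
            labelled: list[tuple[float, bool]] = []
            dets = []
            unhit = list(range(n_gt))
            for _i in range(int(rng.integers(1, 20))):
                score = float(rng.uniform())
                if unhit and rng.random() < 0.5:
                    f = unhit.pop()
                    dets.append(det(f, 0, 0, score=score))
                    labelled.append((score, True))
                else:
                    dets.append(det(int(rng.integers(0, n_gt)), 500, 0, score=score))
                    labelled.append((score, False))
            curve = average_precision(dets, gts, S)
            # oracle path: known flags -> PR sequence -> dense numeric integration
            labelled.sort(key=lambda r: -r[0])
            tp = 0
            pts = []
            for i, (_, is_tp) in enumerate(labelled, start=1):
                tp += int(is_tp)
                pts.append((tp / n_gt, tp / i))
            grid = np.linspace(1e-9, 1.0, 200_001)
            interp = np.zeros_like(grid)
            for r, p in pts:
                interp = np.where((grid <= r) & (p > interp), p, interp)
            ap_oracle = float(np.mean(interp))
            assert curve.ap == pytest.approx(ap_oracle, abs=2e-3)


class TestMeanAveragePrecision:
    def test_all_ones(self):
        gts = [ann(0, 0, 0, cls=c) for c in BehaviourClass]
        dets = [det(0, a.box.x, a.box.y, cls=a.cls, score=0.9) for a in gts]
        m, per = mean_average_precision(dets, gts)
        assert m == pytest.approx(1.0)
        assert len(per) == 5

    def test_simple_mean(self):
        gts = [ann(0, 0, 0, cls=S), ann(0, 50, 50, cls=BehaviourClass.SITTING)]
        # standing: perfect; sitting: 1 FP ranked above the TP -> AP 0.5
        dets = [det(0, 0, 0, cls=S, score=0.9),
                det(0, 200, 200, cls=BehaviourClass.SITTING, score=0.9),
                det(0, 50, 50, cls=BehaviourClass.SITTING, score=0.8)]
        m, per = mean_average_precision(dets, gts)
        assert per[S] == pytest.approx(1.0)
        assert per[BehaviourClass.SITTING] == pytest.approx(0.5)
        assert m == pytest.approx(0.75)

    def test_empty_classes_excluded(self):
        gts = [ann(0, 0, 0, cls=S)]
        dets = [det(0, 0, 0, cls=S, score=0.9)]
        m, per = mean_average_precision(dets, gts)
        assert set(per) == {S}
        assert m == 1.0


class TestLogAverageMissRate:
    def test_perfect_detector_floor(self):
        gts = [ann(f, 0, 0) for f in range(10)]
        dets = [det(f, 0, 0, score=0.9) for f in range(10)]
        curve = log_average_miss_rate(dets, gts, S)
        assert curve.lamr == pytest.approx(1e-10)

    def test_blind_detector(self):
        gts = [ann(f, 0, 0) for f in range(10)]
        curve = log_average_miss_rate([], gts, S)
        assert curve.lamr == pytest.approx(1.0)

    def test_manual_fixture(self):
        # 10 frames, 10 GT; detections: 5 TPs at high scores, 2 FPs interleaved.
        gts = [ann(f, 0, 0) for f in range(10)]
        dets = [
            det(0, 0, 0, score=0.95), det(1, 0, 0, score=0.90),
            det(0, 500, 0, score=0.85),                       # FP
            det(2, 0, 0, score=0.80), det(3, 0, 0, score=0.75),
            det(1, 500, 0, score=0.70),                       # FP
            det(4, 0, 0, score=0.65),
        ]
        curve = log_average_miss_rate(dets, gts, S)
        # manual sweep: curve points (fppi, miss):
        # (0,1) (0,.9) (0,.8) (.1,.8) (.1,.7) (.1,.6) (.2,.6) (.2,.5)
        refs = np.logspace(-2, 0, 9)
        expected_samples = []
        pts = [(0.0, 1.0), (0.0, 0.9), (0.0, 0.8), (0.1, 0.8), (0.1, 0.7),
               (0.1, 0.6), (0.2, 0.6), (0.2, 0.5)]
        for ref in refs:
            feas = [m for f, m in pts if f <= ref]
            expected_samples.append(min(feas) if feas else 1.0)
        expected = float(np.exp(np.mean(np.log(expected_samples))))
        assert curve.lamr == pytest.approx(expected, abs=1e-12)


class TestMOT:
    def track_records(self, per_frame):
        """per_frame: {frame: [(ident, x, y), ...]} -> record list."""
        out = []
        for f, items in per_frame.items():
            for ident, x, y in items:
                out.append((ident, det(f, x, y)))
        return out

    def test_identical_tracks(self):
        gt = self.track_records({f: [(1, 0, 0), (2, 50, 50)] for f in range(10)})
        rep = evaluate_tracking(gt, gt)
        assert rep.mota == 1.0
        assert rep.motp == 1.0
        assert rep.idsw == 0

    def test_constructed_096(self):
        # 10 GT/frame x 10 frames = 100 GT; inject 2 FN + 1 FP + 1 IDSW
        gt, pred = [], []
        for f in range(10):
            for i in range(10):
                gt.append((i, det(f, 60.0 * i, 0)))
                if f == 3 and i in (0, 1):
                    continue  # 2 FN
                pid = i
                if f >= 5 and i == 2:
                    pid = 99  # identity change -> 1 IDSW at f=5
                pred.append((pid, det(f, 60.0 * i, 0)))
        pred.append((77, det(7, 0, 300)))  # 1 FP
        rep = evaluate_tracking(gt, pred)
        assert (rep.fn, rep.fp, rep.idsw) == (2, 1, 1)
        assert rep.mota == pytest.approx(0.96)

    def test_swap_counts_two_switches(self):
        gt, pred = [], []
        for f in range(10):
            gt.append((1, det(f, 0, 0)))
            gt.append((2, det(f, 200, 0)))
            a, b = (10, 20) if f < 5 else (20, 10)
            pred.append((a, det(f, 0, 0)))
            pred.append((b, det(f, 200, 0)))
        rep = evaluate_tracking(gt, pred)
        assert rep.idsw == 2

    def test_match_persistence_prevents_spurious_switch(self):
        # two preds nearly coincide with one GT; persistence keeps the original
        gt, pred = [], []
        for f in range(6):
            gt.append((1, det(f, 0, 0)))
            pred.append((10, det(f, 0, 0)))
            if f >= 2:
                pred.append((20, det(f, 1, 0)))  # interloper with high IoU
        rep = evaluate_tracking(gt, pred)
        assert rep.idsw == 0

    def test_hungarian_at_least_greedy(self):
        # optimality: per-frame matching count equals brute-force max-matching
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = int(rng.integers(1, 6))
            gt = [(i, det(0, float(rng.integers(0, 40)), float(rng.integers(0, 40))))
                  for i in range(n)]
            pred = [(100 + i, det(0, float(rng.integers(0, 40)), float(rng.integers(0, 40))))
                    for i in range(n)]
            rep_tp = evaluate_tracking(gt, pred).tp if _any_overlap(gt, pred) else 0
            best = 0
            for perm in itertools.permutations(range(n)):
                c = sum(
                    1 for i, j in enumerate(perm)
                    if iou(gt[i][1].box, pred[j][1].box) >= 0.5
                )
                best = max(best, c)
            assert rep_tp == best

    def test_zero_gt_errors(self):
        with pytest.raises(ValueError):
            evaluate_tracking([], [(1, det(0, 0, 0))])

    def test_mota_leq_one_and_exact_condition(self):
        gt = self.track_records({f: [(1, 0, 0)] for f in range(5)})
        rep = evaluate_tracking(gt, gt)
        assert rep.mota <= 1.0
        assert rep.mota == 1.0 and rep.fn == rep.fp == rep.idsw == 0

    def test_mota_convenience(self):
        gt = self.track_records({0: [(1, 0, 0)]})
        assert mota(gt, gt) == 1.0


def _any_overlap(gt, pred):
    return any(iou(g[1].box, p[1].box) >= 0.5 for g in gt for p in pred)


class TestMOTP:
    def test_exact_matches(self):
        assert motp([1.0, 1.0, 1.0]) == 1.0

    def test_two_match_fixture(self):
        assert motp([1.0, 1 / 7]) == pytest.approx((1 + 1 / 7) / 2)

    def test_distance_flag(self):
        assert motp([1.0, 0.5], distance=True) == pytest.approx(0.25)

    def test_order_invariance(self):
        assert motp([0.9, 0.6, 0.7]) == pytest.approx(motp([0.6, 0.7, 0.9]))

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            motp([])


class TestLocomotionMSE:
    def test_identical(self):
        assert locomotion_mse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_hand_value(self):
        assert locomotion_mse([1.0, 2.0], [2.0, 2.0]) == 0.5

    def test_arithmetic_oracle(self, rng):
        t = rng.uniform(0, 10, 20)
        e = rng.uniform(0, 10, 20)
        expected = sum((a - b) ** 2 for a, b in zip(t, e)) / 20
        assert locomotion_mse(t, e) == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            locomotion_mse([1.0], [1.0, 2.0])
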