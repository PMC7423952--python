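# penwatch

A detection-agnostic toolkit for quantifying the postures and drinking
behaviour of group-housed animals from top-down video detections. The CNN
detector itself is out of scope: any callable that emits per-frame bounding
boxes with behaviour classes and confidences plugs in, and a seeded pen
simulator provides ground truth and a detector-noise channel for testing and
benchmarking.

The pipeline:

```
simulate ──► detections ──► anchors   (K-medoids anchor-box estimation)
                 │
                 ├────────► index     (group-level behaviour indices, % change)
                 │
                 └─► track ─► profile (per-animal trajectory, time budget,
                       │               distance, speed)
                       └────► evaluate (AP/mAP, log-average miss rate,
                                        MOTA/MOTP, locomotion MSE)
```

## What's inside

| Module                | Purpose |
|-----------------------|---------|
| `penwatch.geometry`   | `[x, y, width, height]` boxes, IoU, shape-only IoU |
| `penwatch.anchors`    | K-medoids clustering of box shapes with `1 − IoU` distance; anchor-count/quality sweep |
| `penwatch.detections` | CSV/JSON-lines wire format, strict validation, detector contract |
| `penwatch.tracking`   | Tracking-by-detection: Hungarian assignment (with non-assignment cost), constant-velocity Kalman coasting, tentative→confirmed→deleted lifecycle |
| `penwatch.analytics`  | Behaviour indices per window (mean animals/frame, robust to dropped frames), percent change vs baseline, individual profiles |
| `penwatch.evaluation` | AP (all-points), mAP, log-average miss rate vs FPPI, CLEAR-MOT MOTA/MOTP, locomotion MSE |
| `penwatch.simulator`  | Seeded pen world (Markov behaviour chains, walk-while-standing, drinker-coupled drinking) + degradation channel (jitter, misses, false positives, class confusion, frame drops) |
| `penwatch.cli`        | `penwatch` command-line app tying it together |

## CLI quick start

```bash
# synthetic pen: 15 animals, 500 frames, mild detector noise
penwatch simulate --frames 500 --seed 1 --jitter-sigma 1 --miss-rate 0.05 \
    --out-dir runs/sim

# anchor estimation and sweep from the ground-truth boxes
penwatch anchors --annotations runs/sim/annotations.csv --k 3 --sweep-max 10 \
    --out-dir runs/anchors

# track, then per-animal profiles
penwatch track --detections runs/sim/detections.csv --out-dir runs/trk
penwatch profile --tracks runs/trk/tracks.csv --frames runs/sim/frames.csv \
    --out-dir runs/prof

# group-level behaviour indices in 100-frame windows + percent change
penwatch index --detections runs/sim/detections.csv --frames runs/sim/frames.csv \
    --window-size 100 --out-dir runs/idx

# detection + tracking metrics against ground truth
penwatch evaluate --ground-truth runs/sim/annotations.csv \
    --predictions runs/trk/tracks.csv --out runs/report.json

# full synthetic study: baseline days, disruption days, percent-change table
penwatch demo --seed 1 --out-dir runs/demo
```

All commands are deterministic for a fixed seed and config; rerunning
produces byte-identical artifacts. Output CSVs carry a schema-version header
comment.

## File formats

- detections: `frame,x,y,width,height,class,score`
- annotations: `frame,x,y,width,height,class,gt_id`
- tracks: `frame,x,y,width,height,class,score,track_id,source`
- frames: `frame,timestamp,fps` (recorded frames only; dropped frames are
  simply absent, timestamps keep true spacing)

Classes are exactly `standing`, `sitting`, `lateral_lying`, `sternal_lying`,
`drinking` (mutually exclusive per animal per frame). A `.jsonl` extension
switches any reader/writer to JSON-lines with the same field names.
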