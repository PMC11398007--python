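# gaitlab

Markerless gait analysis from 2D pose keypoints over a virtual walkway.

Gait speed over a short, standardized walkway is one of the most robust
functional health indicators in clinical medicine ("the sixth vital sign"):
it predicts falls, frailty, cognitive decline and surgical risk.  Measuring
it well normally requires instrumented walkways or optical motion capture.
`gaitlab` implements the analysis engine for the low-cost alternative: a
single handheld camera records a subject walking a 4 m virtual walkway whose
start line, end line and 10 cm waypoints are anchored by augmented-reality
markers; a pose-estimation backend emits 25 body-joint keypoints per frame
at 60 fps; this package turns those keypoint streams into validated
spatiotemporal gait metrics.

The package is aimed at researchers building or validating camera-based gait
instruments, and at anyone who needs a fully synthetic, ground-truth-complete
test bed for gait event detection and metric estimation.

## The pipeline

For joint *i* at time *t*, the raw screen view is the tuple
`(J_i, x_{i,t}, y_{i,t}, q_{i,t}, t)` — pixel coordinates plus a detector
quality score.  Three coordinate systems connect pixels to the clinic:

1. **Camera view** — intrinsics-normalized coordinates,
   `x' = (x − c_x) / f_x`, `y' = (y − c_y) / f_y`.
2. **World view** — depth-scaled 3D coordinates in units of a reference
   depth `z0`, using the AR depth track: `X = x'·(z/z0)`, `Y = y'·(z/z0)`,
   `Z = z/z0` (pinhole back-projection, the default; the inverse-factor
   variant `X = x'·(z0/z)` is also selectable).  The AR start/end markers,
   a known 4 m apart, fix the metric scale.
3. **Walkway frame** — scalar progression of each joint along the
   start→end axis, in metres.

Signals are smoothed by a distance-adaptive Savitzky–Golay filter
(`ŷ_i = Σ_j c_j(d_i) · y_{i+j}`), whose window widens with the subject's
depth ratio `z/z0` because pixel amplitude shrinks with distance while pixel
noise does not.  Gait events (heel strike, toe off, heel rise, feet
adjacent, tibia vertical) are detected from prominence-filtered extrema of
foot-keypoint signals — troughs of the "consistent lowest local mean" — and
segmented into stance and swing phases.  Metrics follow: gait speed from
interpolated line-crossing times, stride and step length from heel-joint
footprint positions, cadence, base of support, and reaction/ignition times
from a velocity-threshold movement-onset detector.  Joint angles use the
three-point included-angle formula
`θ = arccos((a−b)·(c−b) / (|a−b||c−b|))` with vertex *b*.

A synthetic articulated walker (`gaitlab.simulate`) generates all of this
with analytic ground truth — event times, crossing times, stride lengths,
knee-angle traces — so every stage is testable without recorded data, and a
statistics module provides the method-comparison toolkit (Spearman with
exact small-n permutation p-values, Pearson, percent error, Bland–Altman).

## Worked example

Simulate a 1.0 m/s walk with 2 px keypoint noise and 1% joint dropout, then
analyze it:

```bash
gaitlab simulate --out demo --speed 1.0 --noise-sd 2 --dropout 0.01 --seed 5
gaitlab analyze demo/walk_000.keypoints.jsonl \
    --sidecar demo/walk_000.sidecar.json --out demo/bundle
```

which prints (abridged):

```json
{
 "metrics": {
  "gait_speed": 0.999999999999998,
  "stride_length": 1.0905603771087071,
  "step_length": 0.545242632787337,
  "step_count": 8,
  "cadence": 119.99999999999976,
  "base_of_support": 0.11828021657976259,
  "ignition_time": 0.6666666666666596,
  "walk_time": 4.000000000000008
 },
 "version": "0.1.0"
}
```

The simulated subject truly walked at 1.000 m/s with a 1.0909 m stride and a
0.12 m step width: the pipeline recovers speed essentially exactly (it is
depth-anchored), stride length to 0.03%, and base of support to 2 mm
despite the pixel noise.  `step_count` is the number of heel strikes inside
the 4 m measurement window; `cadence` is that count over the walk time, so
on a short walkway it is quantized by boundary effects.  The bundle
directory also holds `events.csv` (every detected gait event), `angles.csv`
(hip/knee/ankle angle traces) and a structured per-stage `log.json`.

The same works in Python:

```python
import gaitlab as gl

walk = gl.simulate_walk(gl.WalkSpec(speed=1.0, pixel_noise_sd=2.0, seed=5))
result = gl.analyze_walk(walk.series, walk.spec.camera, walk.depth, walk.walkway)
print(result.metrics.gait_speed, walk.truth.speed)
```

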