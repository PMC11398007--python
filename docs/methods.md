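# Methods

This note documents the models, conventions and numerical choices behind
`gaitlab`, in the order data flows through the pipeline.

## Keypoint model

A recording is a dense array series: timestamps `(n,)`, pixel coordinates
`(n, 25, 2)` and quality scores `(n, 25)`.  Screen coordinates follow the
pose-estimation convention: origin at the image top-left, x rightward,
y downward, units pixels; timestamps are seconds from recording start.

The 25-joint skeleton roster is artifact-defined (head, nose, neck, sternum,
mid-hip, and left/right ear, shoulder, elbow, wrist, hip, knee, ankle, heel,
big toe, small toe).  Missingness is always encoded in-band as
`quality = 0` with NaN coordinates — every frame carries all 25 joints, so
downstream code never handles ragged frames.  `fill_missing` bridges
dropout gaps of at most `max_gap_frames` (default 3, i.e. 50 ms at 60 fps)
by linear interpolation in time, tags the filled samples, and leaves longer
gaps missing; it never alters a detected keypoint.  Two plain-text dialects
(JSONL per frame, long-format CSV) round-trip losslessly.

## Coordinate systems

Camera view divides out the intrinsics: `x' = (x − cx)/fx`, `y' = (y − cy)/fy`.
The transform is affine and exactly invertible, which the tests assert to
1e-9 px.

World view scales the normalized ray by depth, in units of a reference
depth `z0`.  Two conventions are implemented:

* `pinhole` (default): `X = x'·(z/z0)`, `Y = y'·(z/z0)`, `Z = z/z0`.  This
  is standard pinhole back-projection; the resulting frame is a rigid,
  uniformly scaled copy of metric space, so angles are preserved and a
  single scale factor (anchored by the AR start/end markers, 4 m apart)
  converts world units to metres.
* `as_printed`: `X = x'·(z0/z)`, `Y = y'·(z0/z)`, `Z = z/z0`.  This variant
  shrinks lateral coordinates with distance — the opposite of
  back-projection — and is dimensionally inconsistent with its own depth
  coordinate, but it is retained as a selectable convention for fidelity to
  the published transform.  The two agree exactly wherever `z = z0` and
  differ by the factor `(z0/z)²` on lateral coordinates.

Depth may be per-frame (broadcast to all joints) or per-joint.  `z0` is
taken from the calibration sidecar; absent that, the subject's depth at the
first fully-detected frame.

The walkway is defined by its start/end world points, its metric length
(default 4.0 m, the clinical protocol that excludes initial acceleration;
5 m selectable), the 10 cm waypoint spacing, and an `up` vector that fixes
the vertical.  Progression is the signed projection of a joint onto the
start→end axis in metres; the mediolateral direction is `up × axis`.

## Distance-adaptive Savitzky–Golay smoothing

The smoothed value at frame *i* is the least-squares polynomial fit of
degree `d_i` over a window of `m_i` frames, evaluated at the centre —
equivalently a weighted sum with weights `c_j(d_i)`.  The adaptation:
`m_i` is the nearest odd value of `base_window · (z_i/z0)`, clamped to
`[min_window, max_window]` (defaults 9, 5, 21), so frames recorded farther
from the camera — where a pixel of noise spans more of the body — get wider
windows.  The degree rule is constant 3 by default, standard for kinematic
traces.  Both rules are callables on the policy and every realized
`(m_i, d_i)` pair is exposed for audit.

Edges are handled by symmetric window shrinkage, never padding: the window
shrinks to the largest odd width centred on the frame, and the degree drops
to `m−1` when necessary (width 1 is the identity).  Padding would fabricate
data exactly where reaction/ignition timing is measured.  Missing samples
are bridged by linear interpolation for filter stability but stay flagged
via their quality scores.

Correctness is pinned to two oracles: the closed-form window-5/degree-2
weights `(−3, 12, 17, 12, −3)/35`, and a brute-force per-window polyfit
evaluated at every point including the shrunken edges.

## Joint angles

The included angle at vertex `b` is `arccos` of the normalized dot product
of `a−b` and `c−b`, clamped to `[−1, 1]` so the function is total; frames
with any missing constituent joint are masked invalid rather than
NaN-propagated.  Default triples per side: knee = (hip, knee, ankle),
hip = (shoulder, hip, knee), ankle = (knee, ankle, big toe); the raw
included angle is reported (flexion is its supplement).  Angles may be
evaluated on the 2D camera view or on the world-view sagittal plane
(progression, vertical); since the pinhole world frame is angle-preserving,
the latter recovers true segment angles.

Base of support is the mean mediolateral inter-ankle distance during double
support (frames covered by stance intervals on both sides), in metres; with
no double-support frames it is reported missing with a warning.

## Gait events

The primitive is a trough detector implementing "consistent lowest local
mean": local minima of a centred moving average (window 5) kept when their
prominence reaches a fraction (default 0.2) of the averaged signal's
peak-to-peak range, with minima closer than `min_separation` (default
0.4 s, about half a gait cycle at fast cadence) resolved by keeping the
deeper one, ties to the earlier frame.  Numerically flat signals yield no
events.  Peaks are troughs of the negated signal.

Event rules, per side, on the smoothed world track:

* **Toe off** — troughs of the big-toe progression relative to the pelvis.
  The toe is maximally behind the pelvis exactly at lift-off, making the
  trough a symmetric slope kink whose discrete extremum is frame-accurate.
  The ankle substitutes when toe quality is chronically low.  A `vertical`
  signal variant exists but is not the default: the toe's height is at
  ground level for the whole of stance, so its troughs are
  plateau-degenerate and carry no unique timing.
* **Heel strike** — peaks of heel-relative-to-pelvis progression (the
  forward-position-extremum family used with marker-based capture).
* **Heel rise** — the onset of heel lift within each stance, located at the
  half-maximum of the heel's vertical velocity between heel strike and toe
  off, with sub-frame interpolation rounded to the nearest frame.  For a
  smoothed velocity step the half-maximum sits at the step location itself,
  which makes the estimate robust to the smoothing width.
* **Feet adjacent** — troughs of the absolute inter-ankle progression
  distance; the event is attributed to the faster-moving (swinging) side.
* **Tibia vertical** — sign changes of the knee−ankle progression
  difference (the shank crosses vertical once in mid-stance and once in
  swing), deduplicated at 0.15 s.

Stance tiles heel strike → next ipsilateral toe off; swing tiles toe off →
next ipsilateral heel strike; incomplete boundary phases are dropped and
consecutive same-type events produce a warning and a skipped phase.

## Metrics

Crossing times of the start (progression 0) and end (progression = length)
lines are linearly interpolated between bracketing frames; gait speed is
length over the crossing interval.  Stride length is the difference of
*footprint positions* — the heel joint's progression during the stationary
early-stance frames just after each detected heel strike — between
consecutive ipsilateral heel strikes inside the walkway; step length the
same between contralateral strikes.  Reading placements rather than
pelvis-position-at-event-time makes the lengths insensitive to ±1-frame
event timing, mirroring what a pressure walkway measures.  Step count is
heel strikes inside the crossing interval, cadence is step count over walk
time (quantized on a 4 m walkway by boundary counting).  Movement onset is
the first time pelvis progression velocity exceeds 0.05 m/s sustained for
0.2 s; reaction time = onset − command time (when a command time is
supplied), ignition time = start-line crossing − onset.  Any metric that
cannot be computed is reported as missing with an explanatory warning,
never as a silent zero.

## The synthetic walker

The generator emulates the clinical capture geometry: the camera stands
2.5 m beyond the end line at 1.4 m height; the subject starts 0.5 m before
the start line (acceleration is excluded from the measured 4 m), stands for
1 s, accelerates linearly for 0.4 s, walks at constant speed, and freezes
0.3 m past the end line for a 0.5 s tail.  Gait is driven by the pelvis
distance walked `D(t)`; each foot cycles with period = stride length in
`D`, anchored to the ground during stance (zero progression velocity) and
advancing during swing with profile `dF/dD = 2 + β·sin(πs)`, which fixes
the foot's lift-off and landing velocity at exactly twice the pelvis speed.
That choice makes the relative-progression extrema that the detectors look
for coincide exactly with the model's toe-off and heel-strike instants,
with symmetric kinks that survive symmetric smoothing unshifted.  Knees are
placed by two-link inverse kinematics between hip and ankle
(thigh 0.245 · height, shank 0.246 · height, hip at 0.53 · height), with a
straight-leg clamp at full extension; heel rise begins at 40% of the cycle
at 0.5 m of lift per metre walked; toe clearance peaks at 5 cm.  Arms,
head and trunk sway smoothly and phase-locked.  The subject begins in a
split stance (5 cm stagger), so the first one or two steps are transients;
they fall before the start line and outside the measured window.

Defaults mirror the study conditions the package is validated under: 60 fps,
4 m walkway, stance fraction 0.6, step width 0.12 m, subject height 1.72 m,
cadence tied to speed by the affine rule `85 + 25·v` steps/min (so speed,
cadence and stride stay mutually consistent: speed = stride · cadence/120).

Ground truth is emitted analytically from the continuous model — heel
strike, toe off and heel rise from closed-form cycle positions, feet
adjacent and tibia vertical by root-finding on the continuous signals —
never by re-detecting on the sampled output.  A single seeded generator
drives pixel noise (Gaussian, per coordinate), the quality model
(`clip(N(0.9, 0.05), 0.01, 1)`) and dropout (independent per joint-frame,
quality → 0), so identical specs reproduce bit-identical cohorts.

What the generator does *not* emulate — and what passing tests therefore do
not show about real recordings: pose-estimator bias and outliers (noise is
unbiased Gaussian; real detectors produce structured, occlusion-correlated
errors), depth error (the AR depth track is taken as exact, so
progression-axis signals are noise-limited only by the model; real AR depth
drifts at the centimetre scale), lens distortion, camera shake, pathological
or asymmetric gait, and clothing/footwear effects.  Accuracy figures from
the synthetic cohort are therefore an upper bound on what identical
algorithms achieve on real video.

## Validation harness

The agreement module mirrors standard method-comparison practice: Spearman
rank correlation (average ranks for ties; exact two-sided permutation
p-value by full enumeration for n ≤ 9, t approximation above), Pearson
correlation, percent error (the relative absolute difference of each pair —
the reading under which a "within 2%" agreement claim is well-posed per
measurement), and Bland–Altman bias with 1.96·sd limits of agreement.

`scripts/acceptance.py` ties these together: 50 simulated walks (speeds
uniform 0.6–1.4 m/s, 2 px noise, 1% dropout), full default pipeline, and
the maximum percent error of gait speed and mean stride length versus
ground truth.  The cohort size and noise level were chosen to exercise the
whole pipeline in well under a minute on one core.

## Known limitations

* Cadence on a 4 m walkway is quantized by boundary counting (±1 heel
  strike changes it by ~12%); it is faithful to its definition, not a
  precision estimate.
* The `as_printed` world convention is provided for fidelity, but metrics
  computed under it are not metrically meaningful away from `z = z0`.
* Event detection assumes a roughly straight walk along the walkway axis;
  turning gait and stop-and-go protocols are out of scope.
* The smoother's polynomial-reproduction guarantee holds per realized
  window; across a window-size change boundary the filter is only
  approximately shift-invariant.
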