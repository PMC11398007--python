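"""Synthetic articulated walker with analytic ground truth.

The generator emulates the clinical capture geometry: a subject stands a
configurable offset before the start line of a 4 m virtual walkway and walks
at constant speed toward a handheld camera positioned beyond the end line,
so the subject's depth decreases through the recording.  All 25 skeleton
joints are animated by a planar (sagittal) gait model with parameterized
lateral offsets, projected through the pinhole intrinsics to 60 fps pixel
streams, with Gaussian pixel noise and a per-joint quality/dropout model.

The gait model is driven by the pelvis distance walked, D(t): the subject
stands for ``stand_duration``, accelerates linearly over ``ramp_duration``,
walks at ``speed`` until ``overshoot`` metres past the end line, then freezes
(capping D) for a short tail.  Each foot cycles with period ``stride_length``
in D; during stance the foot is anchored to the ground (zero progression
velocity), during swing it advances with velocity profile
``dF/dD = 2 + beta * sin(pi * s)`` so that the foot's velocity at lift-off and
landing is exactly twice the pelvis speed.  This makes the toe's and heel's
progression relative to the pelvis piecewise monotone with symmetric slope
kinks of exactly +-speed at toe off and heel strike, so those events are the
exact extrema of the signals the event detectors examine.  Knees are placed
by two-link inverse kinematics between hip and ankle (straight-leg clamp at
full extension).

Every ground-truth quantity is derived from the continuous model — event
times analytically or by root-finding on the continuous signals — never by
re-detecting on the sampled output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from .events import EventType, Side
from .keypoints import JOINT_INDEX, N_JOINTS, KeypointSeries
from .views import CameraIntrinsics, DepthTrack
from .walkway import WalkwayDefinition

__all__ = [
    "WalkSpec",
    "GroundTruth",
    "SimulatedWalk",
    "SpecificationError",
    "default_cadence",
    "simulate_walk",
    "simulate_cohort",
    "match_events",
]


class SpecificationError(ValueError):
    """Inconsistent or out-of-range walk specification."""


def default_cadence(speed: float) -> float:
    """Affine speed->cadence rule (steps/min) used when cadence is unspecified."""
    return 85.0 + 25.0 * speed


@dataclass
class WalkSpec:
    """Parameters of one simulated walk.

    ``speed = stride_length * cadence / 120`` must hold within 1e-6 whenever
    all three are given; unspecified members are derived (cadence from the
    affine default rule, stride from the other two).
    """

    speed: float = 1.0  # m/s
    cadence: float | None = None  # steps/min
    stride_length: float | None = None  # m
    stance_fraction: float = 0.6
    step_width: float = 0.12  # m, lateral heel-centre separation
    subject_height: float = 1.72  # m
    start_offset: float = 0.5  # m of acceleration room before the start line
    walkway_length: float = 4.0  # m
    overshoot: float = 0.3  # m walked past the end line before freezing
    camera: CameraIntrinsics = field(
        default_factory=lambda: CameraIntrinsics(fx=720.0, fy=720.0, cx=360.0, cy=640.0)
    )
    camera_height: float = 1.4  # m
    camera_beyond_end: float = 2.5  # m behind the end line
    stand_duration: float = 1.0  # s standing before gait initiation
    ramp_duration: float = 0.4  # s linear acceleration to speed
    tail_duration: float = 0.5  # s recorded after the freeze
    command_time: float = 0.7  # s, "walk" command (for reaction time)
    heel_rise_fraction: float = 0.4  # gait-cycle fraction at which the heel lifts
    clearance: float = 0.05  # m peak toe clearance in swing
    fps: float = 60.0
    pixel_noise_sd: float = 0.0  # px
    dropout_prob: float = 0.0  # per joint per frame
    quality_mean: float = 0.9
    quality_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.1 <= self.speed <= 3.0):
            raise SpecificationError(f"speed {self.speed} m/s outside plausible range")
        if not (0.5 < self.stance_fraction < 0.75):
            raise SpecificationError("stance_fraction must be in (0.5, 0.75)")
        if self.cadence is None and self.stride_length is None:
            self.cadence = default_cadence(self.speed)
        if self.cadence is None:
            self.cadence = 120.0 * self.speed / self.stride_length
        if self.stride_length is None:
            self.stride_length = 120.0 * self.speed / self.cadence
        if abs(self.speed - self.stride_length * self.cadence / 120.0) > 1e-6:
            raise SpecificationError(
                f"inconsistent triple: speed={self.speed}, cadence={self.cadence}, "
                f"stride={self.stride_length} (need speed = stride * cadence / 120)"
            )
        if self.stride_length <= 0 or self.cadence <= 0:
            raise SpecificationError("cadence and stride_length must be positive")
        if self.command_time >= self.stand_duration:
            raise SpecificationError("command_time must precede gait initiation")


@dataclass
class GroundTruth:
    """Analytic truth for one simulated walk."""

    speed: float
    stride_length: float
    step_length: float
    cadence: float
    step_count: int
    step_width: float
    stance_fraction: float
    walk_time: float
    t_cross_start: float
    t_cross_end: float
    movement_onset: float
    command_time: float
    reaction_time: float
    ignition_time: float
    events: dict[tuple[str, str], list[float]]
    t: np.ndarray
    knee_angle: dict[str, np.ndarray]

    def event_times(self, type_: EventType, side: Side) -> list[float]:
        return self.events.get((type_.value, side.value), [])


@dataclass
class SimulatedWalk:
    spec: WalkSpec
    series: KeypointSeries
    depth: DepthTrack
    walkway: WalkwayDefinition
    truth: GroundTruth


# anthropometric fractions of subject height
_HIP_H = 0.53
_THIGH = 0.245
_SHANK = 0.246
_SHOULDER_H = 0.80
_NECK_H = 0.84
_STERNUM_H = 0.70
_HEAD_H = 0.95
_NOSE_H = 0.91
_EAR_H = 0.90
_ANKLE_H = 0.09
_HEEL_RISE_RATE = 0.5  # metres of heel lift per metre of cycle distance
_HEEL_CLEAR = 0.03
_ANKLE_FWD = 0.06
_BIG_TOE_FWD = 0.22
_SMALL_TOE_FWD = 0.19
_INIT_STAGGER = 0.05  # split-stance standing posture, metres
_HIP_W = 0.18
_SHOULDER_W = 0.36
_EAR_W = 0.14
_BOUNCE = 0.015
_SWAY = 0.02
_ARM_SWING = 0.12


class _WalkModel:
    """Continuous-time articulated model; evaluates positions at any D."""

    def __init__(self, spec: WalkSpec):
        self.spec = spec
        self.v = spec.speed
        self.L = spec.stride_length
        self.f_st = spec.stance_fraction
        self.r_hr = spec.heel_rise_fraction
        self.p0 = -spec.start_offset
        self.lead = self.f_st * self.L / 2.0
        self.D_stop = spec.start_offset + spec.walkway_length + spec.overshoot
        self.t1 = spec.stand_duration
        self.Tr = spec.ramp_duration
        self.D_ramp = self.v * self.Tr / 2.0
        self.camera_prog = spec.walkway_length + spec.camera_beyond_end
        self.H = spec.subject_height
        # side parameters: phase offset, initial-cycle index, initial placement
        self.side_par = {
            "left": (0.0, 0, self.p0 + _INIT_STAGGER),
            "right": (0.5, -1, self.p0 - _INIT_STAGGER),
        }

    # -- distance walked ----------------------------------------------------
    def D_of_t(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        d = np.where(
            t <= self.t1,
            0.0,
            np.where(
                t <= self.t1 + self.Tr,
                self.v * (t - self.t1) ** 2 / (2 * self.Tr),
                self.D_ramp + self.v * (t - self.t1 - self.Tr),
            ),
        )
        return np.minimum(d, self.D_stop)

    def t_of_D(self, D: float) -> float:
        if D <= 0:
            return self.t1
        if D <= self.D_ramp:
            return self.t1 + float(np.sqrt(2 * self.Tr * D / self.v))
        return self.t1 + self.Tr + (D - self.D_ramp) / self.v

    @property
    def duration(self) -> float:
        return self.t_of_D(self.D_stop) + self.spec.tail_duration

    # -- per-side foot kinematics -------------------------------------------
    def _placement(self, k: np.ndarray, side: str) -> np.ndarray:
        o, k_init, init_pl = self.side_par[side]
        steady = self.p0 + (k + o) * self.L + self.lead
        return np.where(k <= k_init, init_pl, steady)

    def foot(self, D: np.ndarray, side: str):
        """Foot-origin progression, heel height and toe height at distances D."""
        D = np.asarray(D, dtype=float)
        o, _, _ = self.side_par[side]
        phi_raw = D / self.L - o
        k = np.floor(phi_raw)
        phi = phi_raw - k
        in_stance = phi <= self.f_st
        pl = self._placement(k, side)
        pl_next = self._placement(k + 1, side)
        dD_sw = (1.0 - self.f_st) * self.L
        s = np.clip((phi - self.f_st) / (1.0 - self.f_st), 0.0, 1.0)
        delta = pl_next - pl
        beta = (delta / dD_sw - 2.0) * np.pi / 2.0
        prog_swing = pl + dD_sw * (2.0 * s + beta * (1.0 - np.cos(np.pi * s)) / np.pi)
        prog = np.where(in_stance, pl, prog_swing)
        h_to = _HEEL_RISE_RATE * self.L * (self.f_st - self.r_hr)
        heel_stance = _HEEL_RISE_RATE * self.L * np.clip(phi - self.r_hr, 0.0, None)
        heel_swing = h_to * (1.0 + np.cos(np.pi * s)) / 2.0 + _HEEL_CLEAR * np.sin(np.pi * s)
        heel_h = np.where(in_stance, heel_stance, heel_swing)
        toe_h = np.where(in_stance, 0.0, self.spec.clearance * np.sin(np.pi * s))
        return prog, heel_h, toe_h

    def _knee(self, hip_p, hip_h, ank_p, ank_h):
        """Two-link IK in the sagittal plane; anterior solution, clamped."""
        lt, ls = _THIGH * self.H, _SHANK * self.H
        dx = ank_p - hip_p
        dy = ank_h - hip_h
        d = np.sqrt(dx * dx + dy * dy)
        d = np.maximum(d, 1e-9)
        reach = lt + ls
        a = np.clip((lt**2 - ls**2 + d**2) / (2 * d), None, np.minimum(lt, d))
        h = np.sqrt(np.clip(lt**2 - a**2, 0.0, None))
        ux, uy = dx / d, dy / d
        clamped = d >= reach
        kx = np.where(clamped, hip_p + lt * ux, hip_p + a * ux - uy * h)
        ky = np.where(clamped, hip_h + lt * uy, hip_h + a * uy + ux * h)
        return kx, ky

    def positions(self, D: np.ndarray) -> np.ndarray:
        """(n, 25, 3) joint positions in (progression, lateral, height), metres."""
        D = np.atleast_1d(np.asarray(D, dtype=float))
        n = D.size
        out = np.empty((n, N_JOINTS, 3))
        cyc = D / self.L
        pelvis_p = self.p0 + D
        pelvis_h = _HIP_H * self.H - _BOUNCE * (1.0 - np.cos(4 * np.pi * cyc)) / 2.0
        sway = _SWAY * np.sin(2 * np.pi * cyc)

        def put(name, p, lat, h):
            j = JOINT_INDEX[name]
            out[:, j, 0] = p
            out[:, j, 1] = lat
            out[:, j, 2] = h

        put("mid_hip", pelvis_p, sway, pelvis_h)
        put("sternum", pelvis_p, sway, _STERNUM_H * self.H)
        put("neck", pelvis_p, sway, _NECK_H * self.H)
        put("head", pelvis_p, sway, _HEAD_H * self.H)
        put("nose", pelvis_p + 0.03, sway, _NOSE_H * self.H)
        arm = _ARM_SWING * np.sin(2 * np.pi * cyc)
        for side, sgn in (("left", 1.0), ("right", -1.0)):
            # arms swing in anti-phase with the ipsilateral leg
            a_sgn = -1.0 if side == "left" else 1.0
            put(f"{side}_ear", pelvis_p, sway + sgn * _EAR_W / 2, _EAR_H * self.H)
            put(f"{side}_shoulder", pelvis_p, sway + sgn * _SHOULDER_W / 2, _SHOULDER_H * self.H)
            put(f"{side}_elbow", pelvis_p + 0.5 * a_sgn * arm, sway + sgn * _SHOULDER_W / 2, 0.62 * self.H)
            put(f"{side}_wrist", pelvis_p + a_sgn * arm + 0.05, sway + sgn * _SHOULDER_W / 2, 0.47 * self.H)
            hip_lat = sway + sgn * _HIP_W / 2
            put(f"{side}_hip", pelvis_p, hip_lat, pelvis_h)
            foot_p, heel_h, toe_h = self.foot(D, side)
            foot_lat = sgn * self.spec.step_width / 2
            ank_p = foot_p + _ANKLE_FWD
            ank_h = _ANKLE_H + 0.75 * heel_h + 0.25 * toe_h
            put(f"{side}_ankle", ank_p, foot_lat, ank_h)
            put(f"{side}_heel", foot_p, foot_lat, heel_h)
            put(f"{side}_big_toe", foot_p + _BIG_TOE_FWD, foot_lat, toe_h)
            put(f"{side}_small_toe", foot_p + _SMALL_TOE_FWD, foot_lat + sgn * 0.04, toe_h)
            kx, ky = self._knee(pelvis_p, pelvis_h, ank_p, ank_h)
            put(f"{side}_knee", kx, 0.5 * (hip_lat + foot_lat), ky)
        return out

    # -- ground-truth event enumeration -------------------------------------
    def _analytic_event_distances(self) -> dict[tuple[str, str], list[float]]:
        ev: dict[tuple[str, str], list[float]] = {}
        for side in ("left", "right"):
            o, k_init, _ = self.side_par[side]
            hs, to, hr = [], [], []
            k = k_init
            while True:
                d_hs = (k + 1 + o) * self.L
                d_to = (k + o + self.f_st) * self.L
                d_hr = (k + o + self.r_hr) * self.L
                if min(d_hs, d_to, d_hr) > self.D_stop:
                    break
                if 0.0 < d_hs < self.D_stop:
                    hs.append(d_hs)
                if 0.0 < d_to < self.D_stop:
                    to.append(d_to)
                if 0.0 < d_hr < self.D_stop:
                    hr.append(d_hr)
                k += 1
            ev[(EventType.HEEL_STRIKE.value, side)] = hs
            ev[(EventType.TOE_OFF.value, side)] = to
            ev[(EventType.HEEL_RISE.value, side)] = hr
        return ev

    def _root_scan(self, f: Callable[[float], float], lo: float, hi: float, n: int = 400) -> list[float]:
        grid = np.linspace(lo, hi, n)
        vals = np.array([f(g) for g in grid])
        roots = []
        for i in range(n - 1):
            if vals[i] == 0.0:
                roots.append(float(grid[i]))
            elif vals[i] * vals[i + 1] < 0:
                roots.append(float(brentq(f, grid[i], grid[i + 1], xtol=1e-10)))
        return roots

    def event_distances(self) -> dict[tuple[str, str], list[float]]:
        ev = self._analytic_event_distances()

        def foot_prog(D: float, side: str) -> float:
            return float(self.foot(np.array([D]), side)[0][0])

        # feet adjacent: swing ankle passes stance ankle, once per swing
        for side in ("left", "right"):
            other = "right" if side == "left" else "left"
            o, k_init, _ = self.side_par[side]
            adj = []
            k = k_init
            while True:
                d_lo = (k + o + self.f_st) * self.L
                d_hi = (k + 1 + o) * self.L
                if d_lo >= self.D_stop:
                    break
                k += 1
                lo = max(d_lo, 0.0) + 1e-9
                hi = min(d_hi, self.D_stop) - 1e-9
                if hi <= lo:
                    continue
                g = lambda D: foot_prog(D, side) - foot_prog(D, other)
                adj.extend(self._root_scan(g, lo, hi, n=60))
            ev[(EventType.FEET_ADJACENT.value, side)] = adj

        # tibia vertical: knee-ankle progression difference crosses zero
        for side in ("left", "right"):
            j_knee = JOINT_INDEX[f"{side}_knee"]
            j_ankle = JOINT_INDEX[f"{side}_ankle"]

            def shank(D: float) -> float:
                p = self.positions(np.array([D]))
                return float(p[0, j_knee, 0] - p[0, j_ankle, 0])

            n_grid = max(200, int(self.D_stop / self.L * 120))
            ev[(EventType.TIBIA_VERTICAL.value, side)] = self._root_scan(
                shank, 1e-6, self.D_stop - 1e-6, n=n_grid
            )
        return ev


def simulate_walk(spec: WalkSpec) -> SimulatedWalk:
    """Generate one walk: keypoint series, depth, walkway, and ground truth."""
    model = _WalkModel(spec)
    n = int(np.floor(model.duration * spec.fps)) + 1
    t = np.arange(n) / spec.fps
    D = model.D_of_t(t)
    P = model.positions(D)  # (n, 25, 3) in (prog, lat, height)

    z = model.camera_prog - P[:, :, 0]  # per-joint depth, metres
    z0 = float(model.camera_prog - model.p0)  # pelvis depth at frame 0
    cam = spec.camera
    u = cam.cx + cam.fx * P[:, :, 1] / z
    v = cam.cy + cam.fy * (spec.camera_height - P[:, :, 2]) / z

    rng = np.random.default_rng(spec.seed)
    if spec.pixel_noise_sd > 0:
        u = u + rng.normal(0.0, spec.pixel_noise_sd, u.shape)
        v = v + rng.normal(0.0, spec.pixel_noise_sd, v.shape)
    quality = np.clip(rng.normal(spec.quality_mean, spec.quality_sd, (n, N_JOINTS)), 0.01, 1.0)
    if spec.dropout_prob > 0:
        drop = rng.random((n, N_JOINTS)) < spec.dropout_prob
        quality[drop] = 0.0
        u = np.where(drop, np.nan, u)
        v = np.where(drop, np.nan, v)

    series = KeypointSeries(t, np.stack([u, v], axis=2), quality, nominal_fps=spec.fps)
    depth = DepthTrack(z, z0)

    start = np.array([0.0, spec.camera_height / z0, (model.camera_prog - 0.0) / z0])
    end = np.array([0.0, spec.camera_height / z0, (model.camera_prog - spec.walkway_length) / z0])
    walkway = WalkwayDefinition(
        start=start,
        end=end,
        length=spec.walkway_length,
        waypoint_spacing=0.10,
        scale=z0,
        up=np.array([0.0, -1.0, 0.0]),
    )

    # --- ground truth -------------------------------------------------------
    t_cross_start = model.t_of_D(spec.start_offset)
    t_cross_end = model.t_of_D(spec.start_offset + spec.walkway_length)
    events = {
        key: [model.t_of_D(d) for d in dists]
        for key, dists in model.event_distances().items()
    }
    hs_all = (
        events[(EventType.HEEL_STRIKE.value, "left")]
        + events[(EventType.HEEL_STRIKE.value, "right")]
    )
    step_count = sum(1 for ht in hs_all if t_cross_start <= ht <= t_cross_end)

    knee_angle = {}
    for side in ("left", "right"):
        hp = P[:, JOINT_INDEX[f"{side}_hip"], :][:, [0, 2]]
        kn = P[:, JOINT_INDEX[f"{side}_knee"], :][:, [0, 2]]
        an = P[:, JOINT_INDEX[f"{side}_ankle"], :][:, [0, 2]]
        uvec = hp - kn
        vvec = an - kn
        cosang = np.sum(uvec * vvec, axis=1) / (
            np.linalg.norm(uvec, axis=1) * np.linalg.norm(vvec, axis=1)
        )
        knee_angle[side] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))

    truth = GroundTruth(
        speed=spec.speed,
        stride_length=spec.stride_length,
        step_length=spec.stride_length / 2.0,
        cadence=spec.cadence,
        step_count=step_count,
        step_width=spec.step_width,
        stance_fraction=spec.stance_fraction,
        walk_time=t_cross_end - t_cross_start,
        t_cross_start=t_cross_start,
        t_cross_end=t_cross_end,
        movement_onset=model.t1,
        command_time=spec.command_time,
        reaction_time=model.t1 - spec.command_time,
        ignition_time=t_cross_start - model.t1,
        events=events,
        t=t,
        knee_angle=knee_angle,
    )
    return SimulatedWalk(spec, series, depth, walkway, truth)


def simulate_cohort(
    n: int,
    speed_range: tuple[float, float] = (0.6, 1.4),
    noise_sd: float = 2.0,
    seed: int = 0,
    dropout_prob: float = 0.01,
    **overrides,
) -> list[SimulatedWalk]:
    """n walks with speeds uniform in speed_range, cadence co-varying affinely.

    A single seed governs both the speed draws and every walk's noise stream
    (per-walk seeds are spawned from it), so the same call reproduces the
    same cohort bit for bit.
    """
    if n < 1:
        raise SpecificationError("cohort size must be >= 1")
    lo, hi = speed_range
    if not (lo < hi):
        raise SpecificationError(f"empty speed range {speed_range}")
    if n == 1:
        warnings.warn("single-walk cohort: downstream statistics will be degenerate", stacklevel=2)
    rng = np.random.default_rng(seed)
    speeds = rng.uniform(lo, hi, size=n)
    walk_seeds = rng.integers(0, 2**31 - 1, size=n)
    walks = []
    for sp, ws in zip(speeds, walk_seeds):
        spec = WalkSpec(
            speed=float(sp),
            pixel_noise_sd=noise_sd,
            dropout_prob=dropout_prob,
            seed=int(ws),
            **overrides,
        )
        walks.append(simulate_walk(spec))
    return walks


def match_events(
    truth_times: list[float],
    detected_times: list[float],
    tol: float,
    window: tuple[float, float] | None = None,
) -> tuple[int, int, int]:
    """Greedy 1-1 matching of detected to true event times within +-tol seconds.

    When *window* is given, recall is scored over truth events inside it
    (matched against all detections) and precision over detections inside the
    window shrunk by tol (matched against all truth events), so jitter across
    the window boundary is not penalized.
    Returns (true positives, false positives, false negatives).
    """
    tr = sorted(truth_times)
    de = sorted(detected_times)
    if window is None:
        lo, hi = -np.inf, np.inf
    else:
        lo, hi = window

    def greedy(queries: list[float], pool: list[float]) -> int:
        used = [False] * len(pool)
        hits = 0
        for x in queries:
            best, best_d = None, tol
            for i, y in enumerate(pool):
                if not used[i] and abs(y - x) <= best_d:
                    best, best_d = i, abs(y - x)
            if best is not None:
                used[best] = True
                hits += 1
        return hits

    tr_win = [x for x in tr if lo <= x <= hi]
    tp = greedy(tr_win, de)
    fn = len(tr_win) - tp
    de_core = [y for y in de if lo + tol <= y <= hi - tol]
    fp = len(de_core) - greedy(de_core, tr)
    return tp, fp, fn
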