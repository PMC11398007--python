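"""Gait event detection and phase segmentation.

Events are located on scalar signals derived from the (smoothed) world track.
The workhorse is a trough detector: troughs are prominence-filtered local
minima of a centred moving average ("consistent lowest local mean"), with
close minima resolved by keeping the deeper one.

Per-side detection rules:

* TOE_OFF       — troughs of the big-toe progression relative to the pelvis
                  (the toe is maximally behind the pelvis at lift-off).  A
                  ``vertical`` signal variant is selectable.
* HEEL_STRIKE   — maxima of the heel progression relative to the pelvis (the
                  heel is maximally ahead at initial contact; the classic
                  forward-position-extremum rule).
* HEEL_RISE     — onset of heel lift in late stance, located at the
                  half-maximum of the heel's vertical velocity between the
                  preceding heel strike and the toe off (for a smoothed
                  velocity step this is the step location itself).
* FEET_ADJACENT — troughs of the absolute inter-ankle progression distance;
                  the side is the swinging foot.
* TIBIA_VERTICAL — frames where the knee-ankle segment is orthogonal to the
                  ground axis, i.e. sign changes of the knee-ankle progression
                  difference.

Stance = heel strike -> next ipsilateral toe off; swing = toe off -> next
ipsilateral heel strike; incomplete boundary phases are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Literal

import numpy as np
from scipy.signal import find_peaks

from .keypoints import JOINT_INDEX
from .views import WorldTrack, project_to_walkway_axis, vertical_height
from .walkway import WalkwayDefinition

__all__ = [
    "EventType",
    "Side",
    "Phase",
    "GaitEvent",
    "GaitPhase",
    "TroughPolicy",
    "EventConfig",
    "InsufficientDataError",
    "detect_troughs",
    "detect_events",
    "segment_phases",
]


class EventType(str, Enum):
    HEEL_STRIKE = "HEEL_STRIKE"
    TOE_OFF = "TOE_OFF"
    HEEL_RISE = "HEEL_RISE"
    FEET_ADJACENT = "FEET_ADJACENT"
    TIBIA_VERTICAL = "TIBIA_VERTICAL"


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"


class Phase(str, Enum):
    STANCE = "STANCE"
    SWING = "SWING"


class InsufficientDataError(ValueError):
    """Required joints missing throughout the recording."""


@dataclass(frozen=True, order=True)
class GaitEvent:
    t: float
    type: EventType = field(compare=False)
    side: Side = field(compare=False)
    frame: int = field(compare=False)


@dataclass(frozen=True)
class GaitPhase:
    side: Side
    phase: Phase
    start_t: float
    end_t: float


@dataclass
class TroughPolicy:
    """Parameters of the local-mean trough detector."""

    local_mean_window: int = 5
    min_separation: float = 0.4  # seconds; ~half a gait cycle at fast cadence
    prominence_fraction: float = 0.2  # of the local-mean signal's peak-to-peak

    def __post_init__(self) -> None:
        if self.local_mean_window < 1:
            raise ValueError("local_mean_window must be >= 1")
        if self.min_separation <= 0:
            raise ValueError("min_separation must be positive")
        if not (0 < self.prominence_fraction < 1):
            raise ValueError("prominence_fraction must be in (0, 1)")


@dataclass
class EventConfig:
    """Signal choices and thresholds for full event detection."""

    troughs: TroughPolicy = field(default_factory=TroughPolicy)
    toe_off_signal: Literal["relative_progression", "vertical"] = "relative_progression"
    toe_quality_floor: float = 0.2  # mean quality below this -> ankle fallback
    heel_rise_velocity_floor: float = 0.05  # m/s; stances lifting slower emit no event
    tibia_min_separation: float = 0.15  # seconds between successive crossings


def _local_mean(signal: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with symmetric shrinkage at the edges."""
    n = signal.size
    if window <= 1 or n == 0:
        return signal.astype(float).copy()
    out = np.empty(n, dtype=float)
    half = (window - 1) // 2
    csum = np.concatenate([[0.0], np.cumsum(signal)])
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = (csum[i + h + 1] - csum[i - h]) / (2 * h + 1)
    return out


def detect_troughs(signal: np.ndarray, policy: TroughPolicy | None = None, dt: float = 1.0 / 60.0) -> list[int]:
    """Frames of consistent lowest local mean of *signal*.

    Local minima of the centred moving average are kept when their prominence
    is at least ``prominence_fraction`` of the averaged signal's peak-to-peak
    range; minima closer than ``min_separation`` seconds are resolved by
    keeping the deeper one (ties -> earlier frame).  A constant signal yields
    no troughs.
    """
    policy = policy or TroughPolicy()
    signal = np.asarray(signal, dtype=float)
    if signal.size < policy.local_mean_window:
        raise ValueError(
            f"signal length {signal.size} < local_mean_window {policy.local_mean_window}"
        )
    sm = _local_mean(signal, policy.local_mean_window)
    p2p = float(np.nanmax(sm) - np.nanmin(sm))
    # numerically flat signals (no oscillation to detect) yield no troughs
    if not np.isfinite(p2p) or p2p <= 1e-9 * max(1.0, float(np.nanmax(np.abs(sm)))):
        return []
    idx, props = find_peaks(-sm, prominence=policy.prominence_fraction * p2p)
    if idx.size == 0:
        return []
    # enforce min_separation: deepest first, ties to the earlier frame
    min_gap = policy.min_separation / dt
    order = sorted(range(idx.size), key=lambda k: (sm[idx[k]], idx[k]))
    kept: list[int] = []
    for k in order:
        f = int(idx[k])
        if all(abs(f - g) >= min_gap for g in kept):
            kept.append(f)
    return sorted(kept)


def _detect_peaks(signal: np.ndarray, policy: TroughPolicy, dt: float) -> list[int]:
    return detect_troughs(-np.asarray(signal, dtype=float), policy, dt)


def _joint_ok(track: WorldTrack, joint: str) -> bool:
    return bool((track.quality[:, JOINT_INDEX[joint]] > 0).any())


def _progression(track: WorldTrack, walkway: WalkwayDefinition, joint: str) -> np.ndarray:
    return project_to_walkway_axis(track, walkway, joint)


def detect_events(
    track: WorldTrack,
    walkway: WalkwayDefinition,
    config: EventConfig | TroughPolicy | None = None,
) -> list[GaitEvent]:
    """Detect all five gait event types on a smoothed world track."""
    if config is None:
        config = EventConfig()
    elif isinstance(config, TroughPolicy):
        config = EventConfig(troughs=config)
    policy = config.troughs
    n = track.n_frames
    if n < 2:
        raise InsufficientDataError("track too short for event detection")
    dt = float(np.median(np.diff(track.t)))

    required = ["mid_hip"] + [f"{s}_{j}" for s in ("left", "right") for j in ("heel", "ankle", "knee")]
    for joint in required:
        if not _joint_ok(track, joint):
            raise InsufficientDataError(f"required joint {joint!r} missing throughout")

    pelvis = _progression(track, walkway, "mid_hip")
    events: list[GaitEvent] = []

    ankle_prog = {s: _progression(track, walkway, f"{s}_ankle") for s in ("left", "right")}

    for side in (Side.LEFT, Side.RIGHT):
        s = side.value
        # --- toe off ---
        toe_name = f"{s}_big_toe"
        use_toe = (
            _joint_ok(track, toe_name)
            and float(np.mean(track.quality[:, JOINT_INDEX[toe_name]])) >= config.toe_quality_floor
        )
        foot_joint = toe_name if use_toe else f"{s}_ankle"
        if config.toe_off_signal == "vertical":
            to_signal = vertical_height(track, walkway, foot_joint)
        else:
            to_signal = _progression(track, walkway, foot_joint) - pelvis
        for f in detect_troughs(to_signal, policy, dt):
            events.append(GaitEvent(float(track.t[f]), EventType.TOE_OFF, side, f))
        # --- heel strike ---
        hs_signal = _progression(track, walkway, f"{s}_heel") - pelvis
        hs_frames = _detect_peaks(hs_signal, policy, dt)
        for f in hs_frames:
            events.append(GaitEvent(float(track.t[f]), EventType.HEEL_STRIKE, side, f))
        # --- heel rise: velocity half-maximum onset within each stance ---
        heel_h = vertical_height(track, walkway, f"{s}_heel")
        heel_v = np.gradient(heel_h, track.t)
        to_frames = sorted(
            e.frame for e in events if e.side is side and e.type is EventType.TOE_OFF
        )
        for to in to_frames:
            prev = [f for f in hs_frames if f < to]
            seg_lo = prev[-1] + 2 if prev else 0
            if to - seg_lo < 4:
                continue
            seg_v = heel_v[seg_lo : to + 1]
            vmax = float(np.nanmax(seg_v))
            if vmax < config.heel_rise_velocity_floor:
                continue
            onset = np.flatnonzero(seg_v >= vmax / 2.0)
            if onset.size:
                f = int(seg_lo + onset[0])
                # sub-frame interpolation of the half-max crossing, rounded
                # to the nearest frame
                if f > seg_lo and heel_v[f] > heel_v[f - 1]:
                    frac = (vmax / 2.0 - heel_v[f - 1]) / (heel_v[f] - heel_v[f - 1])
                    if frac < 0.5:
                        f -= 1
                events.append(GaitEvent(float(track.t[f]), EventType.HEEL_RISE, side, f))
        # --- tibia vertical: knee-ankle progression crossings ---
        shank = _progression(track, walkway, f"{s}_knee") - ankle_prog[s]
        sign = np.sign(shank)
        crossings = np.flatnonzero(np.diff(sign) != 0)
        last_f = -np.inf
        for i in crossings:
            f = int(i if abs(shank[i]) <= abs(shank[i + 1]) else i + 1)
            if (f - last_f) * dt < config.tibia_min_separation:
                continue
            last_f = f
            events.append(GaitEvent(float(track.t[f]), EventType.TIBIA_VERTICAL, side, f))

    # --- feet adjacent: minima of inter-ankle progression distance ---
    gap = np.abs(ankle_prog["left"] - ankle_prog["right"])
    vel = {s: np.gradient(ankle_prog[s], track.t) for s in ("left", "right")}
    for f in detect_troughs(gap, policy, dt):
        side = Side.LEFT if abs(vel["left"][f]) >= abs(vel["right"][f]) else Side.RIGHT
        events.append(GaitEvent(float(track.t[f]), EventType.FEET_ADJACENT, side, f))

    events.sort(key=lambda e: (e.t, e.type.value, e.side.value))
    return events


def segment_phases(events: list[GaitEvent]) -> list[GaitPhase]:
    """Tile stance/swing phases from alternating heel-strike/toe-off streams."""
    phases: list[GaitPhase] = []
    for side in (Side.LEFT, Side.RIGHT):
        seq = sorted(
            (e for e in events if e.side is side and e.type in (EventType.HEEL_STRIKE, EventType.TOE_OFF)),
            key=lambda e: e.t,
        )
        prev: GaitEvent | None = None
        for e in seq:
            if prev is not None:
                if prev.type is e.type:
                    warnings.warn(
                        f"consecutive {e.type.value} events on {side.value} side; phase skipped",
                        stacklevel=2,
                    )
                elif prev.type is EventType.HEEL_STRIKE:
                    phases.append(GaitPhase(side, Phase.STANCE, prev.t, e.t))
                else:
                    phases.append(GaitPhase(side, Phase.SWING, prev.t, e.t))
            prev = e
    phases.sort(key=lambda p: (p.start_t, p.side.value))
    return phases
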