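"""Spatiotemporal gait metrics over the virtual walkway.

Gait speed is walkway length over the start->end line crossing interval of
the pelvis (crossings located by linear interpolation between bracketing
frames).  Stride and step lengths are measured along the progression axis
from heel placements: the heel is stationary during early stance, so its
progression shortly after each detected heel strike is the footprint
position, robust to event-timing quantization — the same quantity a pressure
walkway reports.  Reaction time (command to movement onset) and ignition
time (onset to start-line crossing) use a velocity-threshold onset detector:
first time the pelvis progression velocity exceeds 0.05 m/s sustained for
0.2 s.

Metrics that cannot be computed are reported as missing (None) with an
explanatory warning, never as silent zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .events import EventType, GaitEvent, GaitPhase, Side
from .kinematics import base_of_support
from .views import WorldTrack, project_to_walkway_axis
from .walkway import WalkwayDefinition

__all__ = [
    "GaitMetrics",
    "IncompleteWalkError",
    "crossing_times",
    "compute_metrics",
    "ONSET_VELOCITY_THRESHOLD",
    "ONSET_SUSTAIN_SECONDS",
]

ONSET_VELOCITY_THRESHOLD = 0.05  # m/s
ONSET_SUSTAIN_SECONDS = 0.2


class IncompleteWalkError(ValueError):
    """The subject never crossed the start or end line."""


@dataclass
class GaitMetrics:
    """Flat result record; missing metrics are None, with reasons in warnings."""

    gait_speed: float | None = None
    walk_time: float | None = None
    t_start: float | None = None
    t_end: float | None = None
    stride_length: float | None = None
    stride_length_sd: float | None = None
    stride_length_left: float | None = None
    stride_length_right: float | None = None
    step_length: float | None = None
    step_length_sd: float | None = None
    step_count: int | None = None
    cadence: float | None = None
    base_of_support: float | None = None
    reaction_time: float | None = None
    ignition_time: float | None = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        d = {k: v for k, v in self.__dict__.items()}
        # NaN -> None for clean JSON
        for k, v in d.items():
            if isinstance(v, float) and not np.isfinite(v):
                d[k] = None
        return d


def crossing_times(
    t: np.ndarray, progression: np.ndarray, walkway: WalkwayDefinition
) -> tuple[float, float]:
    """Start/end line crossing times by linear interpolation.

    The first upward crossing of progression 0 and of ``walkway.length`` are
    used.  Raises :class:`IncompleteWalkError` when a line is never crossed.
    """
    t = np.asarray(t, dtype=float)
    p = np.asarray(progression, dtype=float)

    def first_crossing(level: float) -> float:
        at = np.flatnonzero(p == level)
        above = np.flatnonzero((p[:-1] < level) & (p[1:] >= level))
        candidates = []
        if at.size:
            candidates.append(float(t[at[0]]))
        if above.size:
            i = int(above[0])
            frac = (level - p[i]) / (p[i + 1] - p[i])
            candidates.append(float(t[i] + frac * (t[i + 1] - t[i])))
        if not candidates:
            raise IncompleteWalkError(
                f"progression never reaches {level:g} m (max {np.nanmax(p):.3f} m)"
            )
        return min(candidates)

    return first_crossing(0.0), first_crossing(walkway.length)


def _movement_onset(t: np.ndarray, progression: np.ndarray) -> float | None:
    """First time pelvis velocity exceeds the threshold, sustained 0.2 s."""
    if t.size < 3:
        return None
    v = np.gradient(progression, t)
    dt = float(np.median(np.diff(t)))
    k = max(1, int(round(ONSET_SUSTAIN_SECONDS / dt)))
    fast = v > ONSET_VELOCITY_THRESHOLD
    if t.size < k:
        return None
    run = np.convolve(fast.astype(int), np.ones(k, dtype=int), mode="valid")
    hits = np.flatnonzero(run == k)
    if hits.size == 0:
        return None
    return float(t[int(hits[0])])


def _heel_placement(prog: np.ndarray, frame: int) -> float:
    """Heel progression shortly after contact (stationary early-stance window)."""
    n = prog.size
    lo = min(frame + 1, n - 1)
    hi = min(frame + 5, n)
    window = prog[lo:hi]
    window = window[np.isfinite(window)]
    if window.size == 0:
        return float(prog[frame])
    return float(np.median(window))


def compute_metrics(
    world: WorldTrack,
    events: list[GaitEvent],
    phases: list[GaitPhase],
    walkway: WalkwayDefinition,
    command_t: float | None = None,
) -> GaitMetrics:
    """Assemble the spatiotemporal metric set for one walk."""
    m = GaitMetrics()
    pelvis = project_to_walkway_axis(world, walkway, "mid_hip")
    t = world.t

    try:
        m.t_start, m.t_end = crossing_times(t, pelvis, walkway)
        m.walk_time = m.t_end - m.t_start
        m.gait_speed = walkway.length / m.walk_time
    except IncompleteWalkError as exc:
        m.warnings.append(f"incomplete walk: {exc}")

    onset = _movement_onset(t, pelvis)
    if onset is None:
        m.warnings.append("no movement onset detected")
    else:
        if command_t is not None:
            m.reaction_time = onset - command_t
        if m.t_start is not None:
            m.ignition_time = m.t_start - onset

    if m.t_start is None or m.t_end is None:
        return m

    hs = sorted(
        (e for e in events if e.type is EventType.HEEL_STRIKE and m.t_start <= e.t <= m.t_end),
        key=lambda e: e.t,
    )
    m.step_count = len(hs)
    if m.walk_time:
        m.cadence = m.step_count / m.walk_time * 60.0

    heel_prog = {
        side: project_to_walkway_axis(world, walkway, f"{side}_heel")
        for side in ("left", "right")
    }

    strides: dict[str, list[float]] = {"left": [], "right": []}
    for side in (Side.LEFT, Side.RIGHT):
        mine = [e for e in hs if e.side is side]
        placements = [_heel_placement(heel_prog[side.value], e.frame) for e in mine]
        strides[side.value] = [b - a for a, b in zip(placements[:-1], placements[1:])]

    all_strides = strides["left"] + strides["right"]
    if all_strides:
        m.stride_length = float(np.mean(all_strides))
        m.stride_length_sd = float(np.std(all_strides, ddof=1)) if len(all_strides) > 1 else None
        if strides["left"]:
            m.stride_length_left = float(np.mean(strides["left"]))
        if strides["right"]:
            m.stride_length_right = float(np.mean(strides["right"]))
    else:
        m.warnings.append("fewer than 2 ipsilateral heel strikes in walkway; stride length missing")

    steps: list[float] = []
    for a, b in zip(hs[:-1], hs[1:]):
        if a.side is not b.side:
            pa = _heel_placement(heel_prog[a.side.value], a.frame)
            pb = _heel_placement(heel_prog[b.side.value], b.frame)
            steps.append(pb - pa)
    if steps:
        m.step_length = float(np.mean(steps))
        m.step_length_sd = float(np.std(steps, ddof=1)) if len(steps) > 1 else None
    else:
        m.warnings.append("no contralateral heel-strike pairs in walkway; step length missing")

    import warnings as _warnings

    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        bos = base_of_support(world, phases, walkway)
    for w in caught:
        m.warnings.append(str(w.message))
    m.base_of_support = None if not np.isfinite(bos) else bos

    return m
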