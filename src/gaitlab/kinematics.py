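"""Joint-angle traces and base of support.

The included angle at a joint is defined by three keypoints (a, b, c) with b
at the vertex: theta = arccos( (a-b)·(c-b) / (|a-b| |c-b|) ), reported in
degrees in [0, 180].  The arccos argument is clamped to [-1, 1] so the
function is total on non-degenerate input.  Default angle triples follow
standard sagittal kinematics: knee = (hip, knee, ankle), hip = (shoulder,
hip, knee), ankle = (knee, ankle, big_toe), per side; the raw included angle
is reported (flexion is 180 minus it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .keypoints import JOINT_INDEX
from .events import GaitPhase, Phase
from .views import WorldTrack, CameraTrack
from .walkway import WalkwayDefinition

__all__ = [
    "EPSILON",
    "AngleDefinition",
    "JointAngleTrace",
    "DegenerateGeometryError",
    "DEFAULT_ANGLE_DEFINITIONS",
    "joint_angle",
    "angle_traces",
    "base_of_support",
]

EPSILON = 1e-9


class DegenerateGeometryError(ValueError):
    """Vertex coincides with an endpoint."""


@dataclass(frozen=True)
class AngleDefinition:
    """Named angle triple: vectors b->a and b->c span the angle at vertex b."""

    name: str
    a: str
    b: str
    c: str

    def __post_init__(self) -> None:
        if len({self.a, self.b, self.c}) != 3:
            raise ValueError(f"angle {self.name!r}: a, b, c must be distinct joints")
        for j in (self.a, self.b, self.c):
            if j not in JOINT_INDEX:
                raise KeyError(f"angle {self.name!r}: unknown joint {j!r}")


DEFAULT_ANGLE_DEFINITIONS: tuple[AngleDefinition, ...] = tuple(
    AngleDefinition(f"{side}_{name}", a.format(s=side), b.format(s=side), c.format(s=side))
    for side in ("left", "right")
    for name, a, b, c in (
        ("knee", "{s}_hip", "{s}_knee", "{s}_ankle"),
        ("hip", "{s}_shoulder", "{s}_hip", "{s}_knee"),
        ("ankle", "{s}_knee", "{s}_ankle", "{s}_big_toe"),
    )
)


@dataclass
class JointAngleTrace:
    """Per-frame angle in degrees with a validity mask."""

    name: str
    t: np.ndarray
    theta: np.ndarray
    valid: np.ndarray


def joint_angle(a, b, c) -> float | np.ndarray:
    """Included angle (degrees) at vertex *b* formed by points *a* and *c*.

    Accepts single points or arrays of points of shape (..., 2) or (..., 3).
    Raises :class:`DegenerateGeometryError` when an endpoint coincides with
    the vertex (within 1e-9).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    u = a - b
    v = c - b
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    if np.any(nu <= EPSILON) or np.any(nv <= EPSILON):
        raise DegenerateGeometryError("vertex coincides with an endpoint")
    cosang = np.sum(u * v, axis=-1) / (nu * nv)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def _track_points(track: WorldTrack | CameraTrack, joint: str) -> np.ndarray:
    j = JOINT_INDEX[joint]
    if isinstance(track, WorldTrack):
        # sagittal-plane projection: progression (Z) and vertical (Y)
        return np.stack([track.Z[:, j], track.Y[:, j]], axis=1)
    return np.stack([track.x[:, j], track.y[:, j]], axis=1)


def angle_traces(
    track: WorldTrack | CameraTrack,
    definitions: tuple[AngleDefinition, ...] | list[AngleDefinition] = DEFAULT_ANGLE_DEFINITIONS,
) -> list[JointAngleTrace]:
    """Evaluate each angle definition on every frame of a (smoothed) track.

    Frames where any of the three joints is missing (quality 0) or has
    degenerate geometry are masked invalid, never NaN-propagated silently.
    """
    traces = []
    for d in definitions:
        pts = {j: _track_points(track, j) for j in (d.a, d.b, d.c)}
        ja, jb, jc = (JOINT_INDEX[j] for j in (d.a, d.b, d.c))
        valid = (
            (track.quality[:, ja] > 0)
            & (track.quality[:, jb] > 0)
            & (track.quality[:, jc] > 0)
        )
        u = pts[d.a] - pts[d.b]
        v = pts[d.c] - pts[d.b]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        finite = np.isfinite(nu) & np.isfinite(nv)
        ok = valid & finite & (nu > EPSILON) & (nv > EPSILON)
        theta = np.full(track.n_frames, np.nan)
        with np.errstate(invalid="ignore"):
            cosang = np.sum(u * v, axis=1) / np.where(ok, nu * nv, 1.0)
        theta[ok] = np.degrees(np.arccos(np.clip(cosang[ok], -1.0, 1.0)))
        traces.append(JointAngleTrace(d.name, track.t.copy(), theta, ok))
    return traces


def base_of_support(
    world: WorldTrack,
    phases: list[GaitPhase],
    walkway: WalkwayDefinition,
) -> float:
    """Mean mediolateral inter-ankle distance during double support, metres.

    Double support = frames covered by a STANCE interval on both sides.
    Returns NaN (with a warning) when no double-support frames exist.
    """
    in_stance = {side: np.zeros(world.n_frames, dtype=bool) for side in ("left", "right")}
    for ph in phases:
        if ph.phase is Phase.STANCE:
            mask = (world.t >= ph.start_t) & (world.t <= ph.end_t)
            in_stance[ph.side.value] |= mask
    double = in_stance["left"] & in_stance["right"]
    la = world.positions("left_ankle")
    ra = world.positions("right_ankle")
    ml = walkway.mediolateral
    sep = np.abs((la - ra) @ ml) * walkway.scale
    good = double & np.isfinite(sep)
    if not good.any():
        warnings.warn("no double-support frames; base of support undefined", stacklevel=2)
        return float("nan")
    return float(np.mean(sep[good]))
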