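"""Screen, camera and world coordinate views.

A recording passes through three frames of reference:

1. *Screen view* — raw pixel coordinates as emitted by the pose backend
   (:class:`~gaitlab.keypoints.KeypointSeries`).
2. *Camera view* — pixels normalized by the camera intrinsics,
   ``x' = (x - cx) / fx``, ``y' = (y - cy) / fy``; unitless, device-independent.
3. *World view* — depth-scaled 3D coordinates in units of the reference depth
   ``z0``, anchored by the AR walkway markers.

Two world conventions are provided.  ``pinhole`` back-projects the normalized
ray to the joint's depth, ``X = x' * (z / z0)``, which yields a Euclidean
frame (in z0 units) and is the default.  ``as_printed`` applies the inverse
factor ``X = x' * (z0 / z)``; it shrinks lateral coordinates with distance and
is retained for fidelity to the published transform.  Both share
``Z = z / z0`` and agree exactly wherever ``z == z0``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .keypoints import JOINT_INDEX, N_JOINTS, KeypointSeries
from .walkway import WalkwayDefinition

__all__ = [
    "CameraIntrinsics",
    "DepthTrack",
    "CameraTrack",
    "WorldTrack",
    "AlignmentError",
    "to_camera_view",
    "from_camera_view",
    "to_world_view",
    "project_to_walkway_axis",
    "vertical_height",
    "load_sidecar",
    "save_sidecar",
]

WorldConvention = Literal["pinhole", "as_printed"]


class AlignmentError(ValueError):
    """Depth and track do not cover the same frames."""


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics: focal lengths and principal point, in pixels."""

    fx: float
    fy: float
    cx: float
    cy: float

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError(f"focal lengths must be positive (fx={self.fx}, fy={self.fy})")


@dataclass
class DepthTrack:
    """Subject depth in metres: per-frame scalar (n,) or per-joint (n, 25).

    ``z0`` is the reference depth that defines the world unit.  A scalar
    per-frame depth is broadcast to all joints.
    """

    z: np.ndarray
    z0: float

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim not in (1, 2) or (self.z.ndim == 2 and self.z.shape[1] != N_JOINTS):
            raise ValueError(f"depth array must be (n,) or (n, {N_JOINTS}); got {self.z.shape}")
        if np.any(self.z <= 0) or self.z0 <= 0:
            raise ValueError("depths must be strictly positive")

    @property
    def n_frames(self) -> int:
        return int(self.z.shape[0])

    def per_joint(self) -> np.ndarray:
        """Depth broadcast to shape (n, 25)."""
        if self.z.ndim == 1:
            return np.broadcast_to(self.z[:, None], (self.n_frames, N_JOINTS))
        return self.z

    def per_frame(self, reference_joint: str = "mid_hip") -> np.ndarray:
        """A single representative depth per frame (the reference joint's)."""
        if self.z.ndim == 1:
            return self.z
        return self.z[:, JOINT_INDEX[reference_joint]]


@dataclass
class CameraTrack:
    """Normalized (unitless) coordinates per joint per frame, with quality and t."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    quality: np.ndarray
    nominal_fps: float = 60.0

    @property
    def n_frames(self) -> int:
        return int(self.t.shape[0])


@dataclass
class WorldTrack:
    """Depth-scaled 3D coordinates in z0 units, with quality and t."""

    t: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    Z: np.ndarray
    quality: np.ndarray
    convention: WorldConvention = "pinhole"
    nominal_fps: float = 60.0

    @property
    def n_frames(self) -> int:
        return int(self.t.shape[0])

    def positions(self, joint: str | int) -> np.ndarray:
        """(n, 3) world positions of one joint."""
        j = JOINT_INDEX[joint] if isinstance(joint, str) else int(joint)
        return np.stack([self.X[:, j], self.Y[:, j], self.Z[:, j]], axis=1)


def to_camera_view(series: KeypointSeries, cam: CameraIntrinsics) -> CameraTrack:
    """Normalize pixel coordinates by the intrinsics; quality and t carried through."""
    return CameraTrack(
        t=series.t.copy(),
        x=(series.xy[:, :, 0] - cam.cx) / cam.fx,
        y=(series.xy[:, :, 1] - cam.cy) / cam.fy,
        quality=series.quality.copy(),
        nominal_fps=series.nominal_fps,
    )


def from_camera_view(track: CameraTrack, cam: CameraIntrinsics) -> KeypointSeries:
    """Invert :func:`to_camera_view`, recovering pixel coordinates exactly."""
    xy = np.stack([track.x * cam.fx + cam.cx, track.y * cam.fy + cam.cy], axis=2)
    return KeypointSeries(track.t.copy(), xy, track.quality.copy(), track.nominal_fps)


def to_world_view(
    track: CameraTrack, depth: DepthTrack, convention: WorldConvention = "pinhole"
) -> WorldTrack:
    """Lift the normalized track to the depth-scaled world frame.

    ``pinhole``:    X = x' * (z/z0), Y = y' * (z/z0), Z = z/z0
    ``as_printed``: X = x' * (z0/z), Y = y' * (z0/z), Z = z/z0
    """
    if convention not in ("pinhole", "as_printed"):
        raise ValueError(f"unknown world convention {convention!r}")
    if depth.n_frames != track.n_frames:
        raise AlignmentError(
            f"depth covers {depth.n_frames} frames, track has {track.n_frames}"
        )
    ratio = depth.per_joint() / depth.z0  # z / z0, shape (n, 25)
    lateral = ratio if convention == "pinhole" else 1.0 / ratio
    return WorldTrack(
        t=track.t.copy(),
        X=track.x * lateral,
        Y=track.y * lateral,
        Z=ratio.copy(),
        quality=track.quality.copy(),
        convention=convention,
        nominal_fps=track.nominal_fps,
    )


def project_to_walkway_axis(
    world: WorldTrack, walkway: WalkwayDefinition, joint: str = "mid_hip"
) -> np.ndarray:
    """Per-frame scalar progression of *joint* along the start->end axis, metres.

    0 at the start line, ``walkway.length`` at the end line.
    """
    pos = world.positions(joint)
    return (pos - walkway.start) @ walkway.axis * walkway.scale


def vertical_height(
    world: WorldTrack, walkway: WalkwayDefinition, joint: str
) -> np.ndarray:
    """Per-frame height of *joint* above the walkway plane, metres."""
    pos = world.positions(joint)
    return (pos - walkway.start) @ walkway.up * walkway.scale


# ---------------------------------------------------------------------------
# Sidecar I/O: intrinsics + depth + walkway in one JSON document.

def save_sidecar(
    path: str,
    cam: CameraIntrinsics,
    depth: DepthTrack,
    walkway: WalkwayDefinition | None = None,
    extra: dict | None = None,
) -> str:
    doc: dict = {
        "fx": cam.fx,
        "fy": cam.fy,
        "cx": cam.cx,
        "cy": cam.cy,
        "z0": depth.z0,
        "depth": depth.z.tolist(),
    }
    if walkway is not None:
        doc["walkway"] = {
            "start": walkway.start.tolist(),
            "end": walkway.end.tolist(),
            "length": walkway.length,
            "waypoint_spacing": walkway.waypoint_spacing,
            "scale": walkway.scale,
            "up": walkway.up.tolist(),
        }
    if extra:
        doc.update(extra)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, sort_keys=True)
    return path


def load_sidecar(path: str) -> tuple[CameraIntrinsics, DepthTrack, WalkwayDefinition | None]:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    cam = CameraIntrinsics(doc["fx"], doc["fy"], doc["cx"], doc["cy"])
    depth = DepthTrack(np.asarray(doc["depth"], dtype=float), float(doc["z0"]))
    walkway = None
    if "walkway" in doc:
        w = doc["walkway"]
        walkway = WalkwayDefinition(
            start=np.asarray(w["start"]),
            end=np.asarray(w["end"]),
            length=float(w["length"]),
            waypoint_spacing=float(w["waypoint_spacing"]),
            scale=float(w["scale"]),
            up=np.asarray(w.get("up", [0.0, -1.0, 0.0])),
        )
    return cam, depth, walkway
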