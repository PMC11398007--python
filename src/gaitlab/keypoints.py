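"""Keypoint data model and file dialects.

A pose-estimation backend emits, for every video frame, one record per body
joint: ``(joint, x, y, quality, timestamp)`` with image coordinates in pixels
(origin top-left, x rightward, y downward), a detector confidence in [0, 1]
and the timestamp in seconds from recording start.  This module fixes the
25-joint skeleton vocabulary, holds a whole recording as a
:class:`KeypointSeries` (dense numpy arrays), and reads/writes two plain-text
dialects:

* JSONL — one frame per line: ``{"t": float, "kp": [[name, x, y, q], ...]}``
* CSV   — long format with mandatory header ``t,joint,x,y,quality``

Missing detections are encoded as ``quality = 0`` (coordinates NaN), never as
absent rows: after parsing, every frame carries all 25 joints.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np
import pandas as pd

__all__ = [
    "SKELETON",
    "JOINT_INDEX",
    "N_JOINTS",
    "JointId",
    "Keypoint",
    "KeypointFrame",
    "KeypointSeries",
    "FormatError",
    "ValidationError",
    "read_keypoint_series",
    "write_keypoint_series",
    "fill_missing",
    "joint_index",
]

#: Fixed 25-entry skeleton vocabulary (artifact-defined ordering).  The index
#: in this tuple is the joint id.
SKELETON: tuple[str, ...] = (
    "head",
    "nose",
    "neck",
    "sternum",
    "mid_hip",
    "left_ear",
    "left_shoulder",
    "left_elbow",
    "left_wrist",
    "left_hip",
    "left_knee",
    "left_ankle",
    "left_heel",
    "left_big_toe",
    "left_small_toe",
    "right_ear",
    "right_shoulder",
    "right_elbow",
    "right_wrist",
    "right_hip",
    "right_knee",
    "right_ankle",
    "right_heel",
    "right_big_toe",
    "right_small_toe",
)

N_JOINTS = len(SKELETON)
assert N_JOINTS == 25

JOINT_INDEX: dict[str, int] = {name: i for i, name in enumerate(SKELETON)}


class FormatError(ValueError):
    """File does not conform to the declared dialect."""


class ValidationError(ValueError):
    """File parses but violates a series invariant."""


def joint_index(name: str) -> int:
    """Map a joint name to its integer id, raising on unknown names."""
    try:
        return JOINT_INDEX[name]
    except KeyError:
        raise ValidationError(f"unknown joint name: {name!r}") from None


@dataclass(frozen=True)
class JointId:
    """A (id, name) pair from the fixed skeleton; id in [0, 24]."""

    id: int
    name: str

    def __post_init__(self) -> None:
        if not (0 <= self.id < N_JOINTS) or SKELETON[self.id] != self.name:
            raise ValidationError(f"invalid joint: ({self.id}, {self.name!r})")

    @classmethod
    def from_name(cls, name: str) -> "JointId":
        return cls(joint_index(name), name)


@dataclass(frozen=True)
class Keypoint:
    """A single detected joint location at one frame."""

    joint: JointId
    x: float
    y: float
    quality: float
    t: float

    @property
    def missing(self) -> bool:
        return self.quality == 0.0


@dataclass(frozen=True)
class KeypointFrame:
    """All 25 joints at one timestamp."""

    t: float
    keypoints: tuple[Keypoint, ...]

    def __post_init__(self) -> None:
        if len(self.keypoints) != N_JOINTS:
            raise ValidationError(
                f"frame at t={self.t} has {len(self.keypoints)} keypoints, expected {N_JOINTS}"
            )


@dataclass
class KeypointSeries:
    """A dense recording: timestamps (n,), coordinates (n, 25, 2), quality (n, 25).

    Invariants enforced at construction: strictly increasing timestamps;
    quality in [0, 1]; non-finite coordinates only where quality == 0.
    A median frame interval deviating more than 20% from 1/nominal_fps
    attaches a warning string rather than failing.
    """

    t: np.ndarray
    xy: np.ndarray
    quality: np.ndarray
    nominal_fps: float = 60.0
    interpolated: np.ndarray | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float)
        self.quality = np.asarray(self.quality, dtype=float)
        n = self.t.shape[0]
        if self.xy.shape != (n, N_JOINTS, 2) or self.quality.shape != (n, N_JOINTS):
            raise ValidationError(
                f"shape mismatch: t {self.t.shape}, xy {self.xy.shape}, quality {self.quality.shape}"
            )
        if n > 1 and not np.all(np.diff(self.t) > 0):
            bad = int(np.argmin(np.diff(self.t)))
            raise ValidationError(
                f"timestamps not strictly increasing (first violation after frame {bad})"
            )
        if np.any((self.quality < 0) | (self.quality > 1)):
            raise ValidationError("quality values outside [0, 1]")
        bad_coord = ~np.isfinite(self.xy).all(axis=2) & (self.quality > 0)
        if np.any(bad_coord):
            raise ValidationError("non-finite coordinates with quality > 0")
        # flag missing coordinates consistently
        self.xy[self.quality == 0] = np.nan
        if self.interpolated is None:
            self.interpolated = np.zeros((n, N_JOINTS), dtype=bool)
        if n > 1:
            med = float(np.median(np.diff(self.t)))
            expected = 1.0 / self.nominal_fps
            if abs(med - expected) > 0.2 * expected:
                msg = (
                    f"median frame interval {med:.4f}s deviates >20% from "
                    f"nominal 1/{self.nominal_fps:g}s"
                )
                if msg not in self.warnings:
                    self.warnings.append(msg)

    @property
    def n_frames(self) -> int:
        return int(self.t.shape[0])

    def frame(self, i: int) -> KeypointFrame:
        """Materialize frame *i* as record objects (convenience view)."""
        t = float(self.t[i])
        kps = tuple(
            Keypoint(
                JointId(j, SKELETON[j]),
                float(self.xy[i, j, 0]),
                float(self.xy[i, j, 1]),
                float(self.quality[i, j]),
                t,
            )
            for j in range(N_JOINTS)
        )
        return KeypointFrame(t, kps)

    def __iter__(self) -> Iterator[KeypointFrame]:
        return (self.frame(i) for i in range(self.n_frames))

    def copy(self) -> "KeypointSeries":
        return KeypointSeries(
            self.t.copy(),
            self.xy.copy(),
            self.quality.copy(),
            self.nominal_fps,
            None if self.interpolated is None else self.interpolated.copy(),
            list(self.warnings),
        )


Dialect = Literal["jsonl", "csv"]


def _float_or_nan(v: object) -> float:
    if v is None:
        return math.nan
    return float(v)  # type: ignore[arg-type]


def read_keypoint_series(path: str, dialect: Dialect = "jsonl", nominal_fps: float = 60.0) -> KeypointSeries:
    """Read a keypoint file in the given dialect into a validated series.

    Malformed rows are rejected with their line number.  Timestamps must be
    strictly increasing and every frame must carry all 25 joints exactly once.
    """
    if dialect == "jsonl":
        ts: list[float] = []
        xys: list[np.ndarray] = []
        quals: list[np.ndarray] = []
        with open(path, "r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    rec = json.loads(line)
                    t = float(rec["t"])
                    kp = rec["kp"]
                except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                    raise FormatError(f"{path}:{lineno}: malformed frame record ({exc})") from None
                if len(kp) != N_JOINTS:
                    raise ValidationError(
                        f"{path}:{lineno}: frame has {len(kp)} keypoints, expected {N_JOINTS}"
                    )
                xy = np.full((N_JOINTS, 2), np.nan)
                q = np.zeros(N_JOINTS)
                seen: set[int] = set()
                for entry in kp:
                    try:
                        name, x, y, quality = entry
                    except (TypeError, ValueError):
                        raise FormatError(f"{path}:{lineno}: keypoint entry not a 4-tuple") from None
                    j = joint_index(str(name))
                    if j in seen:
                        raise ValidationError(f"{path}:{lineno}: duplicate joint {name!r}")
                    seen.add(j)
                    xy[j, 0] = _float_or_nan(x)
                    xy[j, 1] = _float_or_nan(y)
                    q[j] = float(quality)
                ts.append(t)
                xys.append(xy)
                quals.append(q)
        if not ts:
            return KeypointSeries(
                np.empty(0), np.empty((0, N_JOINTS, 2)), np.empty((0, N_JOINTS)), nominal_fps
            )
        return KeypointSeries(np.array(ts), np.stack(xys), np.stack(quals), nominal_fps)

    if dialect == "csv":
        try:
            df = pd.read_csv(path)
        except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
            raise FormatError(f"{path}: unreadable CSV ({exc})") from None
        required = {"t", "joint", "x", "y", "quality"}
        missing_cols = required - set(df.columns)
        if missing_cols:
            raise FormatError(f"{path}: missing required columns {sorted(missing_cols)}")
        if df.empty:
            return KeypointSeries(
                np.empty(0), np.empty((0, N_JOINTS, 2)), np.empty((0, N_JOINTS)), nominal_fps
            )
        for name in df["joint"].unique():
            joint_index(str(name))
        ts = sorted(df["t"].unique())
        t_index = {t: i for i, t in enumerate(ts)}
        n = len(ts)
        xy = np.full((n, N_JOINTS, 2), np.nan)
        q = np.zeros((n, N_JOINTS))
        counts = np.zeros((n, N_JOINTS), dtype=int)
        fi = df["t"].map(t_index).to_numpy()
        ji = df["joint"].map(JOINT_INDEX).to_numpy()
        np.add.at(counts, (fi, ji), 1)
        if np.any(counts > 1):
            raise ValidationError(f"{path}: duplicate (t, joint) rows")
        if np.any(counts.sum(axis=1) != N_JOINTS):
            bad = int(np.argmax(counts.sum(axis=1) != N_JOINTS))
            raise ValidationError(
                f"{path}: frame t={ts[bad]} has {int(counts.sum(axis=1)[bad])} joints, expected {N_JOINTS}"
            )
        xy[fi, ji, 0] = df["x"].to_numpy(dtype=float)
        xy[fi, ji, 1] = df["y"].to_numpy(dtype=float)
        q[fi, ji] = df["quality"].to_numpy(dtype=float)
        # original file order must match sorted order, else timestamps were non-monotone
        file_order = df["t"].drop_duplicates().to_numpy()
        if not np.array_equal(file_order, np.array(ts)):
            raise ValidationError(f"{path}: timestamps not strictly increasing in file order")
        return KeypointSeries(np.array(ts, dtype=float), xy, q, nominal_fps)

    raise ValueError(f"unknown dialect {dialect!r}")


def write_keypoint_series(series: KeypointSeries, path: str, dialect: Dialect = "jsonl") -> str:
    """Write *series* to *path*; the emitted file re-reads to an equal series.

    Floats are written at full precision (repr), so the round trip is lossless
    well beyond the 6-decimal contract.  Missing keypoints (quality 0) are
    written with null/empty coordinates.
    """
    if dialect == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for i in range(series.n_frames):
                kp = []
                for j in range(N_JOINTS):
                    x, y = series.xy[i, j]
                    kp.append(
                        [
                            SKELETON[j],
                            None if not np.isfinite(x) else float(x),
                            None if not np.isfinite(y) else float(y),
                            float(series.quality[i, j]),
                        ]
                    )
                fh.write(json.dumps({"t": float(series.t[i]), "kp": kp}) + "\n")
        return path

    if dialect == "csv":
        n = series.n_frames
        df = pd.DataFrame(
            {
                "t": np.repeat(series.t, N_JOINTS),
                "joint": list(SKELETON) * n,
                "x": series.xy[:, :, 0].ravel(),
                "y": series.xy[:, :, 1].ravel(),
                "quality": series.quality.ravel(),
            }
        )
        df.to_csv(path, index=False)
        return path

    raise ValueError(f"unknown dialect {dialect!r}")


def fill_missing(series: KeypointSeries, max_gap_frames: int = 3) -> KeypointSeries:
    """Linearly interpolate short dropout gaps in time.

    Quality-0 keypoints inside gaps of at most *max_gap_frames* consecutive
    frames, bracketed by valid detections of the same joint, are interpolated
    (per coordinate, linear in t) and tagged in ``series.interpolated``; their
    quality is set to the mean of the bracketing qualities.  Longer gaps, and
    gaps touching either end of the recording, remain missing.  Keypoints with
    quality > 0 are never altered.
    """
    if max_gap_frames < 0:
        raise ValueError("max_gap_frames must be >= 0")
    out = series.copy()
    if max_gap_frames == 0 or series.n_frames == 0:
        return out
    t = out.t
    for j in range(N_JOINTS):
        valid = out.quality[:, j] > 0
        if valid.all() or not valid.any():
            continue
        idx = np.flatnonzero(valid)
        for a, b in zip(idx[:-1], idx[1:]):
            gap = b - a - 1
            if gap == 0 or gap > max_gap_frames:
                continue
            inside = np.arange(a + 1, b)
            w = (t[inside] - t[a]) / (t[b] - t[a])
            out.xy[inside, j, 0] = out.xy[a, j, 0] + w * (out.xy[b, j, 0] - out.xy[a, j, 0])
            out.xy[inside, j, 1] = out.xy[a, j, 1] + w * (out.xy[b, j, 1] - out.xy[a, j, 1])
            out.quality[inside, j] = 0.5 * (out.quality[a, j] + out.quality[b, j])
            out.interpolated[inside, j] = True
    return out
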