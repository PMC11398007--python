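"""Virtual walkway geometry.

The AR layer of the capture app places a start line, an end line and 10 cm
waypoints on the floor.  Those markers anchor both the progression axis
(start -> end) and the metric scale of the world frame: the start/end
separation is known to be ``length`` metres, so
``scale = length / |end - start|`` converts world units to metres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WalkwayDefinition", "DegenerateWalkwayError"]


class DegenerateWalkwayError(ValueError):
    """Start and end line coincide."""


@dataclass
class WalkwayDefinition:
    """Start/end world points, metric length, and the world->metre scale.

    ``up`` is the unit vector (world frame) pointing away from the floor;
    it defines the vertical for foot-clearance signals and, together with
    the progression axis, the mediolateral direction for base of support.
    """

    start: np.ndarray
    end: np.ndarray
    length: float = 4.0
    waypoint_spacing: float = 0.10
    scale: float | None = None
    up: np.ndarray = field(default_factory=lambda: np.array([0.0, -1.0, 0.0]))

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float)
        self.end = np.asarray(self.end, dtype=float)
        self.up = np.asarray(self.up, dtype=float)
        span = float(np.linalg.norm(self.end - self.start))
        if span <= 0:
            raise DegenerateWalkwayError("walkway start and end coincide")
        if self.scale is None:
            self.scale = self.length / span
        if abs(span * self.scale - self.length) > 1e-6:
            raise ValueError(
                f"|end - start| * scale = {span * self.scale:.8f} != length {self.length}"
            )
        if self.waypoint_spacing <= 0 or abs(
            round(self.length / self.waypoint_spacing) * self.waypoint_spacing - self.length
        ) > 1e-9:
            raise ValueError("waypoint_spacing must evenly divide length")
        n_up = np.linalg.norm(self.up)
        if n_up == 0:
            raise ValueError("up vector must be nonzero")
        self.up = self.up / n_up

    @property
    def axis(self) -> np.ndarray:
        """Unit vector from start line toward end line (world frame)."""
        d = self.end - self.start
        return d / np.linalg.norm(d)

    @property
    def mediolateral(self) -> np.ndarray:
        """Unit vector orthogonal to the progression axis within the ground plane."""
        m = np.cross(self.up, self.axis)
        n = np.linalg.norm(m)
        if n == 0:
            raise ValueError("up vector parallel to walkway axis")
        return m / n

    def waypoints(self) -> np.ndarray:
        """Progression positions (metres) of the 10 cm AR waypoints, 0..length."""
        k = int(round(self.length / self.waypoint_spacing))
        return np.linspace(0.0, self.length, k + 1)
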