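"""Distance-adaptive Savitzky–Golay smoothing.

Keypoint traces are smoothed by local least-squares polynomial fitting: the
smoothed value at frame *i* is a weighted sum of its neighbours,
``y_hat[i] = sum_j c_j(d_i) * y[i+j]``, with the weights obtained by fitting a
degree-``d_i`` polynomial over a window of ``m_i`` frames centred on *i*.

The twist for handheld capture is that pixel amplitude shrinks with the
subject's distance from the camera while pixel noise does not, so relative
noise grows with depth.  The window size therefore adapts to the per-frame
depth ratio ``z_i / z0``: ``m_i`` is the nearest odd value of
``base_window * scaling(z_i / z0)`` clamped to ``[min_window, max_window]``
(linear scaling by default — farther frames get wider windows).

Edges are handled by symmetric window shrinkage (never padding): near the
series boundary the window shrinks to the largest odd width that fits, and
the degree drops with it if needed.  This avoids fabricating data at walk
onset/offset, where reaction and ignition timing are measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.signal import savgol_coeffs, savgol_filter

from .views import CameraTrack, DepthTrack, WorldTrack
from .keypoints import KeypointSeries

__all__ = ["SmoothingPolicy", "savgol_coefficients", "smooth_series", "realized_windows"]


def _nearest_odd(v: float) -> int:
    k = int(round((v - 1.0) / 2.0))
    return 2 * k + 1


@dataclass
class SmoothingPolicy:
    """Window/degree selection rule for the adaptive filter.

    ``distance_scaling`` maps the depth ratio z/z0 to a window multiplier
    (default: identity, i.e. linear in distance); ``degree_rule`` maps the
    ratio to the polynomial degree (default: constant 3, standard for
    kinematic traces).
    """

    base_window: int = 9
    min_window: int = 5
    max_window: int = 21
    degree_rule: Callable[[float], int] = field(default=lambda ratio: 3)
    distance_scaling: Callable[[float], float] = field(default=lambda ratio: ratio)

    def __post_init__(self) -> None:
        for name in ("base_window", "min_window", "max_window"):
            w = getattr(self, name)
            if w % 2 == 0 or w < 1:
                raise ValueError(f"{name} must be odd and positive, got {w}")
        if not (self.min_window <= self.base_window <= self.max_window):
            raise ValueError("require min_window <= base_window <= max_window")

    def realized(self, ratio: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-frame (window, degree) for depth ratios z/z0 (auditable)."""
        ratio = np.asarray(ratio, dtype=float)
        scaled = np.array([self.distance_scaling(r) for r in ratio])
        windows = np.clip(
            [_nearest_odd(self.base_window * s) for s in scaled],
            self.min_window,
            self.max_window,
        ).astype(int)
        degrees = np.array([int(self.degree_rule(r)) for r in ratio])
        if np.any(degrees >= windows):
            raise ValueError("realized degree must be smaller than realized window")
        if np.any(degrees < 0):
            raise ValueError("degree must be >= 0")
        return windows, degrees


def realized_windows(ratio: np.ndarray, policy: SmoothingPolicy) -> tuple[np.ndarray, np.ndarray]:
    """Convenience alias for :meth:`SmoothingPolicy.realized` (for audit logs)."""
    return policy.realized(ratio)


def savgol_coefficients(window: int, degree: int) -> np.ndarray:
    """Convolution weights c_j, j = -m..m, for centre-point evaluation.

    Obtained by least-squares polynomial fitting on the integer stencil;
    the weights sum to 1.  ``window`` must be odd and exceed ``degree``.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be odd and positive, got {window}")
    if not (0 <= degree < window):
        raise ValueError(f"require 0 <= degree < window, got degree={degree}, window={window}")
    return savgol_coeffs(window, degree, use="dot")


def _interp_nan_columns(y: np.ndarray) -> np.ndarray:
    """Fill NaN runs per column by linear interpolation (edge NaNs held at ends)."""
    out = y.copy()
    n = y.shape[0]
    idx = np.arange(n)
    for c in range(y.shape[1]):
        col = out[:, c]
        good = np.isfinite(col)
        if good.all() or not good.any():
            continue
        out[:, c] = np.interp(idx, idx[good], col[good])
    return out


def _smooth_columns(y: np.ndarray, windows: np.ndarray, degrees: np.ndarray) -> np.ndarray:
    """Apply the per-frame (window, degree) filter to each column of y (n, k)."""
    n = y.shape[0]
    half = np.minimum(np.arange(n), n - 1 - np.arange(n))  # max symmetric half-width
    w_eff = np.minimum(windows, 2 * half + 1)
    d_eff = np.minimum(degrees, w_eff - 1)
    filled = _interp_nan_columns(y)
    out = np.empty_like(filled)
    interior = w_eff == windows
    # interior frames, grouped by (window, degree): one vectorized pass each
    for m in np.unique(windows[interior]):
        for d in np.unique(degrees[interior & (windows == m)]):
            rows = interior & (windows == m) & (degrees == d)
            if m == 1:
                out[rows] = filled[rows]
                continue
            sm = savgol_filter(filled, int(m), int(d), axis=0, mode="interp")
            out[rows] = sm[rows]
    # edge frames: direct weighted sum with the shrunken window
    for i in np.flatnonzero(~interior):
        m, d = int(w_eff[i]), int(d_eff[i])
        if m == 1:
            out[i] = filled[i]
            continue
        c = savgol_coefficients(m, d)
        h = (m - 1) // 2
        out[i] = c @ filled[i - h : i + h + 1]
    # columns that were entirely NaN stay NaN
    all_nan = ~np.isfinite(y).any(axis=0)
    out[:, all_nan] = np.nan
    return out


def smooth_series(
    track: WorldTrack | CameraTrack | KeypointSeries,
    depth: DepthTrack,
    policy: SmoothingPolicy | None = None,
):
    """Smooth every coordinate signal of *track* with the adaptive filter.

    Accepts a world track (X, Y, Z), a camera track (x', y') or a raw pixel
    series; returns the same type.  Quality (and the missing mask) is carried
    through unchanged — missing samples are bridged by linear interpolation
    for filtering stability but remain flagged.
    """
    policy = policy or SmoothingPolicy()
    n = track.n_frames
    if n < policy.min_window:
        raise ValueError(
            f"series length {n} shorter than min_window {policy.min_window}"
        )
    if depth.n_frames != n:
        raise ValueError(f"depth covers {depth.n_frames} frames, track has {n}")
    ratio = depth.per_frame() / depth.z0
    windows, degrees = policy.realized(ratio)

    if isinstance(track, WorldTrack):
        return WorldTrack(
            t=track.t.copy(),
            X=_smooth_columns(track.X, windows, degrees),
            Y=_smooth_columns(track.Y, windows, degrees),
            Z=_smooth_columns(track.Z, windows, degrees),
            quality=track.quality.copy(),
            convention=track.convention,
            nominal_fps=track.nominal_fps,
        )
    if isinstance(track, CameraTrack):
        return CameraTrack(
            t=track.t.copy(),
            x=_smooth_columns(track.x, windows, degrees),
            y=_smooth_columns(track.y, windows, degrees),
            quality=track.quality.copy(),
            nominal_fps=track.nominal_fps,
        )
    if isinstance(track, KeypointSeries):
        out = track.copy()
        out.xy[:, :, 0] = _smooth_columns(track.xy[:, :, 0], windows, degrees)
        out.xy[:, :, 1] = _smooth_columns(track.xy[:, :, 1], windows, degrees)
        out.xy[out.quality == 0] = np.nan  # keep the missing sentinel
        return out
    raise TypeError(f"cannot smooth object of type {type(track).__name__}")
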