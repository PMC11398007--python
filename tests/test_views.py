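"""Coordinate views: camera normalization, world conventions, walkway axis."""

import numpy as np
import pytest

import gaitlab as gl
from gaitlab.views import (
    AlignmentError,
    CameraIntrinsics,
    DepthTrack,
    from_camera_view,
    load_sidecar,
    project_to_walkway_axis,
    save_sidecar,
    to_camera_view,
    to_world_view,
)
from gaitlab.walkway import DegenerateWalkwayError, WalkwayDefinition


def _series_at(x, y, n=2):
    t = np.arange(n) / 60.0
    xy = np.empty((n, 25, 2))
    xy[..., 0] = x
    xy[..., 1] = y
    return gl.KeypointSeries(t, xy, np.full((n, 25), 0.9))


def test_principal_point_maps_to_origin():
    cam = CameraIntrinsics(fx=800, fy=800, cx=640, cy=360)
    track = to_camera_view(_series_at(640.0, 360.0), cam)
    np.testing.assert_allclose(track.x, 0.0)
    np.testing.assert_allclose(track.y, 0.0)


def test_normalization_hand_value():
    cam = CameraIntrinsics(fx=800, fy=800, cx=640, cy=360)
    track = to_camera_view(_series_at(960.0, 360.0), cam)
    np.testing.assert_allclose(track.x, 0.4)  # (960 - 640) / 800


def test_nonpositive_focal_length_rejected():
    with pytest.raises(ValueError):
        CameraIntrinsics(fx=0, fy=800, cx=0, cy=0)
    with pytest.raises(ValueError):
        CameraIntrinsics(fx=800, fy=-1, cx=0, cy=0)


def test_camera_view_inversion_recovers_pixels(noisy_walk):
    cam = noisy_walk.spec.camera
    series = noisy_walk.series
    back = from_camera_view(to_camera_view(series, cam), cam)
    assert np.nanmax(np.abs(back.xy - series.xy)) < 1e-9


def test_world_view_at_reference_depth_equals_camera_view():
    cam = CameraIntrinsics(fx=800, fy=800, cx=640, cy=360)
    series = _series_at(960.0, 260.0, n=3)
    track = to_camera_view(series, cam)
    depth = DepthTrack(np.full(3, 2.5), z0=2.5)
    for conv in ("pinhole", "as_printed"):
        world = to_world_view(track, depth, conv)
        np.testing.assert_allclose(world.X, track.x, atol=1e-12)
        np.testing.assert_allclose(world.Y, track.y, atol=1e-12)
        np.testing.assert_allclose(world.Z, 1.0)


def test_world_conventions_hand_values_and_ratio():
    cam = CameraIntrinsics(fx=800, fy=800, cx=640, cy=360)
    track = to_camera_view(_series_at(960.0, 360.0), cam)  # x' = 0.4
    z0 = 1.5
    depth = DepthTrack(np.full(2, 2 * z0), z0=z0)  # z = 2 z0
    printed = to_world_view(track, depth, "as_printed")
    pinhole = to_world_view(track, depth, "pinhole")
    np.testing.assert_allclose(printed.X, 0.2)
    np.testing.assert_allclose(pinhole.X, 0.8)
    np.testing.assert_allclose(printed.Z, 2.0)
    np.testing.assert_allclose(pinhole.Z, 2.0)
    # lateral coordinates differ by exactly (z0/z)^2
    np.testing.assert_allclose(printed.X / pinhole.X, (z0 / (2 * z0)) ** 2)


def test_depth_track_alignment_and_positivity():
    cam = CameraIntrinsics(fx=800, fy=800, cx=640, cy=360)
    track = to_camera_view(_series_at(1.0, 2.0, n=4), cam)
    with pytest.raises(AlignmentError):
        to_world_view(track, DepthTrack(np.full(3, 2.0), z0=2.0))
    with pytest.raises(ValueError):
        DepthTrack(np.array([1.0, -0.5]), z0=2.0)


def test_walkway_progression_anchored_and_linear(clean_walk):
    """Noise-free constant-speed walker: progression slope equals true speed."""
    w = clean_walk
    cam_track = to_camera_view(w.series, w.spec.camera)
    world = to_world_view(cam_track, w.depth, "pinhole")
    prog = project_to_walkway_axis(world, w.walkway, "mid_hip")
    # standing phase: exactly start_offset before the start line
    np.testing.assert_allclose(prog[0], -w.spec.start_offset, atol=1e-9)
    # steady-state slope = speed
    sel = (prog > 0.5) & (prog < 3.5)
    slope = np.polyfit(world.t[sel], prog[sel], 1)[0]
    np.testing.assert_allclose(slope, w.truth.speed, atol=1e-6)


def test_reversed_walkway_flips_progression_sign(clean_walk):
    w = clean_walk
    world = to_world_view(to_camera_view(w.series, w.spec.camera), w.depth)
    fwd = project_to_walkway_axis(world, w.walkway)
    reverse = WalkwayDefinition(
        start=w.walkway.end, end=w.walkway.start, length=w.walkway.length,
        scale=w.walkway.scale, up=w.walkway.up,
    )
    back = project_to_walkway_axis(world, reverse)
    np.testing.assert_allclose(back, w.walkway.length - fwd, atol=1e-9)
    moving = np.diff(fwd) > 1e-6
    assert (np.diff(back)[moving] < 0).all()


def test_walkway_projection_rotation_equivariance(rng):
    """Rigidly rotating track and walkway together leaves progression unchanged."""
    n = 50
    t = np.arange(n) / 60.0
    pos = rng.normal(size=(n, 25, 3))
    world = gl.WorldTrack(t, pos[..., 0], pos[..., 1], pos[..., 2] + 5.0, np.full((n, 25), 0.9))
    walkway = WalkwayDefinition(start=np.array([0, 1.0, 6.0]), end=np.array([0, 1.0, 2.0]), scale=1.0)
    # random rotation matrix via QR
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    p_rot = np.einsum("ij,nkj->nki", q, pos + np.array([0, 0, 5.0]))
    world_rot = gl.WorldTrack(t, p_rot[..., 0], p_rot[..., 1], p_rot[..., 2], world.quality)
    walkway_rot = WalkwayDefinition(
        start=q @ walkway.start, end=q @ walkway.end, scale=1.0, up=q @ walkway.up
    )
    np.testing.assert_allclose(
        project_to_walkway_axis(world_rot, walkway_rot),
        project_to_walkway_axis(world, walkway),
        atol=1e-9,
    )


def test_degenerate_walkway_rejected():
    with pytest.raises(DegenerateWalkwayError):
        WalkwayDefinition(start=np.zeros(3), end=np.zeros(3))


def test_sidecar_round_trip(tmp_path, clean_walk):
    w = clean_walk
    p = tmp_path / "sidecar.json"
    save_sidecar(str(p), w.spec.camera, w.depth, w.walkway)
    cam, depth, walkway = load_sidecar(str(p))
    assert cam == w.spec.camera
    np.testing.assert_allclose(depth.z, w.depth.z)
    assert depth.z0 == w.depth.z0
    np.testing.assert_allclose(walkway.start, w.walkway.start)
    assert walkway.scale == w.walkway.scale
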