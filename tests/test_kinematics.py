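"""Joint angles: closed forms, invariances, trace masking, base of support."""

import numpy as np
import pytest

import gaitlab as gl
from gaitlab.events import GaitPhase, Phase, Side
from gaitlab.kinematics import (
    DEFAULT_ANGLE_DEFINITIONS,
    AngleDefinition,
    DegenerateGeometryError,
    angle_traces,
    base_of_support,
    joint_angle,
)


@pytest.mark.parametrize(
    "a,b,c,expected",
    [
        ((1, 0), (0, 0), (0, 1), 90.0),
        ((-1, 0), (0, 0), (1, 0), 180.0),
        ((1, 0), (0, 0), (1, 1), 45.0),
        ((2, 0), (0, 0), (2, 2), 45.0),  # scale of c does not matter
        ((1, 0, 0), (0, 0, 0), (0, 0, 1), 90.0),  # 3-D points
    ],
)
def test_closed_form_angles(a, b, c, expected):
    assert joint_angle(a, b, c) == pytest.approx(expected, abs=1e-9)


def test_degenerate_vertex_rejected():
    with pytest.raises(DegenerateGeometryError):
        joint_angle((0, 0), (0, 0), (1, 1))
    with pytest.raises(DegenerateGeometryError):
        joint_angle((1, 1), (1, 1 + 1e-12), (2, 0))


def test_symmetry_and_similarity_invariance(rng):
    """theta(a,b,c) == theta(c,b,a), and is invariant under rotation,
    translation and uniform scaling — 1000 random triples."""
    for _ in range(1000):
        a, b, c = rng.normal(size=(3, 2)) * rng.uniform(0.1, 10)
        if min(np.linalg.norm(a - b), np.linalg.norm(c - b)) < 1e-6:
            continue
        theta = joint_angle(a, b, c)
        assert 0.0 <= theta <= 180.0
        assert joint_angle(c, b, a) == pytest.approx(theta, abs=1e-9)
        phi = rng.uniform(0, 2 * np.pi)
        R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        shift = rng.normal(size=2) * 5
        s = rng.uniform(0.2, 5.0)
        ta, tb, tc = (s * (R @ p) + shift for p in (a, b, c))
        assert joint_angle(ta, tb, tc) == pytest.approx(theta, abs=1e-7)


def test_clamping_makes_arccos_total():
    # numerically collinear points can push |cos| epsilon above 1
    a, b, c = (1e8, 1e8), (0.0, 0.0), (3e8, 3e8)
    assert joint_angle(a, b, c) == pytest.approx(0.0, abs=1e-6)


def test_angle_definition_validation():
    with pytest.raises(ValueError):
        AngleDefinition("bad", "left_knee", "left_knee", "left_ankle")
    with pytest.raises(KeyError):
        AngleDefinition("bad", "left_patella", "left_knee", "left_ankle")


def test_straight_leg_walker_knee_is_180():
    n = 20
    t = np.arange(n) / 60.0
    X = np.zeros((n, 25))
    Y = np.zeros((n, 25))
    Z = np.zeros((n, 25))
    idx = gl.keypoints.JOINT_INDEX
    Y[:, idx["left_hip"]] = 0.0
    Y[:, idx["left_knee"]] = 0.5
    Y[:, idx["left_ankle"]] = 1.0  # collinear down the Y axis
    world = gl.WorldTrack(t, X, Y, Z, np.full((n, 25), 0.9))
    (trace,) = angle_traces(world, [AngleDefinition("left_knee", "left_hip", "left_knee", "left_ankle")])
    assert trace.valid.all()
    np.testing.assert_allclose(trace.theta, 180.0, atol=1e-6)


def test_simulated_knee_flexion_recovered_within_1_degree(clean_walk):
    """Pipeline knee-angle trace vs the analytic model's trace, noise-free."""
    w = clean_walk
    world = gl.to_world_view(gl.to_camera_view(w.series, w.spec.camera), w.depth)
    smoothed = gl.smooth_series(world, w.depth)
    traces = {tr.name: tr for tr in angle_traces(smoothed, DEFAULT_ANGLE_DEFINITIONS)}
    sel = (w.truth.t >= w.truth.t_cross_start) & (w.truth.t <= w.truth.t_cross_end)
    for side in ("left", "right"):
        est = traces[f"{side}_knee"].theta[sel]
        true = w.truth.knee_angle[side][sel]
        # peak flexion (minimum included angle) within 1 degree
        assert abs(est.min() - true.min()) < 1.0
        # pointwise agreement away from the full-extension kinks, where the
        # smoother necessarily rounds the corner
        assert np.nanmedian(np.abs(est - true)) < 1.0


def test_missing_joint_masks_trace(small_series):
    s = small_series  # frame 2, joint 10 (left_knee) missing
    world = gl.WorldTrack(
        s.t, s.xy[..., 0], s.xy[..., 1], np.ones_like(s.quality), s.quality
    )
    (trace,) = angle_traces(world, [AngleDefinition("left_knee", "left_hip", "left_knee", "left_ankle")])
    assert not trace.valid[2]
    assert np.isnan(trace.theta[2])
    assert trace.valid[[0, 1, 3, 4, 5]].all()


def _world_with_ankles(n, left_x, right_x):
    t = np.arange(n) / 60.0
    X = np.zeros((n, 25))
    idx = gl.keypoints.JOINT_INDEX
    X[:, idx["left_ankle"]] = left_x
    X[:, idx["right_ankle"]] = right_x
    Y = np.full((n, 25), 0.5)
    Z = np.tile(np.linspace(5, 4, n)[:, None], (1, 25))
    return gl.WorldTrack(t, X, Y, Z, np.full((n, 25), 0.9))


def _walkway(scale=1.0):
    return gl.WalkwayDefinition(
        start=np.array([0, 0.5, 6.0]), end=np.array([0, 0.5, 2.0]),
        length=4.0 * scale, scale=scale, up=np.array([0.0, -1.0, 0.0]),
    )


def test_base_of_support_symmetric_offset():
    world = _world_with_ankles(30, +0.1, -0.1)
    phases = [
        GaitPhase(Side.LEFT, Phase.STANCE, 0.0, 0.5),
        GaitPhase(Side.RIGHT, Phase.STANCE, 0.0, 0.5),
    ]
    assert base_of_support(world, phases, _walkway()) == pytest.approx(0.2, abs=1e-9)


def test_base_of_support_undefined_without_double_support():
    world = _world_with_ankles(30, 0.1, -0.1)
    phases = [
        GaitPhase(Side.LEFT, Phase.STANCE, 0.0, 0.2),
        GaitPhase(Side.RIGHT, Phase.SWING, 0.0, 0.2),
    ]
    with pytest.warns(UserWarning, match="double-support"):
        assert np.isnan(base_of_support(world, phases, _walkway()))


def test_step_width_recovered_under_noise(noisy_walk, clean_result):
    """sigma = 2 px: estimated base of support within 2 cm of true step width."""
    w = noisy_walk
    res = gl.analyze_walk(w.series, w.spec.camera, w.depth, w.walkway)
    assert res.metrics.base_of_support == pytest.approx(w.truth.step_width, abs=0.02)
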