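"""Trough detection, gait events, and stance/swing segmentation."""

import warnings

import numpy as np
import pytest

import gaitlab as gl
from gaitlab.events import (
    EventType,
    GaitEvent,
    Phase,
    Side,
    TroughPolicy,
    detect_events,
    detect_troughs,
    segment_phases,
)
from gaitlab.simulate import match_events


def brute_force_local_minima(signal, window):
    """Oracle: all strict local minima of the centred moving average."""
    n = len(signal)
    half = (window - 1) // 2
    sm = np.array(
        [
            np.mean(signal[max(0, i - min(half, i, n - 1 - i)) : i + min(half, i, n - 1 - i) + 1])
            for i in range(n)
        ]
    )
    return [i for i in range(1, n - 1) if sm[i] < sm[i - 1] and sm[i] < sm[i + 1]], sm


def test_sine_troughs_at_analytic_minima():
    t = np.arange(0, 3, 1 / 60.0)
    y = np.sin(2 * np.pi * t)
    troughs = detect_troughs(y, TroughPolicy(), dt=1 / 60.0)
    assert len(troughs) == 3
    for found, expected in zip(troughs, (0.75, 1.75, 2.75)):
        assert abs(t[found] - expected) <= 1 / 60.0 + 1e-9


def test_constant_signal_has_no_troughs():
    assert detect_troughs(np.full(100, 2.5)) == []


def test_noisy_sine_troughs_within_two_frames(rng):
    t = np.arange(0, 3, 1 / 60.0)
    y = np.sin(2 * np.pi * t) + rng.normal(0, 0.05, t.size)
    troughs = detect_troughs(y, TroughPolicy(), dt=1 / 60.0)
    assert len(troughs) == 3
    for found, expected in zip(troughs, (0.75, 1.75, 2.75)):
        assert abs(t[found] - expected) <= 2 / 60.0 + 1e-9


def test_reflection_duality_against_brute_force(rng):
    """Troughs of -f are peaks of f; both agree with an exhaustive scan once
    prominence and separation filters are neutralized."""
    y = np.cumsum(rng.normal(size=200))
    y = y - np.linspace(y[0], y[-1], 200)  # bridge: several interior extrema
    policy = TroughPolicy(local_mean_window=5, min_separation=1e-9, prominence_fraction=1e-9)
    oracle_minima, sm = brute_force_local_minima(-y, 5)
    assert detect_troughs(-y, policy, dt=1.0) == oracle_minima
    assert detect_troughs(-y, policy, dt=1.0) == detect_troughs(-(-(-y)), policy, dt=1.0)


def test_shift_and_offset_invariance():
    t = np.arange(0, 4, 1 / 60.0)
    y = np.sin(2 * np.pi * 0.9 * t)
    base = detect_troughs(y, dt=1 / 60.0)
    assert detect_troughs(y + 42.0, dt=1 / 60.0) == base


def test_min_separation_keeps_deeper_trough():
    y = np.zeros(200)
    y[50] = -1.0  # shallower
    y[60] = -2.0  # deeper, 10 frames away
    y = np.convolve(y, np.ones(3) / 3, mode="same")
    policy = TroughPolicy(local_mean_window=1, min_separation=20.0, prominence_fraction=0.1)
    assert detect_troughs(y, policy, dt=1.0) == [60]


def test_events_on_noise_free_walk_within_one_frame(clean_walk, clean_result):
    w, res = clean_walk, clean_result
    dt = 1.0 / w.spec.fps
    window = (w.truth.t_cross_start, w.truth.t_cross_end)
    for et in EventType:
        for side in ("left", "right"):
            truth = w.truth.events[(et.value, side)]
            det = [e.t for e in res.events if e.type is et and e.side.value == side]
            tp, fp, fn = match_events(truth, det, tol=1.0 * dt + 1e-9, window=window)
            assert fp == 0 and fn == 0, f"{et.value}/{side}: fp={fp} fn={fn}"
            assert tp == len([x for x in truth if window[0] <= x <= window[1]])


def test_event_streams_strictly_ordered(clean_result):
    for et in EventType:
        for side in (Side.LEFT, Side.RIGHT):
            ts = [e.t for e in clean_result.events if e.type is et and e.side is side]
            assert all(b > a for a, b in zip(ts, ts[1:]))


def test_standing_still_produces_no_events(clean_walk):
    w = clean_walk
    n = 120
    series = gl.KeypointSeries(
        w.series.t[:n].copy(), np.tile(w.series.xy[0], (n, 1, 1)), w.series.quality[:n].copy()
    )
    depth = gl.DepthTrack(np.tile(w.depth.z[0], (n, 1)), w.depth.z0)
    world = gl.to_world_view(gl.to_camera_view(series, w.spec.camera), depth)
    smoothed = gl.smooth_series(world, depth)
    assert detect_events(smoothed, w.walkway) == []


def test_missing_required_joint_raises(clean_walk):
    w = clean_walk
    world = gl.to_world_view(gl.to_camera_view(w.series, w.spec.camera), w.depth)
    world.quality[:, gl.keypoints.JOINT_INDEX["left_heel"]] = 0.0
    with pytest.raises(gl.events.InsufficientDataError, match="left_heel"):
        detect_events(world, w.walkway)


def test_segment_phases_definition():
    ev = [
        GaitEvent(1.0, EventType.HEEL_STRIKE, Side.LEFT, 60),
        GaitEvent(1.6, EventType.TOE_OFF, Side.LEFT, 96),
        GaitEvent(2.1, EventType.HEEL_STRIKE, Side.LEFT, 126),
    ]
    phases = segment_phases(ev)
    assert phases == [
        gl.GaitPhase(Side.LEFT, Phase.STANCE, 1.0, 1.6),
        gl.GaitPhase(Side.LEFT, Phase.SWING, 1.6, 2.1),
    ]


def test_single_heel_strike_yields_no_phases():
    assert segment_phases([GaitEvent(1.0, EventType.HEEL_STRIKE, Side.LEFT, 60)]) == []


def test_consecutive_same_type_warns_and_skips():
    ev = [
        GaitEvent(1.0, EventType.HEEL_STRIKE, Side.LEFT, 60),
        GaitEvent(1.5, EventType.HEEL_STRIKE, Side.LEFT, 90),
        GaitEvent(2.0, EventType.TOE_OFF, Side.LEFT, 120),
    ]
    with pytest.warns(UserWarning, match="consecutive"):
        phases = segment_phases(ev)
    assert phases == [gl.GaitPhase(Side.LEFT, Phase.STANCE, 1.5, 2.0)]


def test_phases_tile_without_overlap(clean_result):
    for side in (Side.LEFT, Side.RIGHT):
        seq = [p for p in clean_result.phases if p.side is side]
        for a, b in zip(seq, seq[1:]):
            assert b.start_t == pytest.approx(a.end_t, abs=1e-9)
            assert a.phase is not b.phase  # alternation


def test_stance_fraction_recovered_within_3_points(clean_walk, clean_result):
    w = clean_walk
    durations = {Phase.STANCE: 0.0, Phase.SWING: 0.0}
    for p in clean_result.phases:
        mid = 0.5 * (p.start_t + p.end_t)
        if w.truth.t_cross_start <= mid <= w.truth.t_cross_end:
            durations[p.phase] += p.end_t - p.start_t
    frac = durations[Phase.STANCE] / (durations[Phase.STANCE] + durations[Phase.SWING])
    assert abs(frac - w.truth.stance_fraction) < 0.03


def test_trough_policy_validation():
    with pytest.raises(ValueError):
        TroughPolicy(min_separation=0.0)
    with pytest.raises(ValueError):
        TroughPolicy(prominence_fraction=1.5)
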