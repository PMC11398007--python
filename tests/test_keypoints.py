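"""Keypoint data model: skeleton vocabulary, dialects, gap filling."""

import json

import numpy as np
import pytest

import gaitlab as gl
from gaitlab.keypoints import (
    JOINT_INDEX,
    N_JOINTS,
    SKELETON,
    FormatError,
    ValidationError,
    fill_missing,
    read_keypoint_series,
    write_keypoint_series,
)


def test_skeleton_is_a_25_name_bijection():
    assert len(SKELETON) == 25
    assert len(set(SKELETON)) == 25
    assert all(JOINT_INDEX[name] == i for i, name in enumerate(SKELETON))
    with pytest.raises(ValidationError):
        gl.JointId(3, "left_knee")  # name does not match id 3


def test_two_frame_jsonl_fixture_counts(tmp_path):
    rows = []
    for t in (0.0, 1 / 60):
        kp = [[name, 10.0 * i, 20.0 * i, 0.9] for i, name in enumerate(SKELETON)]
        rows.append(json.dumps({"t": t, "kp": kp}))
    p = tmp_path / "two.jsonl"
    p.write_text("\n".join(rows) + "\n")
    s = read_keypoint_series(str(p), "jsonl")
    assert s.n_frames == 2
    assert s.xy.shape == (2, 25, 2)
    assert sum(len(f.keypoints) for f in s) == 50


def test_non_monotone_timestamps_rejected(tmp_path, small_series):
    bad_t = small_series.t.copy()
    bad_t[2] = bad_t[1] - 1e-4
    with pytest.raises(ValidationError, match="increasing"):
        gl.KeypointSeries(bad_t, small_series.xy, small_series.quality)


def test_unknown_joint_name_rejected_with_line_number(tmp_path):
    kp = [[name, 1.0, 2.0, 0.9] for name in SKELETON]
    kp[0][0] = "left_flipper"
    p = tmp_path / "bad.jsonl"
    p.write_text(json.dumps({"t": 0.0, "kp": kp}) + "\n")
    with pytest.raises(ValidationError, match="left_flipper"):
        read_keypoint_series(str(p), "jsonl")


def test_malformed_jsonl_row_reports_line(tmp_path):
    good = json.dumps(
        {"t": 0.0, "kp": [[n, 1.0, 2.0, 0.9] for n in SKELETON]}
    )
    p = tmp_path / "mixed.jsonl"
    p.write_text(good + "\nnot json at all\n")
    with pytest.raises(FormatError, match=":2"):
        read_keypoint_series(str(p), "jsonl")


def test_csv_missing_column_is_format_error(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("t,joint,x,y\n0.0,head,1,2\n")
    with pytest.raises(FormatError, match="quality"):
        read_keypoint_series(str(p), "csv")


@pytest.mark.parametrize("dialect", ["jsonl", "csv"])
def test_round_trip_identity(tmp_path, dialect, noisy_walk):
    series = noisy_walk.series
    p = tmp_path / f"walk.{dialect}"
    write_keypoint_series(series, str(p), dialect)
    back = read_keypoint_series(str(p), dialect, nominal_fps=series.nominal_fps)
    assert back.n_frames == series.n_frames
    np.testing.assert_allclose(back.t, series.t, atol=1e-9)
    np.testing.assert_allclose(back.quality, series.quality, atol=1e-9)
    finite = np.isfinite(series.xy)
    np.testing.assert_array_equal(np.isfinite(back.xy), finite)
    assert np.nanmax(np.abs(back.xy - series.xy)) <= 1e-6


@pytest.mark.parametrize("dialect", ["jsonl", "csv"])
def test_empty_series_round_trip(tmp_path, dialect):
    empty = gl.KeypointSeries(
        np.empty(0), np.empty((0, N_JOINTS, 2)), np.empty((0, N_JOINTS))
    )
    p = tmp_path / f"empty.{dialect}"
    write_keypoint_series(empty, str(p), dialect)
    back = read_keypoint_series(str(p), dialect)
    assert back.n_frames == 0


def test_missing_sentinel_preserved_round_trip(tmp_path, small_series):
    p = tmp_path / "m.jsonl"
    write_keypoint_series(small_series, str(p), "jsonl")
    back = read_keypoint_series(str(p), "jsonl")
    assert back.quality[2, 10] == 0.0
    assert not np.isfinite(back.xy[2, 10]).any()
    # missingness is encoded in-band: all 25 joints still present per frame
    assert back.xy.shape[1] == N_JOINTS


def test_fill_missing_linear_interpolation():
    n = 6
    t = np.arange(n) / 60.0
    xy = np.tile(np.array([10.0, 100.0]), (n, 25, 1))
    xy[:, 0, 0] = [10, 10, np.nan, np.nan, 16, 16]
    q = np.full((n, 25), 0.8)
    q[2, 0] = q[3, 0] = 0.0
    s = gl.KeypointSeries(t, xy, q)
    out = fill_missing(s, max_gap_frames=2)
    np.testing.assert_allclose(out.xy[2, 0, 0], 12.0)
    np.testing.assert_allclose(out.xy[3, 0, 0], 14.0)
    assert out.interpolated[2, 0] and out.interpolated[3, 0]
    assert out.quality[2, 0] > 0


def test_fill_missing_respects_gap_threshold():
    n = 8
    t = np.arange(n) / 60.0
    xy = np.full((n, 25, 2), 5.0)
    q = np.full((n, 25), 0.8)
    for i in (2, 3, 4):  # 3-frame gap
        q[i, 1] = 0.0
        xy[i, 1] = np.nan
    s = gl.KeypointSeries(t, xy, q)
    out = fill_missing(s, max_gap_frames=2)
    assert (out.quality[2:5, 1] == 0).all()
    assert not np.isfinite(out.xy[2:5, 1]).any()
    out2 = fill_missing(s, max_gap_frames=3)
    assert (out2.quality[2:5, 1] > 0).all()


def test_fill_missing_never_alters_valid_keypoints(noisy_walk):
    s = noisy_walk.series
    out = fill_missing(s, max_gap_frames=3)
    valid = s.quality > 0
    np.testing.assert_array_equal(out.xy[valid], s.xy[valid])
    np.testing.assert_array_equal(out.quality[valid], s.quality[valid])


def test_fill_missing_identity_when_complete(small_series):
    s = small_series.copy()
    s.quality[:] = 0.9
    s.xy[2, 10] = (1.0, 2.0)
    out = fill_missing(s, max_gap_frames=3)
    np.testing.assert_array_equal(out.xy, s.xy)
    np.testing.assert_array_equal(out.quality, s.quality)


def test_irregular_frame_interval_attaches_warning():
    t = np.array([0.0, 0.05, 0.10])  # 20 fps vs nominal 60
    s = gl.KeypointSeries(t, np.full((3, 25, 2), 1.0), np.full((3, 25), 0.5))
    assert any("deviates" in w for w in s.warnings)
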