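"""End-to-end orchestration: read -> fill gaps -> camera view -> world view ->
smoothing -> events -> phases -> metrics -> report.

The pipeline is deterministic given (input, config, seed); every result
bundle embeds the config hash and package version for audit.  Stages of the
production service that are pure infrastructure (video upload, encryption,
anonymization, original-video deletion, user notification) appear only as
no-op stage names in the structured log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .events import EventConfig, GaitEvent, GaitPhase, TroughPolicy, detect_events, segment_phases
from .keypoints import KeypointSeries, fill_missing, read_keypoint_series, write_keypoint_series
from .kinematics import DEFAULT_ANGLE_DEFINITIONS, AngleDefinition, JointAngleTrace, angle_traces
from .metrics import GaitMetrics, compute_metrics
from .simulate import SimulatedWalk, WalkSpec, simulate_cohort, simulate_walk
from .smoothing import SmoothingPolicy, smooth_series
from .stats import PairedMeasurements, bland_altman, pearson_r, percent_variance, spearman_rho
from .views import load_sidecar, save_sidecar, to_camera_view, to_world_view
from .walkway import WalkwayDefinition

__all__ = [
    "PipelineConfig",
    "AnalysisResult",
    "analyze_walk",
    "run_analyze",
    "run_simulate",
    "run_validate",
    "validate_walks",
]

_NOOP_STAGES = (
    "video_upload",
    "encryption",
    "face_anonymization",
    "original_video_deletion",
    "user_notification",
)


@dataclass
class PipelineConfig:
    """Serializable analysis configuration (YAML round-trippable)."""

    dialect: str = "jsonl"
    world_convention: str = "pinhole"
    max_gap_frames: int = 3
    base_window: int = 9
    min_window: int = 5
    max_window: int = 21
    degree: int = 3
    local_mean_window: int = 5
    min_separation: float = 0.4
    prominence_fraction: float = 0.2
    toe_off_signal: str = "relative_progression"
    heel_rise_velocity_floor: float = 0.05
    command_t: float | None = None
    seed: int = 0
    log_level: str = "INFO"
    angles: list[list[str]] = field(
        default_factory=lambda: [[d.name, d.a, d.b, d.c] for d in DEFAULT_ANGLE_DEFINITIONS]
    )

    def smoothing_policy(self) -> SmoothingPolicy:
        deg = int(self.degree)
        return SmoothingPolicy(
            base_window=self.base_window,
            min_window=self.min_window,
            max_window=self.max_window,
            degree_rule=lambda ratio, d=deg: d,
        )

    def event_config(self) -> EventConfig:
        return EventConfig(
            troughs=TroughPolicy(
                local_mean_window=self.local_mean_window,
                min_separation=self.min_separation,
                prominence_fraction=self.prominence_fraction,
            ),
            toe_off_signal=self.toe_off_signal,  # type: ignore[arg-type]
            heel_rise_velocity_floor=self.heel_rise_velocity_floor,
        )

    def angle_definitions(self) -> list[AngleDefinition]:
        return [AngleDefinition(*row) for row in self.angles]

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> str:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class AnalysisResult:
    metrics: GaitMetrics
    events: list[GaitEvent]
    phases: list[GaitPhase]
    angles: list[JointAngleTrace]
    log: list[dict[str, Any]]
    config_hash: str
    version: str = __version__

    def metrics_document(self) -> dict[str, Any]:
        return {
            "metrics": self.metrics.to_dict(),
            "config_hash": self.config_hash,
            "version": self.version,
        }


def _stage(log: list[dict], name: str, t0: float, caught: list, **params) -> None:
    log.append(
        {
            "stage": name,
            "params": params,
            "duration_s": round(time.perf_counter() - t0, 6),
            "warnings": [str(w.message) for w in caught],
        }
    )


def analyze_walk(
    series: KeypointSeries,
    cam,
    depth,
    walkway: WalkwayDefinition,
    config: PipelineConfig | None = None,
) -> AnalysisResult:
    """Run the full analysis pipeline on an in-memory walk."""
    config = config or PipelineConfig()
    log: list[dict[str, Any]] = []
    for name in _NOOP_STAGES[:2]:
        log.append({"stage": name, "params": {"noop": True}, "duration_s": 0.0, "warnings": []})

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        t0 = time.perf_counter()
        filled = fill_missing(series, config.max_gap_frames)
        _stage(log, "fill_missing", t0, caught, max_gap_frames=config.max_gap_frames)

    t0 = time.perf_counter()
    camera_track = to_camera_view(filled, cam)
    _stage(log, "camera_view", t0, [], fx=cam.fx, fy=cam.fy, cx=cam.cx, cy=cam.cy)

    t0 = time.perf_counter()
    world = to_world_view(camera_track, depth, config.world_convention)
    _stage(log, "world_view", t0, [], convention=config.world_convention, z0=depth.z0)

    t0 = time.perf_counter()
    policy = config.smoothing_policy()
    smoothed = smooth_series(world, depth, policy)
    _stage(
        log, "smoothing", t0, [],
        base_window=policy.base_window, min_window=policy.min_window,
        max_window=policy.max_window, degree=config.degree,
    )

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        t0 = time.perf_counter()
        events = detect_events(smoothed, walkway, config.event_config())
        _stage(log, "gait_events", t0, caught, n_events=len(events))

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        t0 = time.perf_counter()
        phases = segment_phases(events)
        _stage(log, "phase_segmentation", t0, caught, n_phases=len(phases))

    t0 = time.perf_counter()
    angles = angle_traces(smoothed, config.angle_definitions())
    _stage(log, "kinematics", t0, [], n_angles=len(angles))

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        t0 = time.perf_counter()
        metrics = compute_metrics(smoothed, events, phases, walkway, config.command_t)
        _stage(log, "gait_metrics", t0, caught, walkway_length=walkway.length)

    for name in _NOOP_STAGES[2:]:
        log.append({"stage": name, "params": {"noop": True}, "duration_s": 0.0, "warnings": []})

    return AnalysisResult(metrics, events, phases, angles, log, config.hash())


def _events_frame(events: list[GaitEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"type": e.type.value, "side": e.side.value, "frame": e.frame, "t": e.t} for e in events]
    )


def _angles_frame(angles: list[JointAngleTrace]) -> pd.DataFrame:
    cols: dict[str, Any] = {}
    if angles:
        cols["t"] = angles[0].t
        for tr in angles:
            cols[tr.name] = np.where(tr.valid, tr.theta, np.nan)
    return pd.DataFrame(cols)


def run_analyze(
    input_path: str,
    sidecar_path: str,
    out_dir: str,
    config: PipelineConfig | None = None,
) -> AnalysisResult:
    """File-level analyze: read keypoints + sidecar, write the result bundle."""
    config = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series = read_keypoint_series(input_path, config.dialect)  # type: ignore[arg-type]
    cam, depth, walkway = load_sidecar(sidecar_path)
    if walkway is None:
        raise ValueError(f"{sidecar_path}: no walkway definition in sidecar")
    result = analyze_walk(series, cam, depth, walkway, config)
    with open(out / "metrics.json", "w", encoding="utf-8") as fh:
        json.dump(result.metrics_document(), fh, sort_keys=True, indent=1)
    _events_frame(result.events).to_csv(out / "events.csv", index=False)
    _angles_frame(result.angles).to_csv(out / "angles.csv", index=False)
    with open(out / "log.json", "w", encoding="utf-8") as fh:
        json.dump(result.log, fh, sort_keys=True, indent=1)
    return result


def _truth_document(walk: SimulatedWalk) -> dict[str, Any]:
    tr = walk.truth
    return {
        "speed": tr.speed,
        "stride_length": tr.stride_length,
        "step_length": tr.step_length,
        "cadence": tr.cadence,
        "step_count": tr.step_count,
        "step_width": tr.step_width,
        "stance_fraction": tr.stance_fraction,
        "walk_time": tr.walk_time,
        "t_cross_start": tr.t_cross_start,
        "t_cross_end": tr.t_cross_end,
        "movement_onset": tr.movement_onset,
        "command_time": tr.command_time,
        "reaction_time": tr.reaction_time,
        "ignition_time": tr.ignition_time,
        "events": {f"{k[0]}:{k[1]}": v for k, v in tr.events.items()},
        "seed": walk.spec.seed,
    }


def run_simulate(
    out_dir: str,
    spec: WalkSpec | None = None,
    cohort: int | None = None,
    dialect: str = "jsonl",
    **cohort_kwargs,
) -> list[Path]:
    """Write one walk (or a cohort) as keypoint file + sidecar + truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cohort is None:
        walks = [simulate_walk(spec or WalkSpec())]
    else:
        walks = simulate_cohort(cohort, seed=(spec.seed if spec else 0), **cohort_kwargs)
    written = []
    manifest = []
    ext = "jsonl" if dialect == "jsonl" else "csv"
    for i, walk in enumerate(walks):
        stem = f"walk_{i:03d}"
        kp = out / f"{stem}.keypoints.{ext}"
        write_keypoint_series(walk.series, str(kp), dialect)  # type: ignore[arg-type]
        sc = out / f"{stem}.sidecar.json"
        save_sidecar(str(sc), walk.spec.camera, walk.depth, walk.walkway)
        truth = out / f"{stem}.truth.json"
        with open(truth, "w", encoding="utf-8") as fh:
            json.dump(_truth_document(walk), fh, sort_keys=True, indent=1)
        manifest.append({"keypoints": kp.name, "sidecar": sc.name, "truth": truth.name})
        written += [kp, sc, truth]
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump({"dialect": dialect, "walks": manifest}, fh, sort_keys=True, indent=1)
    return written


def validate_walks(
    walks: list[SimulatedWalk], config: PipelineConfig | None = None
) -> dict[str, Any]:
    """Analyze each walk and compare pipeline estimates with ground truth.

    Returns per-walk rows plus agreement tables (correlations, percent
    variance, Bland-Altman) for gait speed and stride length.  Walks whose
    analysis fails or yields missing metrics are excluded and counted.
    """
    config = config or PipelineConfig()
    rows = []
    failures = []
    for i, walk in enumerate(walks):
        label = f"walk_{i:03d}"
        try:
            res = analyze_walk(walk.series, walk.spec.camera, walk.depth, walk.walkway, config)
        except Exception as exc:  # noqa: BLE001 - robustness contract: list and continue
            failures.append({"label": label, "error": f"{type(exc).__name__}: {exc}"})
            continue
        m = res.metrics
        if m.gait_speed is None or m.stride_length is None:
            failures.append({"label": label, "error": "; ".join(m.warnings) or "missing metrics"})
            continue
        rows.append(
            {
                "label": label,
                "true_speed": walk.truth.speed,
                "est_speed": m.gait_speed,
                "true_stride": walk.truth.stride_length,
                "est_stride": m.stride_length,
                "true_step_count": walk.truth.step_count,
                "est_step_count": m.step_count,
            }
        )
    report: dict[str, Any] = {"rows": rows, "failures": failures, "n_analyzed": len(rows)}
    if len(rows) >= 2:
        df = pd.DataFrame(rows)
        for metric, ref_col, est_col in (
            ("gait_speed", "true_speed", "est_speed"),
            ("stride_length", "true_stride", "est_stride"),
        ):
            pairs = PairedMeasurements(
                metric, df[ref_col].to_numpy(), df[est_col].to_numpy(), list(df["label"])
            )
            rho, rho_p = spearman_rho(pairs)
            r, r_p = pearson_r(pairs)
            pv = percent_variance(pairs)
            bias, (lo, hi) = bland_altman(pairs)
            report[metric] = {
                "spearman_rho": rho,
                "spearman_p": rho_p,
                "pearson_r": r,
                "pearson_p": r_p,
                "percent_variance_max": pv.max,
                "percent_variance_mean": pv.mean,
                "bland_altman_bias": bias,
                "bland_altman_limits": [lo, hi],
            }
    return report


def run_validate(cohort_dir: str, out_dir: str, config: PipelineConfig | None = None) -> dict[str, Any]:
    """Directory-level validate: analyze every walk in a simulated cohort dir."""
    config = config or PipelineConfig()
    cohort = Path(cohort_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(cohort / "manifest.json", "r", encoding="utf-8") as fh:
        manifest = json.load(fh)
    rows = []
    failures = []
    for entry in manifest["walks"]:
        label = entry["keypoints"].split(".")[0]
        try:
            series = read_keypoint_series(str(cohort / entry["keypoints"]), manifest["dialect"])
            cam, depth, walkway = load_sidecar(str(cohort / entry["sidecar"]))
            with open(cohort / entry["truth"], "r", encoding="utf-8") as fh:
                truth = json.load(fh)
            res = analyze_walk(series, cam, depth, walkway, config)
            m = res.metrics
            if m.gait_speed is None or m.stride_length is None:
                raise ValueError("; ".join(m.warnings) or "missing metrics")
            rows.append(
                {
                    "label": label,
                    "true_speed": truth["speed"],
                    "est_speed": m.gait_speed,
                    "true_stride": truth["stride_length"],
                    "est_stride": m.stride_length,
                }
            )
        except Exception as exc:  # noqa: BLE001
            failures.append({"label": label, "error": f"{type(exc).__name__}: {exc}"})
    report: dict[str, Any] = {"rows": rows, "failures": failures, "n_analyzed": len(rows)}
    if len(rows) >= 2:
        df = pd.DataFrame(rows)
        for metric, ref_col, est_col in (
            ("gait_speed", "true_speed", "est_speed"),
            ("stride_length", "true_stride", "est_stride"),
        ):
            pairs = PairedMeasurements(metric, df[ref_col].to_numpy(), df[est_col].to_numpy())
            rho, rho_p = spearman_rho(pairs)
            r, r_p = pearson_r(pairs)
            pv = percent_variance(pairs)
            bias, (lo, hi) = bland_altman(pairs)
            report[metric] = {
                "spearman_rho": rho,
                "spearman_p": rho_p,
                "pearson_r": r,
                "pearson_p": r_p,
                "percent_variance_max": pv.max,
                "percent_variance_mean": pv.mean,
                "bland_altman_bias": bias,
                "bland_altman_limits": [lo, hi],
            }
        df.to_csv(out / "per_walk.csv", index=False)
    with open(out / "agreement.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, sort_keys=True, indent=1)
    return report
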