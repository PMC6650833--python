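"""Readers and writers for the pipeline's plain-text formats.

All tabular data are CSV with headers; manifests are YAML (JSON accepted,
being a YAML subset).  Column layouts:

* landmarks:   ``t, x0, y0, ..., x67, y67[, confidence]`` (``--one-based-index``
               inputs use ``x1..x68`` and are remapped on read)
* RGB trace:   ``t, mean_r, mean_g, mean_b``
* sensor HR:   ``t, bpm``
* self-reports: ``subject, level, rstress, rboredom``
* datasets:    feature columns + ``label, subject, source, window_start_s``
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import InvalidInputError, SchemaError
from .facial import LandmarkTrack, N_LANDMARKS
from .rppg import RGBTrace
from .segmentation import ManifestEntry, SessionManifest
from .simulate import SimCohort, SimSession

FLOAT_FMT = "%.6f"


def _landmark_columns(one_based: bool = False) -> list[str]:
    off = 1 if one_based else 0
    cols = ["t"]
    for i in range(N_LANDMARKS):
        cols += [f"x{i + off}", f"y{i + off}"]
    return cols


def read_landmarks(path: str | Path, one_based_index: bool = False) -> LandmarkTrack:
    """Read a landmark CSV into a track, inferring fps from the time column."""
    df = pd.read_csv(path)
    cols = _landmark_columns(one_based_index)
    missing = set(cols) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing landmark columns, e.g. {sorted(missing)[:4]}")
    t = df["t"].to_numpy(dtype=float)
    if len(t) < 2:
        raise SchemaError(f"{path}: need at least two frames to infer fps")
    dt = np.diff(t)
    if dt.min() <= 0 or np.ptp(dt) > 1e-6:
        raise SchemaError(f"{path}: frame times must be strictly increasing and uniform")
    fps = 1.0 / float(np.median(dt))
    xy = df[cols[1:]].to_numpy(dtype=float).reshape(len(df), N_LANDMARKS, 2)
    conf = df["confidence"].to_numpy(dtype=float) if "confidence" in df.columns else None
    return LandmarkTrack(fps=fps, points=xy, t0=float(t[0]), confidence=conf)


def write_landmarks(track: LandmarkTrack, path: str | Path) -> None:
    cols = _landmark_columns()
    data = np.column_stack([track.t, track.points.reshape(len(track), -1)])
    df = pd.DataFrame(data, columns=cols)
    if track.confidence is not None:
        df["confidence"] = track.confidence
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_rgb_trace(path: str | Path) -> RGBTrace:
    df = pd.read_csv(path)
    needed = ["t", "mean_r", "mean_g", "mean_b"]
    if set(needed) - set(df.columns):
        raise SchemaError(f"{path}: expected columns {needed}")
    t = df["t"].to_numpy(dtype=float)
    if len(t) < 2:
        raise SchemaError(f"{path}: need at least two samples to infer fps")
    dt = np.diff(t)
    if dt.min() <= 0 or np.ptp(dt) > 1e-6:
        raise SchemaError(f"{path}: sample times must be strictly increasing and uniform")
    return RGBTrace(
        fps=1.0 / float(np.median(dt)),
        rgb=df[needed[1:]].to_numpy(dtype=float),
        t0=float(t[0]),
    )


def write_rgb_trace(trace: RGBTrace, path: str | Path) -> None:
    df = pd.DataFrame(
        {"t": trace.t, "mean_r": trace.rgb[:, 0], "mean_g": trace.rgb[:, 1],
         "mean_b": trace.rgb[:, 2]}
    )
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_sensor_hr(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    if set(["t", "bpm"]) - set(df.columns):
        raise SchemaError(f"{path}: expected columns ['t', 'bpm']")
    return df["t"].to_numpy(dtype=float), df["bpm"].to_numpy(dtype=float)


def write_sensor_hr(t: np.ndarray, bpm: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"t": t, "bpm": bpm}).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_reports(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = ["subject", "level", "rstress", "rboredom"]
    if set(needed) - set(df.columns):
        raise SchemaError(f"{path}: expected columns {needed}")
    return df[needed].astype(int)


def write_reports(reports: pd.DataFrame, path: str | Path) -> None:
    reports.to_csv(path, index=False)


# ----------------------------------------------------------------- manifests

def manifest_to_dict(manifest: SessionManifest) -> dict:
    return {
        "subject": manifest.subject_id,
        "recordings": [
            {"kind": e.kind, "id": e.id, "start_s": e.start_s, "end_s": e.end_s,
             **({"excluded": True, "reason": e.reason} if e.excluded else {})}
            for e in manifest.entries
        ],
    }


def manifest_from_dict(data: dict) -> SessionManifest:
    try:
        entries = [
            ManifestEntry(
                kind=r["kind"], id=int(r["id"]), start_s=float(r["start_s"]),
                end_s=float(r["end_s"]), excluded=bool(r.get("excluded", False)),
                reason=str(r.get("reason", "")),
            )
            for r in data["recordings"]
        ]
        m = SessionManifest(subject_id=int(data["subject"]), entries=entries)
    except (KeyError, TypeError, ValueError) as exc:
        raise SchemaError(f"malformed manifest: {exc}") from exc
    m.validate()
    return m


def read_manifests(path: str | Path) -> list[SessionManifest]:
    """Read a YAML/JSON file holding one manifest or a list of them."""
    data = yaml.safe_load(Path(path).read_text())
    if isinstance(data, dict):
        data = [data]
    if not isinstance(data, list):
        raise SchemaError(f"{path}: expected a manifest mapping or list")
    return [manifest_from_dict(d) for d in data]


def write_manifests(manifests: Sequence[SessionManifest], path: str | Path) -> None:
    payload = [manifest_to_dict(m) for m in manifests]
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


# ------------------------------------------------------------------ datasets

def read_dataset(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "label" not in df.columns or "window_start_s" not in df.columns:
        raise SchemaError(f"{path}: not a playaffect dataset (missing label columns)")
    return df


def write_dataset(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, index=False, float_format=FLOAT_FMT)


def write_json_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


# ----------------------------------------------------------- session folders

def write_session(session: SimSession, directory: str | Path, prefix: str) -> None:
    """Write one simulated recording's streams as ``<prefix>_*.csv`` files."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_landmarks(session.track, d / f"{prefix}_landmarks.csv")
    write_rgb_trace(session.trace, d / f"{prefix}_trace.csv")
    write_sensor_hr(session.sensor_t, session.sensor_bpm, d / f"{prefix}_sensor.csv")


def write_cohort(cohort: SimCohort, directory: str | Path) -> None:
    """Write a simulated cohort as a ready-to-run session directory tree."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_manifests(cohort.manifests, d / "manifests.yaml")
    if len(cohort.reports):
        write_reports(cohort.reports, d / "reports.csv")
    for subject in cohort.subjects:
        sdir = d / f"subject_{subject.subject_id:03d}"
        for g, session in subject.calibration.items():
            write_session(session, sdir, f"calibration_{g}")
        for m, session in subject.evaluation.items():
            write_session(session, sdir, f"level_{m}")


# ------------------------------------------------------------ cohort loading

from dataclasses import dataclass, field as _field


@dataclass
class Recording:
    """One loaded recording's streams (duck-compatible with SimSession)."""

    duration_s: float
    track: LandmarkTrack
    trace: RGBTrace
    sensor_t: np.ndarray
    sensor_bpm: np.ndarray


@dataclass
class SubjectData:
    """One subject's recordings as loaded from a cohort directory."""

    subject_id: int
    manifest: SessionManifest
    calibration: dict = _field(default_factory=dict)
    evaluation: dict = _field(default_factory=dict)


def _load_recording(directory: Path, prefix: str, duration_s: float) -> Recording:
    for suffix in ("landmarks", "trace", "sensor"):
        if not (directory / f"{prefix}_{suffix}.csv").exists():
            raise SchemaError(f"missing {prefix}_{suffix}.csv in {directory}")
    track = read_landmarks(directory / f"{prefix}_landmarks.csv")
    trace = read_rgb_trace(directory / f"{prefix}_trace.csv")
    t, bpm = read_sensor_hr(directory / f"{prefix}_sensor.csv")
    return Recording(duration_s=duration_s, track=track, trace=trace,
                     sensor_t=t, sensor_bpm=bpm)


def load_subject(directory: str | Path, subject_id: int) -> SubjectData:
    """Load one subject's recordings from a cohort directory tree."""
    d = Path(directory)
    manifests = {m.subject_id: m for m in read_manifests(d / "manifests.yaml")}
    if subject_id not in manifests:
        raise InvalidInputError(f"subject {subject_id} not in {d / 'manifests.yaml'}")
    manifest = manifests[subject_id]
    sdir = d / f"subject_{subject_id:03d}"
    data = SubjectData(subject_id=subject_id, manifest=manifest)
    for e in manifest.entries:
        prefix = ("calibration" if e.kind == "calibration" else "level") + f"_{e.id}"
        rec = _load_recording(sdir, prefix, e.end_s - e.start_s)
        if e.kind == "calibration":
            data.calibration[e.id] = rec
        else:
            data.evaluation[e.id] = rec
    return data
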