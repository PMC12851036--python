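"""Plain-text file formats: recording CSV + annotations JSON sidecar, Hess
chart and diagnosis JSON, windows containers.

Recordings are stored as CSV with header ``t,ch0,ch45,ch90`` (seconds and
dimensionless ΔR/R at full float precision); annotations travel in a JSON
sidecar ``<name>.annotations.json`` as a list of
``{onset, hold_duration, direction, angle_deg, ramp_time}`` records.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import CHANNEL_NAMES
from .hess import (
    DiagnosisReport,
    GazePointEstimate,
    HessChart,
    HessGeometry,
)
from .simulate import GazeEvent, StrainRecording

__all__ = [
    "annotations_path",
    "read_recording",
    "write_recording",
    "write_cohort",
    "read_cohort",
    "read_chart",
    "write_chart",
    "write_diagnosis",
    "save_windows",
    "load_windows",
]


def annotations_path(path) -> Path:
    path = Path(path)
    return path.with_suffix(".annotations.json")


def write_recording(recording: StrainRecording, path) -> Path:
    """Lossless CSV + JSON-sidecar serialization of a recording."""
    path = Path(path)
    df = pd.DataFrame({"t": recording.time})
    for i, name in enumerate(CHANNEL_NAMES):
        df[name] = recording.channels[i]
    df.to_csv(path, index=False, float_format="%.17g")
    side = {
        "annotations": [dataclasses.asdict(ev) for ev in recording.annotations],
        "subject_meta": recording.subject_meta,
        "sampling_rate": recording.sampling_rate,
    }
    annotations_path(path).write_text(json.dumps(side, indent=1))
    return path


def read_recording(path) -> StrainRecording:
    """Read a recording CSV; the sampling rate is inferred from ``t`` and
    validated to be uniform (the first offending index is reported)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("t", *CHANNEL_NAMES) if c not in df.columns]
    if missing:
        raise ValueError(f"recording CSV is missing column(s): {', '.join(missing)}")
    t = df["t"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("recording must contain at least 2 samples")
    dt = np.diff(t)
    bad = np.flatnonzero(~np.isclose(dt, dt[0], rtol=1e-6, atol=1e-12))
    if dt[0] <= 0 or bad.size:
        idx = int(bad[0] + 1) if bad.size else 1
        raise ValueError(f"non-uniform timestamps: offending sample index {idx}")
    annotations: list[GazeEvent] = []
    meta: dict = {}
    side_path = annotations_path(path)
    if side_path.exists():
        side = json.loads(side_path.read_text())
        annotations = [GazeEvent(**rec) for rec in side.get("annotations", [])]
        meta = side.get("subject_meta", {})
    return StrainRecording(
        time=t,
        channels=df[list(CHANNEL_NAMES)].to_numpy(dtype=float).T,
        sampling_rate=1.0 / dt[0],
        annotations=annotations,
        subject_meta=meta,
    )


def write_cohort(recordings: list[StrainRecording], directory) -> Path:
    """Write per-subject recording/annotation pairs plus a manifest JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, rec in enumerate(recordings):
        name = f"subject_{rec.subject_meta.get('subject_id', i):03d}.csv"
        write_recording(rec, directory / name)
        entries.append(
            {
                "recording": name,
                "annotations": annotations_path(Path(name)).name,
                "subject_meta": rec.subject_meta,
            }
        )
    manifest = directory / "cohort.json"
    manifest.write_text(json.dumps({"recordings": entries}, indent=1, default=list))
    return manifest


def read_cohort(manifest_path) -> list[StrainRecording]:
    manifest_path = Path(manifest_path)
    data = json.loads(manifest_path.read_text())
    return [
        read_recording(manifest_path.parent / entry["recording"])
        for entry in data["recordings"]
    ]


# ---------------------------------------------------------------------------
# Hess charts and diagnoses
# ---------------------------------------------------------------------------

def write_chart(chart: HessChart, path) -> Path:
    path = Path(path)
    payload = {
        "eye": chart.eye,
        "fixating_eye": chart.fixating_eye,
        "geometry": dataclasses.asdict(chart.geometry),
        "points": [
            {
                "position_id": p.position_id,
                "target_deg": list(p.target_deg),
                "measured_deg": list(p.measured_deg),
                "n": p.n_repeats,
                "dispersion_deg": p.dispersion_deg,
            }
            for p in chart.points
        ],
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_chart(path) -> HessChart:
    payload = json.loads(Path(path).read_text())
    geometry = HessGeometry(**payload["geometry"])
    points = [
        GazePointEstimate(
            position_id=rec["position_id"],
            target_deg=tuple(rec["target_deg"]),
            measured_deg=tuple(rec["measured_deg"]),
            n_repeats=rec.get("n", 1),
            dispersion_deg=rec.get("dispersion_deg", 0.0),
        )
        for rec in payload["points"]
    ]
    return HessChart(
        eye=payload["eye"],
        points=points,
        geometry=geometry,
        fixating_eye=payload.get("fixating_eye"),
    )


def write_diagnosis(report: DiagnosisReport, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(dataclasses.asdict(report), indent=1, default=float))
    return path


# ---------------------------------------------------------------------------
# window containers
# ---------------------------------------------------------------------------

def save_windows(path, X, labels, angles, subject_ids=None) -> Path:
    """NPZ container: windows (n, c, T), labels, angles, subject ids."""
    path = Path(path)
    np.savez_compressed(
        path,
        X=np.asarray(X, dtype=np.float32),
        labels=np.asarray(labels, dtype=str),
        angles=np.asarray(angles, dtype=float),
        subject_ids=np.asarray(
            subject_ids if subject_ids is not None else [-1] * len(labels)
        ),
    )
    return path


def load_windows(path):
    with np.load(path, allow_pickle=False) as data:
        return (
            data["X"],
            data["labels"].astype(object),
            data["angles"],
            data["subject_ids"],
        )
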