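"""Convenience builders that chain the simulator and the preprocessing
pipeline into model-ready window datasets."""
from __future__ import annotations

import math

import numpy as np

from .constants import DIRECTIONS_4
from .preprocess import expand_to_ten_channels, highpass_filter, segment, windows_to_array
from .simulate import SensorSpec, generate_cohort

__all__ = ["make_gaze_dataset", "recordings_to_windows"]


def recordings_to_windows(
    recordings,
    window_seconds: float = 2.0,
    cutoff_hz: float = 0.5,
    long_lag_seconds: float = 0.2,
):
    """Filter, segment and expand a list of recordings.

    Returns ``(X, labels, angles, subject_ids)`` with X of shape (n, 10, T).
    """
    expanded, subject_ids = [], []
    for rec in recordings:
        filtered = highpass_filter(rec, cutoff_hz)
        for w in segment(filtered, window_seconds=window_seconds):
            expanded.append(expand_to_ten_channels(w, long_lag_seconds))
            subject_ids.append(rec.subject_meta.get("subject_id", -1))
    if not expanded:
        raise ValueError("no windows could be segmented from the recordings")
    X, labels, angles = windows_to_array(expanded)
    return X, labels, angles, np.asarray(subject_ids)


def make_gaze_dataset(
    n_windows: int = 5000,
    n_subjects: int = 10,
    seed: int = 0,
    sensor: SensorSpec | None = None,
    directions=DIRECTIONS_4,
    angle_range: tuple[float, float] = (5.0, 20.0),
    gain_jitter: float = 0.1,
    artifact_fraction: float = 0.0,
    window_seconds: float = 2.0,
    cutoff_hz: float = 0.5,
):
    """Simulated multi-subject window dataset under the default study
    conditions (50 Hz sampling, default noise and drift, 5°–20° amplitudes)."""
    events_per_subject = math.ceil(n_windows / n_subjects)
    recordings = generate_cohort(
        n_subjects=n_subjects,
        events_per_subject=events_per_subject,
        gain_jitter=gain_jitter,
        seed=seed,
        sensor=sensor,
        directions=tuple(directions),
        angle_range=angle_range,
        artifact_fraction=artifact_fraction,
    )
    X, labels, angles, subject_ids = recordings_to_windows(
        recordings, window_seconds=window_seconds, cutoff_hz=cutoff_hz
    )
    return X[:n_windows], labels[:n_windows], angles[:n_windows], subject_ids[:n_windows]
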