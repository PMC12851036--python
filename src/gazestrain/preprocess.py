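"""Raw 3-channel recordings -> filtered, segmented, 10-channel model inputs.

Pipeline order: zero-phase high-pass filter on the full recording (0.5 Hz
cutoff, removing baseline wander), per-event segmentation into fixed-length
windows, expansion to 10 channels by channel- and time-differencing, and
channel-wise scaling by a robust scale learned on the training set. No
centering is applied anywhere after filtering: the positive/negative polarity
of the units is the physiological signal the classifier exploits.

The 10-channel recipe (in order):
    0-2   raw unit signals s0, s45, s90
    3-5   pairwise channel differences s0-s45, s45-s90, s0-s90
    6-8   lag-1 time differences Δs0, Δs45, Δs90 (zero-padded at sample 0)
    9     lag-K time difference of the channel mean, K = round(0.2 s x fs),
          capturing deformations on a longer timescale
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .constants import event_class
from .simulate import GazeEvent, StrainRecording

__all__ = [
    "Window",
    "TenChannelWindow",
    "highpass_filter",
    "segment",
    "expand_to_ten_channels",
    "normalize",
    "fit_channel_scales",
    "ChannelScaler",
    "windows_to_array",
]


@dataclass
class Window:
    """Fixed-length 3-channel segment around one annotated event."""

    data: np.ndarray  # (3, T)
    sampling_rate: float
    label: str | None = None
    angle_deg: float | None = None
    source_id: object = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != 3:
            raise ValueError("Window data must have shape (3, T)")
        if not np.isfinite(self.data).all():
            raise ValueError("Window contains non-finite values")


@dataclass
class TenChannelWindow:
    """Differential 10-channel expansion of a :class:`Window`."""

    data: np.ndarray  # (10, T)
    sampling_rate: float
    label: str | None = None
    angle_deg: float | None = None
    source_id: object = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != 10:
            raise ValueError("TenChannelWindow data must have shape (10, T)")


def highpass_filter(recording: StrainRecording, cutoff: float = 0.5) -> StrainRecording:
    """Zero-phase 4th-order Butterworth high-pass on every channel.

    Forward-backward filtering keeps event peaks at their original sample
    positions; the DC component and sub-cutoff baseline wander are removed.
    """
    nyquist = recording.sampling_rate / 2.0
    if cutoff >= nyquist:
        raise ValueError(f"cutoff {cutoff} Hz must be below the Nyquist rate {nyquist} Hz")
    sos = sps.butter(4, cutoff, btype="highpass", fs=recording.sampling_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, recording.channels, axis=1)
    return StrainRecording(
        time=recording.time.copy(),
        channels=filtered,
        sampling_rate=recording.sampling_rate,
        annotations=list(recording.annotations),
        subject_meta=dict(recording.subject_meta),
    )


def segment(
    recording: StrainRecording,
    annotations: list[GazeEvent] | None = None,
    window_seconds: float = 2.0,
) -> list[Window]:
    """One window per annotated event, centered on the event onset.

    Windows that would extend past either recording edge are dropped. An empty
    annotation list yields an empty result.
    """
    fs = recording.sampling_rate
    n_samples = int(round(window_seconds * fs))
    if n_samples < 16:
        raise ValueError("window_seconds x sampling_rate must be >= 16 samples")
    events = recording.annotations if annotations is None else annotations
    n = recording.channels.shape[1]
    source = recording.subject_meta.get("subject_id")
    windows = []
    for ev in events:
        start = int(round(ev.onset * fs)) - n_samples // 2
        if start < 0 or start + n_samples > n:
            continue
        windows.append(
            Window(
                data=recording.channels[:, start : start + n_samples].copy(),
                sampling_rate=fs,
                label=event_class(ev.direction),
                angle_deg=ev.angle_deg,
                source_id=source,
            )
        )
    return windows


def expand_to_ten_channels(
    window: Window, long_lag_seconds: float = 0.2
) -> TenChannelWindow:
    """Channel- and time-differencing expansion from 3 to 10 channels."""
    x = window.data
    if x.shape[0] != 3:
        raise ValueError("expected a 3-channel window")
    s0, s45, s90 = x
    lag1 = np.diff(x, axis=1, prepend=x[:, :1])
    k = max(1, int(round(long_lag_seconds * window.sampling_rate)))
    mean = x.mean(axis=0)
    long_diff = np.zeros_like(mean)
    long_diff[k:] = mean[k:] - mean[:-k]
    out = np.vstack([s0, s45, s90, s0 - s45, s45 - s90, s0 - s90, lag1, long_diff])
    return TenChannelWindow(
        data=out,
        sampling_rate=window.sampling_rate,
        label=window.label,
        angle_deg=window.angle_deg,
        source_id=window.source_id,
    )


def fit_channel_scales(windows: list[TenChannelWindow], percentile: float = 99.0) -> np.ndarray:
    """Per-channel robust scale: the ``percentile`` of |x| over the training set."""
    if not windows:
        raise ValueError("need at least one window to fit scales")
    stacked = np.concatenate([w.data for w in windows], axis=1)
    scale = np.percentile(np.abs(stacked), percentile, axis=1)
    return np.maximum(scale, 1e-12)


def normalize(window: TenChannelWindow, scale: np.ndarray) -> TenChannelWindow:
    """Channel-wise division by a stored training-set scale (no centering)."""
    scale = np.asarray(scale, dtype=float)
    if scale.shape != (10,):
        raise ValueError("scale must have one entry per channel")
    if np.any(scale <= 0):
        raise ValueError("scales must be positive")
    return replace(window, data=window.data / scale[:, None])


class ChannelScaler(BaseEstimator, TransformerMixin):
    """Sklearn-style wrapper around :func:`fit_channel_scales` for arrays.

    Operates on arrays of shape (n_windows, 10, T).
    """

    def __init__(self, percentile: float = 99.0):
        self.percentile = percentile

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[1] != 10:
            raise ValueError("X must have shape (n, 10, T)")
        scale = np.percentile(np.abs(X), self.percentile, axis=(0, 2))
        self.scale_ = np.maximum(scale, 1e-12)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return X / self.scale_[None, :, None]


def windows_to_array(windows: list[TenChannelWindow] | list[Window]):
    """Stack window objects into (X, labels, angles) arrays for estimators."""
    X = np.stack([w.data for w in windows]).astype(np.float32)
    labels = np.array([w.label for w in windows], dtype=object)
    angles = np.array(
        [np.nan if w.angle_deg is None else w.angle_deg for w in windows], dtype=float
    )
    return X, labels, angles
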