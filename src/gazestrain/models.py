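"""Gaze-direction classification, per-direction angle regression, baselines,
and few-shot subject calibration.

Three classifiers are provided:

* :class:`InceptionTimeTinyClassifier` — the lightweight two-depth
  InceptionTime variant (65,156 trainable parameters in its 4-class form)
  operating on 10-channel differential windows;
* :class:`PolarityRuleClassifier` — the physiological baseline that decides
  from the signed extrema of the 0°/90° units alone;
* :class:`KNeighborsDTWClassifier` — a classical KNN with multichannel
  dynamic-time-warping distance.

Angle regression uses one :class:`MLPAngleRegressor` (44,033 parameters in
scalar form) per direction class, fed with the 10 signed channel extrema of a
window; at inference the predicted class routes each window to its regressor,
and the blink/expression class routes to none.
"""
from __future__ import annotations

import copy
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    f1_score,
    precision_recall_fscore_support,
)

from . import nn
from .constants import ARTIFACT_CLASS, CH0, CH90
from .preprocess import (
    ChannelScaler,
    expand_to_ten_channels,
    highpass_filter,
    segment,
    windows_to_array,
)
from .simulate import StrainRecording

__all__ = [
    "ClassifierSpec",
    "RegressorSpec",
    "TrainConfig",
    "EvalReport",
    "count_parameters",
    "InceptionTimeTinyClassifier",
    "MLPAngleRegressor",
    "PolarityRuleClassifier",
    "KNeighborsDTWClassifier",
    "dtw_distance",
    "knn_dtw_classify",
    "polarity_classify",
    "train_classifier",
    "train_regressor",
    "evaluate_classifier",
    "evaluate_regression",
    "extract_regression_features",
    "EndToEndGazeModel",
    "predict_end_to_end",
    "few_shot_calibrate",
    "FewShotConfig",
    "save_end_to_end",
    "load_end_to_end",
]


# ---------------------------------------------------------------------------
# architecture specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifierSpec:
    """Pinned InceptionTime-Tiny architecture description."""

    in_channels: int = 10
    n_filters: int = 32
    kernel_sizes: tuple[int, ...] = (17, 7, 3)
    depth: int = 2
    n_classes: int = 4

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")

    def build(self, rng=None) -> nn.InceptionTimeTinyNet:
        return nn.InceptionTimeTinyNet(
            in_channels=self.in_channels,
            n_filters=self.n_filters,
            kernel_sizes=self.kernel_sizes,
            depth=self.depth,
            n_classes=self.n_classes,
            rng=rng,
        )


@dataclass(frozen=True)
class RegressorSpec:
    """Pinned four-layer MLP description for angle / gaze-point regression."""

    input_dim: int = 10
    hidden: tuple[int, ...] = (256, 128, 64)
    output_dim: int = 1
    dropout: float = 0.2

    def build(self, rng=None) -> nn.MLPNet:
        return nn.MLPNet(
            in_features=self.input_dim,
            hidden=self.hidden,
            out_features=self.output_dim,
            dropout=self.dropout,
            rng=rng,
        )


@dataclass
class TrainConfig:
    """Optimization settings: Adam, cosine-decayed learning rate, 20 epochs."""

    lr: float = 1e-3
    epochs: int = 20
    batch_size: int = 64
    dropout: float = 0.2
    seed: int = 0
    val_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr <= 0:
            raise ValueError("learning rate must be > 0")


def count_parameters(obj) -> int:
    """Exact number of trainable scalars of a spec, estimator, or network."""
    if isinstance(obj, (ClassifierSpec, RegressorSpec)):
        return nn.count_net_parameters(obj.build(np.random.default_rng(0)))
    if isinstance(obj, nn.Layer):
        return nn.count_net_parameters(obj)
    if hasattr(obj, "net_"):
        return nn.count_net_parameters(obj.net_)
    raise TypeError(f"cannot count parameters of {type(obj).__name__}")


# ---------------------------------------------------------------------------
# deep classifier
# ---------------------------------------------------------------------------

class InceptionTimeTinyClassifier(BaseEstimator, ClassifierMixin):
    """Sklearn-style estimator around the numpy InceptionTime-Tiny network.

    ``fit`` expects ``X`` of shape (n_windows, in_channels, T) and arbitrary
    hashable labels in ``y``. Training is deterministic given ``random_state``.
    """

    def __init__(
        self,
        n_filters: int = 32,
        kernel_sizes: tuple[int, ...] = (17, 7, 3),
        depth: int = 2,
        lr: float = 1e-3,
        epochs: int = 20,
        batch_size: int = 64,
        random_state: int = 0,
    ):
        self.n_filters = n_filters
        self.kernel_sizes = kernel_sizes
        self.depth = depth
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state

    def _validate(self, X):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3:
            raise ValueError("X must have shape (n_windows, channels, T)")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        return X

    def fit(self, X, y):
        X = self._validate(X)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if self.classes_.size < 2:
            raise ValueError("training data must contain at least 2 classes")
        rng = np.random.default_rng(self.random_state)
        self.net_ = nn.InceptionTimeTinyNet(
            in_channels=X.shape[1],
            n_filters=self.n_filters,
            kernel_sizes=self.kernel_sizes,
            depth=self.depth,
            n_classes=self.classes_.size,
            rng=rng,
        )
        self._opt = nn.Adam(self.net_.parameters(), lr=self.lr)
        self._shuffle_rng = rng
        self.history_ = self._run_epochs(X, y_idx, self.lr, self.epochs)
        return self

    def _run_epochs(self, X, y_idx, base_lr, epochs) -> pd.DataFrame:
        n = X.shape[0]
        records = []
        for epoch in range(epochs):
            lr_t = nn.cosine_lr(base_lr, epoch, epochs)
            perm = self._shuffle_rng.permutation(n)
            losses, preds, trues = [], [], []
            for start in range(0, n, self.batch_size):
                idx = perm[start : start + self.batch_size]
                logits = self.net_.forward(X[idx], train=True)
                loss, grad = nn.softmax_cross_entropy(logits, y_idx[idx])
                self._opt.zero_grad()
                self.net_.backward(grad)
                self._opt.step(lr_t)
                losses.append(loss * idx.size)
                preds.append(logits.argmax(axis=1))
                trues.append(y_idx[idx])
            preds = np.concatenate(preds)
            trues = np.concatenate(trues)
            records.append(
                {
                    "epoch": epoch + 1,
                    "loss": float(np.sum(losses) / n),
                    "accuracy": float(accuracy_score(trues, preds)),
                    "macro_f1": float(f1_score(trues, preds, average="macro")),
                    "lr": lr_t,
                }
            )
        return pd.DataFrame.from_records(records)

    def fine_tune(self, X, y, lr_scale: float = 0.1, epochs: int = 20) -> "InceptionTimeTinyClassifier":
        """Continue training all weights at a reduced learning rate (in place)."""
        X = self._validate(X)
        y_idx = np.searchsorted(self.classes_, np.asarray(y))
        if not np.array_equal(self.classes_[y_idx], np.asarray(y)):
            raise ValueError("fine-tune labels must be a subset of fitted classes")
        if not hasattr(self, "_shuffle_rng"):
            self._shuffle_rng = np.random.default_rng(self.random_state)
        if not hasattr(self, "history_"):
            self.history_ = pd.DataFrame()
        self._opt = nn.Adam(self.net_.parameters(), lr=self.lr * lr_scale)
        hist = self._run_epochs(X, y_idx, self.lr * lr_scale, epochs)
        self.history_ = pd.concat([self.history_, hist], ignore_index=True)
        return self

    def decision_function(self, X):
        X = self._validate(X)
        out = []
        for start in range(0, X.shape[0], 256):
            out.append(self.net_.forward(X[start : start + 256], train=False))
        return np.concatenate(out) if out else np.empty((0, self.classes_.size))

    def predict_proba(self, X):
        logits = self.decision_function(X)
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        return ez / ez.sum(axis=1, keepdims=True)

    def predict(self, X):
        return self.classes_[self.decision_function(X).argmax(axis=1)]


# ---------------------------------------------------------------------------
# angle regressor
# ---------------------------------------------------------------------------

class MLPAngleRegressor(BaseEstimator, RegressorMixin):
    """Four-layer MLP for gaze angle (scalar) or gaze point (2-D) regression.

    Scalar mode minimizes squared angle error; coordinate mode minimizes the
    Euclidean distance between predicted and target gaze points.
    """

    def __init__(
        self,
        hidden: tuple[int, ...] = (256, 128, 64),
        output_dim: int = 1,
        dropout: float = 0.2,
        lr: float = 1e-3,
        epochs: int = 300,
        batch_size: int = 32,
        min_samples: int = 20,
        random_state: int = 0,
    ):
        self.hidden = hidden
        self.output_dim = output_dim
        self.dropout = dropout
        self.lr = lr
        self.epochs = epochs
        self.batch_size = batch_size
        self.min_samples = min_samples
        self.random_state = random_state

    def _validate(self, X):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 2:
            raise ValueError("X must have shape (n_samples, n_features)")
        return X

    def _loss(self, pred, target):
        if self.output_dim == 1:
            return nn.mse_loss(pred, target)
        return nn.euclidean_loss(pred, target)

    def fit(self, X, y):
        X = self._validate(X)
        y = np.asarray(y, dtype=np.float32).reshape(X.shape[0], -1)
        if y.shape[1] != self.output_dim:
            raise ValueError(f"targets must have {self.output_dim} column(s)")
        if X.shape[0] < self.min_samples:
            raise ValueError(
                f"need at least {self.min_samples} samples to fit the regressor"
            )
        rng = np.random.default_rng(self.random_state)
        self.net_ = nn.MLPNet(
            in_features=X.shape[1],
            hidden=self.hidden,
            out_features=self.output_dim,
            dropout=self.dropout,
            rng=rng,
        )
        self._opt = nn.Adam(self.net_.parameters(), lr=self.lr)
        self._shuffle_rng = rng
        self.history_ = self._run_epochs(X, y, self.lr, self.epochs)
        return self

    def _run_epochs(self, X, y, base_lr, epochs) -> pd.DataFrame:
        n = X.shape[0]
        records = []
        for epoch in range(epochs):
            lr_t = nn.cosine_lr(base_lr, epoch, epochs)
            perm = self._shuffle_rng.permutation(n)
            total = 0.0
            for start in range(0, n, self.batch_size):
                idx = perm[start : start + self.batch_size]
                pred = self.net_.forward(X[idx], train=True)
                loss, grad = self._loss(pred, y[idx])
                self._opt.zero_grad()
                self.net_.backward(grad)
                self._opt.step(lr_t)
                total += loss * idx.size
            records.append({"epoch": epoch + 1, "loss": total / n, "lr": lr_t})
        return pd.DataFrame.from_records(records)

    def fine_tune(self, X, y, lr_scale: float = 0.1, epochs: int = 200) -> "MLPAngleRegressor":
        X = self._validate(X)
        y = np.asarray(y, dtype=np.float32).reshape(X.shape[0], -1)
        if not hasattr(self, "_shuffle_rng"):
            self._shuffle_rng = np.random.default_rng(self.random_state)
        if not hasattr(self, "history_"):
            self.history_ = pd.DataFrame()
        self._opt = nn.Adam(self.net_.parameters(), lr=self.lr * lr_scale)
        hist = self._run_epochs(X, y, self.lr * lr_scale, epochs)
        self.history_ = pd.concat([self.history_, hist], ignore_index=True)
        return self

    def recalibrate(self, X, y, slope_bounds=(0.5, 2.0)):
        """Least-squares affine correction of the network output (scalar mode).

        A low-capacity recalibration layer: predictions on the calibration
        samples are regressed onto the true angles, and the fitted (clipped)
        slope/offset are applied at inference. Unlike weight fine-tuning this
        averages calibration-sample noise, so its variance shrinks with the
        number of samples.
        """
        if self.output_dim != 1:
            raise ValueError("output recalibration is defined for scalar angles")
        X = self._validate(X)
        y = np.asarray(y, dtype=float).ravel()
        p = self.net_.forward(X, train=False)[:, 0].astype(float)
        if p.size < 2 or np.ptp(p) < 1e-6:
            slope = 1.0
            offset = float(np.mean(y - p)) if p.size else 0.0
        else:
            slope, offset = np.polyfit(p, y, 1)
            slope = float(np.clip(slope, *slope_bounds))
            offset = float(np.mean(y - slope * p))
        self.output_scale_ = slope
        self.output_offset_ = offset
        return self

    def predict(self, X):
        X = self._validate(X)
        out = self.net_.forward(X, train=False)
        scale = getattr(self, "output_scale_", 1.0)
        offset = getattr(self, "output_offset_", 0.0)
        if self.output_dim == 1:
            return scale * out[:, 0] + offset
        return out


# ---------------------------------------------------------------------------
# polarity baseline
# ---------------------------------------------------------------------------

def _signed_extrema(x: np.ndarray) -> np.ndarray:
    """Signed value of largest magnitude along the last axis."""
    idx = np.abs(x).argmax(axis=-1)
    return np.take_along_axis(x, idx[..., None], axis=-1)[..., 0]


def polarity_classify(window, threshold: float = 0.002, eye: str = "right") -> str:
    """Rule-based direction decision from the 0°/90°-unit signed extrema.

    A dominant negative 90°-unit extremum means upward gaze (eyelid
    compression), positive means downward; a dominant 0°-unit extremum maps
    through the eye side (positive = abduction). Below ``threshold`` the
    window is "uncertain".
    """
    data = np.asarray(
        window.data if hasattr(window, "sampling_rate") else window, dtype=float
    )
    e = _signed_extrema(data)
    e0, e90 = e[CH0], e[CH90]
    if max(abs(e0), abs(e90)) < threshold:
        return "uncertain"
    if abs(e90) >= abs(e0):
        return "up" if e90 < 0 else "down"
    abducting = e0 > 0
    if eye == "right":
        return "right" if abducting else "left"
    return "left" if abducting else "right"


class PolarityRuleClassifier(BaseEstimator, ClassifierMixin):
    """Stateless wrapper exposing :func:`polarity_classify` on window arrays."""

    def __init__(self, threshold: float = 0.002, eye: str = "right"):
        self.threshold = threshold
        self.eye = eye

    def fit(self, X=None, y=None):
        self.classes_ = np.array(["down", "left", "right", "up"], dtype=object)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        return np.array(
            [polarity_classify(x, self.threshold, self.eye) for x in X], dtype=object
        )


# ---------------------------------------------------------------------------
# DTW baseline
# ---------------------------------------------------------------------------

_DTW_JIT = None


def _get_dtw_jit():
    global _DTW_JIT
    if _DTW_JIT is None:
        from numba import njit

        @njit(cache=True)
        def dtw_1d(a, b):
            n, m = a.shape[0], b.shape[0]
            D = np.full((n + 1, m + 1), np.inf)
            D[0, 0] = 0.0
            for i in range(1, n + 1):
                for j in range(1, m + 1):
                    c = abs(a[i - 1] - b[j - 1])
                    best = D[i - 1, j - 1]
                    if D[i - 1, j] < best:
                        best = D[i - 1, j]
                    if D[i, j - 1] < best:
                        best = D[i, j - 1]
                    D[i, j] = c + best
            return D[n, m]

        @njit(cache=True)
        def dtw_multi(A, B):
            total = 0.0
            for ch in range(A.shape[0]):
                total += dtw_1d(A[ch], B[ch])
            return total

        _DTW_JIT = (dtw_1d, dtw_multi)
    return _DTW_JIT


def dtw_distance(a, b) -> float:
    """Dynamic-time-warping alignment cost with |.|-local cost and
    match/insert/delete steps; symmetric and zero for identical sequences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("sequences must be non-empty")
    dtw_1d, dtw_multi = _get_dtw_jit()
    if a.ndim == 1 and b.ndim == 1:
        return float(dtw_1d(a, b))
    if a.ndim == 2 and b.ndim == 2 and a.shape[0] == b.shape[0]:
        return float(dtw_multi(a, b))
    raise ValueError("sequences must both be 1-D, or 2-D with equal channel counts")


class KNeighborsDTWClassifier(BaseEstimator, ClassifierMixin):
    """K-nearest-neighbour classification under multichannel DTW distance.

    Majority vote among the k nearest training windows; ties are broken by the
    smallest total distance of the tied classes. ``decimate`` subsamples the
    time axis (DTW cost is quadratic in length; the gaze band is <= 1 Hz, so
    moderate decimation is lossless for this signal class).
    """

    def __init__(self, k: int = 1, decimate: int = 1):
        self.k = k
        self.decimate = decimate

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.shape[0] == 0:
            raise ValueError("training set must be non-empty")
        if self.k > X.shape[0]:
            raise ValueError("k cannot exceed the training-set size")
        self._X = X[:, :, :: self.decimate]
        self._y = y
        self.classes_ = np.unique(y)
        return self

    def _distances(self, q):
        _, dtw_multi = _get_dtw_jit()
        return np.array([dtw_multi(x, q) for x in self._X])

    def predict_one(self, query):
        q = np.asarray(query, dtype=float)[:, :: self.decimate]
        d = self._distances(q)
        nearest = np.argsort(d, kind="stable")[: self.k]
        labels = self._y[nearest]
        values, counts = np.unique(labels, return_counts=True)
        winners = values[counts == counts.max()]
        if winners.size == 1:
            return winners[0]
        totals = {v: d[nearest[labels == v]].sum() for v in winners}
        return min(totals, key=totals.get)

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return np.array([self.predict_one(q) for q in X], dtype=self._y.dtype)


def knn_dtw_classify(train_X, train_y, query, k: int = 1):
    """Functional form of :class:`KNeighborsDTWClassifier` for one query."""
    clf = KNeighborsDTWClassifier(k=k).fit(train_X, train_y)
    return clf.predict_one(query)


# ---------------------------------------------------------------------------
# training wrappers and evaluation
# ---------------------------------------------------------------------------

def train_classifier(X, y, spec: ClassifierSpec | None = None, cfg: TrainConfig | None = None):
    """Fit an InceptionTime-Tiny classifier; returns (estimator, history)."""
    spec = spec or ClassifierSpec()
    cfg = cfg or TrainConfig()
    est = InceptionTimeTinyClassifier(
        n_filters=spec.n_filters,
        kernel_sizes=spec.kernel_sizes,
        depth=spec.depth,
        lr=cfg.lr,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        random_state=cfg.seed,
    ).fit(X, y)
    return est, est.history_


def train_regressor(
    features, angles, spec: RegressorSpec | None = None, cfg: TrainConfig | None = None,
    epochs: int | None = None,
):
    """Fit one per-direction angle regressor on extracted features."""
    spec = spec or RegressorSpec()
    cfg = cfg or TrainConfig()
    est = MLPAngleRegressor(
        hidden=spec.hidden,
        output_dim=spec.output_dim,
        dropout=spec.dropout,
        lr=cfg.lr,
        epochs=epochs if epochs is not None else 300,
        random_state=cfg.seed,
    ).fit(features, angles)
    return est


@dataclass
class EvalReport:
    """Classification metrics: accuracy, per-class P/R/F1, confusion matrix."""

    accuracy: float
    macro_f1: float
    per_class: pd.DataFrame
    confusion: pd.DataFrame
    mae_deg: float | None = None
    mae_per_direction: dict | None = None


def evaluate_classifier(model, X, y) -> EvalReport:
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("evaluation set must be non-empty")
    pred = model.predict(X)
    labels = np.unique(np.concatenate([y, pred]))
    prec, rec, f1, support = precision_recall_fscore_support(
        y, pred, labels=labels, zero_division=0
    )
    per_class = pd.DataFrame(
        {"precision": prec, "recall": rec, "f1": f1, "support": support}, index=labels
    )
    cm = pd.DataFrame(
        confusion_matrix(y, pred, labels=labels), index=labels, columns=labels
    )
    return EvalReport(
        accuracy=float(accuracy_score(y, pred)),
        macro_f1=float(f1_score(y, pred, labels=labels, average="macro", zero_division=0)),
        per_class=per_class,
        confusion=cm,
    )


def evaluate_regression(regressors, features, labels, angles) -> EvalReport:
    """Angle-regression metrics: MAE overall and per direction, routed by the
    true labels. Classification fields are left at their degenerate values."""
    labels = np.asarray(labels)
    angles = np.asarray(angles, dtype=float)
    if labels.size == 0:
        raise ValueError("evaluation set must be non-empty")
    per_direction = {}
    errors = []
    for c in np.unique(labels):
        mask = labels == c
        pred = regressors[str(c)].predict(np.asarray(features)[mask])
        err = np.abs(pred - angles[mask])
        per_direction[str(c)] = float(err.mean())
        errors.append(err)
    overall = float(np.concatenate(errors).mean())
    empty = pd.DataFrame()
    return EvalReport(
        accuracy=float("nan"), macro_f1=float("nan"), per_class=empty,
        confusion=empty, mae_deg=overall, mae_per_direction=per_direction,
    )


def extract_regression_features(window) -> np.ndarray:
    """Signed extremum of each of the 10 channels, in expansion order.

    Accepts a TenChannelWindow, one (10, T) array, or a batch (n, 10, T).
    """
    data = np.asarray(
        window.data if hasattr(window, "sampling_rate") else window, dtype=float
    )
    return _signed_extrema(data)


# ---------------------------------------------------------------------------
# end-to-end model
# ---------------------------------------------------------------------------

@dataclass
class EndToEndGazeModel:
    """Classification-then-regression pipeline over raw recordings."""

    classifier: InceptionTimeTinyClassifier
    regressors: dict[str, MLPAngleRegressor]
    scaler: ChannelScaler
    window_seconds: float = 2.0
    cutoff_hz: float = 0.5
    long_lag_seconds: float = 0.2
    no_angle_classes: frozenset = frozenset({ARTIFACT_CLASS})

    def _windows_to_X(self, windows):
        expanded = [expand_to_ten_channels(w, self.long_lag_seconds) for w in windows]
        X = np.stack([w.data for w in expanded]).astype(np.float32)
        return self.scaler.transform(X).astype(np.float32)

    def predict_windows(self, X):
        """(label, angle-or-None) for already expanded+scaled windows."""
        labels = self.classifier.predict(X)
        feats = extract_regression_features(X)
        results = []
        for i, label in enumerate(labels):
            if label in self.no_angle_classes:
                results.append((label, None))
                continue
            if label not in self.regressors:
                raise KeyError(f"no regressor trained for predicted class {label!r}")
            angle = float(self.regressors[label].predict(feats[i : i + 1])[0])
            results.append((label, angle))
        return results

    def predict(self, recording: StrainRecording):
        filtered = highpass_filter(recording, self.cutoff_hz)
        windows = segment(filtered, window_seconds=self.window_seconds)
        if not windows:
            return []
        return self.predict_windows(self._windows_to_X(windows))


def predict_end_to_end(recording, classifier, regressors, scaler, **kwargs):
    """Functional form of :meth:`EndToEndGazeModel.predict`."""
    return EndToEndGazeModel(classifier, regressors, scaler, **kwargs).predict(recording)


@dataclass
class FewShotConfig:
    """Budget for subject calibration: all weights, reduced learning rate."""

    lr_scale: float = 0.1
    classifier_epochs: int = 20
    regressor_epochs: int = 200
    min_samples: int = 2
    max_samples: int = 5


def few_shot_calibrate(
    model: EndToEndGazeModel,
    X,
    labels,
    angles,
    cfg: FewShotConfig | None = None,
) -> EndToEndGazeModel:
    """Adapt a trained model to a new subject from 2–5 windows per position.

    ``X`` holds expanded+scaled windows (n, 10, T); every direction class the
    model regresses must appear between ``min_samples`` and ``max_samples``
    times. The original model is left untouched; a fine-tuned copy is
    returned.
    """
    cfg = cfg or FewShotConfig()
    labels = np.asarray(labels)
    angles = np.asarray(angles, dtype=float)
    X = np.asarray(X, dtype=np.float32)
    positions = [c for c in model.classifier.classes_ if c not in model.no_angle_classes]
    for c in positions:
        n_c = int((labels == c).sum())
        if not cfg.min_samples <= n_c <= cfg.max_samples:
            raise ValueError(
                f"calibration needs {cfg.min_samples}–{cfg.max_samples} samples per "
                f"position; got {n_c} for {c!r}"
            )
    adapted = copy.deepcopy(model)
    adapted.classifier.fine_tune(
        X, labels, lr_scale=cfg.lr_scale, epochs=cfg.classifier_epochs
    )
    feats = extract_regression_features(X)
    for c in positions:
        mask = labels == c
        reg = adapted.regressors[c]
        reg.fine_tune(
            feats[mask], angles[mask], lr_scale=cfg.lr_scale, epochs=cfg.regressor_epochs
        )
        if reg.output_dim == 1:
            reg.recalibrate(feats[mask], angles[mask])
    return adapted


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_end_to_end(path, model: EndToEndGazeModel) -> None:
    """Single-archive checkpoint: specs, weights, scaler, routing metadata."""
    arrays: dict[str, np.ndarray] = {}
    meta = {
        "classifier": {
            k: getattr(model.classifier, k)
            for k in ("n_filters", "kernel_sizes", "depth", "lr", "epochs",
                      "batch_size", "random_state")
        },
        "classes": list(map(str, model.classifier.classes_)),
        "regressors": {},
        "window_seconds": model.window_seconds,
        "cutoff_hz": model.cutoff_hz,
        "long_lag_seconds": model.long_lag_seconds,
        "no_angle_classes": sorted(model.no_angle_classes),
        "in_channels": int(model.classifier.net_.blocks[0].bottleneck.in_ch),
    }
    for key, arr in nn.net_state(model.classifier.net_).items():
        arrays[f"clf__{key}"] = arr
    for i, (label, reg) in enumerate(sorted(model.regressors.items())):
        meta["regressors"][label] = {
            "slot": i,
            **{k: getattr(reg, k) for k in ("hidden", "output_dim", "dropout", "lr",
                                            "epochs", "batch_size", "random_state")},
        }
        for key, arr in nn.net_state(reg.net_).items():
            arrays[f"reg{i}__{key}"] = arr
        arrays[f"reg{i}__outcal"] = np.array(
            [getattr(reg, "output_scale_", 1.0), getattr(reg, "output_offset_", 0.0)]
        )
    arrays["scaler_scale"] = model.scaler.scale_
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta, default=list).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_end_to_end(path) -> EndToEndGazeModel:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(bytes(data["meta_json"].tobytes()).decode())
        clf_kwargs = dict(meta["classifier"])
        clf_kwargs["kernel_sizes"] = tuple(clf_kwargs["kernel_sizes"])
        clf = InceptionTimeTinyClassifier(**clf_kwargs)
        clf.classes_ = np.array(meta["classes"], dtype=object)
        clf.net_ = nn.InceptionTimeTinyNet(
            in_channels=meta["in_channels"],
            n_filters=clf.n_filters,
            kernel_sizes=clf.kernel_sizes,
            depth=clf.depth,
            n_classes=clf.classes_.size,
            rng=np.random.default_rng(clf.random_state),
        )
        nn.load_net_state(
            clf.net_,
            {k[len("clf__"):]: data[k] for k in data.files if k.startswith("clf__")},
        )
        regressors = {}
        for label, rmeta in meta["regressors"].items():
            slot = rmeta.pop("slot")
            rmeta["hidden"] = tuple(rmeta["hidden"])
            reg = MLPAngleRegressor(**rmeta)
            reg.net_ = nn.MLPNet(
                in_features=10,
                hidden=reg.hidden,
                out_features=reg.output_dim,
                dropout=reg.dropout,
                rng=np.random.default_rng(reg.random_state),
            )
            prefix = f"reg{slot}__"
            state = {
                k[len(prefix):]: data[k] for k in data.files if k.startswith(prefix)
            }
            outcal = state.pop("outcal", None)
            nn.load_net_state(reg.net_, state)
            if outcal is not None:
                reg.output_scale_, reg.output_offset_ = map(float, outcal)
            regressors[label] = reg
        scaler = ChannelScaler()
        scaler.scale_ = data["scaler_scale"]
        return EndToEndGazeModel(
            classifier=clf,
            regressors=regressors,
            scaler=scaler,
            window_seconds=meta["window_seconds"],
            cutoff_hz=meta["cutoff_hz"],
            long_lag_seconds=meta["long_lag_seconds"],
            no_angle_classes=frozenset(meta["no_angle_classes"]),
        )
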