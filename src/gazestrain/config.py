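"""Pipeline configuration with strict, lossless YAML round-trips."""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .hess import DiagnosisThresholds, HessGeometry
from .models import ClassifierSpec, RegressorSpec, TrainConfig
from .simulate import SensorSpec

__all__ = ["PreprocessConfig", "PipelineConfig"]


@dataclass(frozen=True)
class PreprocessConfig:
    cutoff_hz: float = 0.5
    window_seconds: float = 2.0
    long_lag_seconds: float = 0.2
    scale_percentile: float = 99.0


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run: sensor physics, preprocessing
    recipe, model architectures, training settings, Hess geometry/thresholds,
    and the master seed."""

    sensor: SensorSpec = field(default_factory=SensorSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    regressor: RegressorSpec = field(default_factory=RegressorSpec)
    training: TrainConfig = field(default_factory=TrainConfig)
    hess_geometry: HessGeometry = field(default_factory=HessGeometry)
    hess_thresholds: DiagnosisThresholds = field(default_factory=DiagnosisThresholds)
    eye: str = "right"
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in data:
                continue
            value = data.pop(f.name)
            if dataclasses.is_dataclass(f.type) or f.name in _NESTED:
                value = _build_nested(f.name, value)
            kwargs[f.name] = value
        if data:
            raise ValueError(f"unknown configuration key(s): {', '.join(sorted(data))}")
        return cls(**kwargs)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


_NESTED = {
    "sensor": SensorSpec,
    "preprocess": PreprocessConfig,
    "classifier": ClassifierSpec,
    "regressor": RegressorSpec,
    "training": TrainConfig,
    "hess_geometry": HessGeometry,
    "hess_thresholds": DiagnosisThresholds,
}


def _build_nested(name: str, value):
    cls = _NESTED[name]
    if isinstance(value, cls):
        return value
    if not isinstance(value, dict):
        raise ValueError(f"configuration field {name!r} must be a mapping")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(value) - known
    if unknown:
        raise ValueError(
            f"unknown configuration key(s) in {name!r}: {', '.join(sorted(unknown))}"
        )
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
    }
    return cls(**coerced)
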