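"""Pipeline configuration: one YAML file, nested blocks per stage.

Unknown keys are rejected so a typo cannot silently fall back to a
default, and a loaded config serialises back to an equal document.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .doa_model import AnnConfig
from .errors import InvalidArgumentError
from .sdi import SDIConfig
from .synthetic import SimulationParams


@dataclass
class PreprocessingConfig:
    fs: float = 500.0
    notch_freq: float = 60.0
    notch_quality: float = 30.0
    artifact_intervals: dict = field(default_factory=dict)  # case id -> [[start_s, end_s], ...]


@dataclass
class HrvConfig:
    resample_fs: float = 4.0
    refractory_s: float = 0.2


@dataclass
class EaclConfig:
    step: float = 5.0


@dataclass
class ModelConfig:
    ann: AnnConfig = field(default_factory=AnnConfig)
    n_members: int = 10
    n_repeats: int = 10
    min_case_correlation: float = 0.3
    n_pure_test: int | None = None
    pure_test_ids: list | None = None


@dataclass
class EvaluationConfig:
    threshold: float = 65.0


@dataclass
class PipelineConfig:
    seed: int = 0
    n_cases: int = 1
    simulation: SimulationParams = field(default_factory=SimulationParams)
    preprocessing: PreprocessingConfig = field(default_factory=PreprocessingConfig)
    hrv: HrvConfig = field(default_factory=HrvConfig)
    sdi: SDIConfig = field(default_factory=SDIConfig)
    eacl: EaclConfig = field(default_factory=EaclConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        """Stable digest of every config value, for run logging."""
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def _build(cls, data: dict, path: str):
    fields = {f.name: f for f in cls.__dataclass_fields__.values()}
    unknown = set(data) - set(fields)
    if unknown:
        raise InvalidArgumentError(f"unknown config key(s) under {path or 'top level'}: "
                                   f"{sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        sub = {"simulation": SimulationParams, "preprocessing": PreprocessingConfig,
               "hrv": HrvConfig, "sdi": SDIConfig, "eacl": EaclConfig,
               "model": ModelConfig, "evaluation": EvaluationConfig,
               "ann": AnnConfig}.get(name)
        if sub is not None and isinstance(value, dict):
            kwargs[name] = _build(sub, value, f"{path}.{name}" if path else name)
        elif name in ("hidden_layers", "split_fractions") and isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def load_config(path) -> PipelineConfig:
    """Load a YAML pipeline config; unknown keys raise."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise InvalidArgumentError(f"{path}: config must be a mapping")
    return _build(PipelineConfig, data, "")


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
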