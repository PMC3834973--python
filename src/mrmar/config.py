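"""YAML run configuration.

A :class:`RunConfig` bundles every tunable of the pipeline and
round-trips losslessly through YAML, so a run is fully described by one
file plus the input images.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .correction import CorrectionConfig
from .detection import DetectionConfig
from .errors import ValidationError
from .phantom import MRSynthesisConfig, PhysicsConfig


@dataclass
class GeometryConfig:
    n_angles: int = 180
    bin_spacing: float | None = None  # None = pixel spacing


@dataclass
class StudyConfig:
    implant_counts: list[int] = field(default_factory=lambda: [1, 2, 3])
    seeds: list[int] = field(default_factory=lambda: [0, 1, 2, 3, 4])
    size: int = 128
    implant_radius: float = 5.0


@dataclass
class RunConfig:
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    correction: CorrectionConfig = field(default_factory=CorrectionConfig)
    physics: PhysicsConfig = field(default_factory=PhysicsConfig)
    mr_synthesis: MRSynthesisConfig = field(default_factory=MRSynthesisConfig)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    study: StudyConfig = field(default_factory=StudyConfig)
    random_seed: int = 0
    paths: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        # YAML mapping keys must be plain scalars; tissue_map floats are fine
        if self.mr_synthesis.tissue_map is not None:
            d["mr_synthesis"]["tissue_map"] = {
                float(k): float(v) for k, v in self.mr_synthesis.tissue_map.items()
            }
        return d


_SECTIONS = {
    "detection": DetectionConfig,
    "correction": CorrectionConfig,
    "physics": PhysicsConfig,
    "mr_synthesis": MRSynthesisConfig,
    "geometry": GeometryConfig,
    "study": StudyConfig,
}


def _build(cls, data: dict):
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValidationError(f"unknown keys {sorted(unknown)} in {cls.__name__}")
    kwargs = dict(data)
    for key in ("shift", "recon_clip"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return cls(**kwargs)


def config_from_dict(data: dict) -> RunConfig:
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            kwargs[name] = _build(cls, data[name] or {})
    if "random_seed" in data:
        kwargs["random_seed"] = int(data["random_seed"])
    if "paths" in data:
        kwargs["paths"] = dict(data["paths"] or {})
    unknown = set(data) - set(_SECTIONS) - {"random_seed", "paths"}
    if unknown:
        raise ValidationError(f"unknown top-level config keys: {sorted(unknown)}")
    return RunConfig(**kwargs)


def load_config(path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValidationError(f"config root must be a mapping, got {type(data).__name__}")
    return config_from_dict(data)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
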