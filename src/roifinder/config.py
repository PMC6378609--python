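"""Run configuration: one YAML/JSON document bundling every tunable.

Unknown keys are rejected so a typo in a config file cannot silently fall
back to a default. The effective configuration is echoed into every output
directory by the CLI.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .annotate import AnnotationParams, QualityThresholds
from .preprocess import FilterSpec
from .roi import ROIParams
from .pipeline import PipelineConfig
from .simulate import AFDriverProfile, MorphologyModel, NoiseModel

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    pass


_SECTIONS = {
    "filter": FilterSpec,
    "annotation": AnnotationParams,
    "quality": QualityThresholds,
    "roi": ROIParams,
    "driver_profile": AFDriverProfile,
    "morphology": MorphologyModel,
    "noise": NoiseModel,
}
_SCALARS = {"seed": int, "neighbor_mode": str, "neighbor_radius_mm": float}


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Every tunable of the pipeline and simulator, with its default."""

    filter: FilterSpec = dataclasses.field(default_factory=FilterSpec)
    annotation: AnnotationParams = dataclasses.field(default_factory=AnnotationParams)
    quality: QualityThresholds = dataclasses.field(default_factory=QualityThresholds)
    roi: ROIParams = dataclasses.field(default_factory=ROIParams)
    driver_profile: AFDriverProfile = dataclasses.field(default_factory=AFDriverProfile)
    morphology: MorphologyModel = dataclasses.field(default_factory=MorphologyModel)
    noise: NoiseModel = dataclasses.field(default_factory=NoiseModel)
    seed: int = 0
    neighbor_mode: str = "structural"
    neighbor_radius_mm: float | None = None

    def pipeline(self) -> PipelineConfig:
        return PipelineConfig(
            filter=self.filter,
            annotation=self.annotation,
            quality=self.quality,
            roi=self.roi,
            neighbor_mode=self.neighbor_mode,
            neighbor_radius_mm=self.neighbor_radius_mm,
        )

    def to_dict(self) -> dict:
        out: dict = {}
        for name, cls in _SECTIONS.items():
            section = getattr(self, name)
            out[name] = {
                f.name: _jsonable(getattr(section, f.name)) for f in dataclasses.fields(cls)
            }
        for name in _SCALARS:
            out[name] = getattr(self, name)
        return out

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.to_dict(), sort_keys=True, indent=1) + "\n")
        return path


def _jsonable(v):
    if isinstance(v, tuple):
        return list(v)
    if isinstance(v, float) and v == float("inf"):
        return "inf"
    return v


def _build_section(cls, doc: dict, section: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(doc) - set(fields)
    if unknown:
        raise ConfigError(f"unknown keys in [{section}]: {sorted(unknown)}")
    kwargs = {}
    for k, v in doc.items():
        if isinstance(v, list):
            v = tuple(v)
        if v == "inf":
            v = float("inf")
        kwargs[k] = v
    return cls(**kwargs)


def load_config(path: str | Path | None = None, text: str | None = None) -> RunConfig:
    """Load a RunConfig from YAML (or JSON, a YAML subset)."""
    if text is None:
        if path is None:
            return RunConfig()
        text = Path(path).read_text()
    doc = yaml.safe_load(text) or {}
    if not isinstance(doc, dict):
        raise ConfigError("config document must be a mapping")
    unknown = set(doc) - set(_SECTIONS) - set(_SCALARS)
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    kwargs: dict = {}
    for name, cls in _SECTIONS.items():
        if name in doc:
            if not isinstance(doc[name], dict):
                raise ConfigError(f"section [{name}] must be a mapping")
            kwargs[name] = _build_section(cls, doc[name], name)
    for name in _SCALARS:
        if name in doc:
            kwargs[name] = doc[name]
    return RunConfig(**kwargs)
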