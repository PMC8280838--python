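"""Validated pipeline configuration (YAML), with strict unknown-key rejection.

One nested config object carries every threshold any stage consumes, so a
run's decisions are fully reproducible from its serialized config; a
canonical hash of the config travels with every output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .motif import ULK1_MOTIF
from .silac import SilacThresholds
from .synth import GeneratorConfig, TmtDynamics, REFERENCE_SITE_ID
from .tmt import TmtThresholds


class ConfigError(ValueError):
    """Configuration failed validation (unknown key, bad value)."""


@dataclass
class ProteinLevelConfig:
    min_sites: int = 3
    min_fraction: float = 0.8


@dataclass
class ConservationConfig:
    min_identity: float = 0.6


@dataclass
class ClusteringConfig:
    """Correlation clustering runs on the most variable profiles (the
    global pattern survey); ``n_most_variable=None`` clusters everything."""

    k: int = 6
    n_most_variable: int | None = 3000


@dataclass
class CurationConfig:
    """Reproducible manual curation: explicit site lists with reasons."""

    manual_include: list = field(default_factory=list)
    manual_exclude: dict = field(default_factory=dict)  # site_id -> reason
    control_peptides: list = field(default_factory=list)  # {label, sequence}


@dataclass
class PipelineConfig:
    localization_min_prob: float = 0.75
    motif: str = ULK1_MOTIF
    reference_site: str = REFERENCE_SITE_ID
    tmt_normalization: str = "anchored_to_DKO0"
    silac: SilacThresholds = field(default_factory=SilacThresholds)
    tmt: TmtThresholds = field(default_factory=TmtThresholds)
    protein_level: ProteinLevelConfig = field(default_factory=ProteinLevelConfig)
    conservation: ConservationConfig = field(default_factory=ConservationConfig)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    curation: CurationConfig = field(default_factory=CurationConfig)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)


_NESTED = {
    "silac": SilacThresholds,
    "tmt": TmtThresholds,
    "protein_level": ProteinLevelConfig,
    "conservation": ConservationConfig,
    "clustering": ClusteringConfig,
    "curation": CurationConfig,
    "generator": GeneratorConfig,
    "tmt_dynamics": TmtDynamics,
}


def _build(cls, data: Mapping[str, Any], path: str = ""):
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path or cls.__name__}: expected a mapping, got {type(data).__name__}")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"{path or cls.__name__}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        sub = _NESTED.get(key)
        if sub is not None and isinstance(value, Mapping):
            kwargs[key] = _build(sub, value, path=f"{path}{key}.")
        elif key == "starvation_rise" and isinstance(value, (list, tuple)):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path or cls.__name__}: {exc}") from exc


def config_from_dict(data: Mapping[str, Any] | None) -> PipelineConfig:
    return _build(PipelineConfig, data or {})


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML pipeline config; ``None`` gives all defaults."""
    if path is None:
        return PipelineConfig()
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data)


def config_to_dict(config: PipelineConfig) -> dict:
    # json round trip normalizes tuples to lists for YAML-safe output
    return json.loads(json.dumps(dataclasses.asdict(config)))


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=True)


def config_hash(config: PipelineConfig) -> str:
    """Canonical sha256 of the full configuration."""
    blob = json.dumps(config_to_dict(config), sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()
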