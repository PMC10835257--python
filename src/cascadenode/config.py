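"""Configuration loading and validation (YAML or JSON)."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .models import ModelSpec
from .pipelines import PipelineConfig

_CONFIG_KEYS = {f.name for f in dataclasses.fields(PipelineConfig)}
_MODEL_KEYS = {f.name for f in dataclasses.fields(ModelSpec)}


def config_to_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def config_from_dict(data: dict) -> PipelineConfig:
    """Build a validated PipelineConfig, rejecting unknown keys."""
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    data = dict(data)
    model = data.pop("model", None)
    if model is not None:
        bad = set(model) - _MODEL_KEYS
        if bad:
            raise ValueError(f"unknown model keys: {sorted(bad)}")
        data["model"] = ModelSpec(**model)
    return PipelineConfig(**data)


def load_config(path) -> PipelineConfig:
    """Read a pipeline configuration from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    return config_from_dict(data)


def dump_config(config: PipelineConfig, path) -> None:
    """Write the configuration to YAML (or JSON by extension)."""
    path = Path(path)
    data = config_to_dict(config)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
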