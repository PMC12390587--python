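"""YAML pipeline configuration with strict key validation.

The configuration mirrors :class:`handvein.pipeline.BenchmarkConfig` with
nested blocks for the synthetic generator, feature extraction and SVM
fusion.  Unknown keys are rejected before any computation, and the full
resolved configuration is embedded in every results bundle for
provenance.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .evaluation import SvmConfig
from .features import MCParams
from .pipeline import BenchmarkConfig
from .synth import RenderParams


class ConfigError(ValueError):
    pass


def _build(cls, data: dict, context: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{context}: expected a mapping, got {type(data).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(
            f"{context}: unknown keys {sorted(unknown)}; allowed: {sorted(fields)}"
        )
    kwargs = {}
    for key, value in data.items():
        ftype = fields[key].type
        if isinstance(value, dict) and key in _NESTED:
            kwargs[key] = _build(_NESTED[key], value, f"{context}.{key}")
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
        del ftype
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{context}: {exc}") from exc


_NESTED = {"render": RenderParams, "mc": MCParams, "svm": SvmConfig}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> BenchmarkConfig:
    """Load (or default) a benchmark configuration; rejects unknown keys."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        data.update(loaded)
    if overrides:
        data.update(overrides)
    return _build(BenchmarkConfig, data, "config")


def dump_config(config: BenchmarkConfig) -> str:
    return yaml.safe_dump(config.to_dict(), sort_keys=False)
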