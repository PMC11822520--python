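"""YAML loading/dumping for the package's flat config documents."""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, Type, TypeVar

import yaml

from .errors import ConfigurationError
from .pca import BaselineConfig
from .quality import QiConfig
from .synthetic import GeneratorConfig

__all__ = [
    "load_generator_config",
    "load_qi_config",
    "load_baseline_config",
    "dump_config",
]

T = TypeVar("T")


def _tupleize(value: Any) -> Any:
    if isinstance(value, list):
        return tuple(_tupleize(v) for v in value)
    return value


def _from_mapping(cls: Type[T], data: dict[str, Any], source: str) -> T:
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{source}: expected a key/value mapping")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigurationError(f"{source}: unknown keys {unknown}")
    return cls(**{k: _tupleize(v) for k, v in data.items()})


def _load(path: str | Path) -> dict[str, Any]:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def load_generator_config(path: str | Path) -> GeneratorConfig:
    return _from_mapping(GeneratorConfig, _load(path), str(path))


def load_qi_config(path: str | Path) -> QiConfig:
    return _from_mapping(QiConfig, _load(path), str(path))


def load_baseline_config(path: str | Path) -> BaselineConfig:
    return _from_mapping(BaselineConfig, _load(path), str(path))


def _listify(value: Any) -> Any:
    if isinstance(value, tuple):
        return [_listify(v) for v in value]
    if isinstance(value, dict):
        return {k: _listify(v) for k, v in value.items()}
    return value


def dump_config(cfg: Any, path: str | Path) -> Path:
    """Write any of the package's config dataclasses as flat YAML."""
    path = Path(path)
    data = _listify(dataclasses.asdict(cfg))
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
    return path
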