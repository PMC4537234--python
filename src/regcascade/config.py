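"""Flat key-value configuration files for the command line.

Format: one ``key = value`` pair per line; blank lines and ``#``
comments ignored.  Keys map directly onto :class:`SyntheticConfig` or
:class:`RunConfig` fields; values are coerced from the field's declared
type.  An unknown key or an uncoercible value raises
:class:`ConfigError` naming the key.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, Type

from .cascade import RunConfig
from .core import ValidationError
from .simulate import SyntheticConfig


class ConfigError(ValueError):
    pass


def parse_kv_file(path: str | Path) -> dict[str, str]:
    pairs: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if not key:
                raise ConfigError(f"{path}:{lineno}: empty key")
            if key in pairs:
                raise ConfigError(f"{path}:{lineno}: duplicate key {key!r}")
            pairs[key] = value
    return pairs


def _coerce(key: str, value: str, typ: Any) -> Any:
    text = str(typ)
    try:
        if typ is bool or "bool" in text:
            lowered = value.lower()
            if lowered in ("true", "1", "yes"):
                return True
            if lowered in ("false", "0", "no"):
                return False
            raise ValueError(value)
        if typ is int or text in ("int", "int | None"):
            return int(value)
        if typ is float or "float" in text:
            return float(value)
        if value.lower() in ("none", ""):
            return None
        return value
    except ValueError as exc:
        raise ConfigError(f"invalid value {value!r} for key {key!r}") from exc


def build_dataclass(cls: Type, pairs: dict[str, str], overrides: dict[str, Any] | None = None):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs: dict[str, Any] = {}
    for key, value in pairs.items():
        if key not in fields:
            raise ConfigError(f"unknown configuration key {key!r}")
        kwargs[key] = _coerce(key, value, fields[key].type)
    for key, value in (overrides or {}).items():
        if value is not None:
            kwargs[key] = value
    missing = [
        name for name, f in fields.items()
        if name not in kwargs
        and f.default is dataclasses.MISSING
        and f.default_factory is dataclasses.MISSING  # type: ignore[misc]
    ]
    if missing:
        raise ConfigError(f"missing required key(s): {', '.join(missing)}")
    try:
        return cls(**kwargs)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def load_synthetic_config(path: str | Path, **overrides) -> SyntheticConfig:
    return build_dataclass(SyntheticConfig, parse_kv_file(path), overrides)


def load_run_config(path: str | Path, **overrides) -> RunConfig:
    return build_dataclass(RunConfig, parse_kv_file(path), overrides)
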