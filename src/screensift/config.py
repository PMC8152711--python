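"""Flat ``key = value`` configuration files mirroring :class:`WorkflowConfig`."""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path
from typing import get_args, get_origin, Optional, Union

from .engine import WorkflowConfig


def _coerce(raw: str, target_type):
    origin = get_origin(target_type)
    if origin is Union:  # Optional[...] - take the first non-None member
        for arg in get_args(target_type):
            if arg is type(None):
                continue
            if raw.lower() in ("none", ""):
                return None
            return _coerce(raw, arg)
    if target_type is bool:
        if raw.lower() in ("true", "1", "yes", "on"):
            return True
        if raw.lower() in ("false", "0", "no", "off"):
            return False
        raise ValueError(f"not a boolean: {raw!r}")
    if target_type is int:
        return int(raw)
    if target_type is float:
        return float(raw)
    import collections.abc

    if origin in (list, tuple, collections.abc.Sequence) or target_type in (list, tuple):
        return [int(x) for x in raw.replace(",", " ").split()]
    return raw


def parse_config(path: str | Path) -> WorkflowConfig:
    """Read a flat config file; unknown keys are an error, omitted keys default."""
    known = {f.name: f.type for f in fields(WorkflowConfig)}
    # dataclass field types arrive as strings under future annotations; resolve them
    resolved = {f.name: f for f in fields(WorkflowConfig)}
    values = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
            key, raw = (part.strip() for part in line.split("=", 1))
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            values[key] = raw
    kwargs = {}
    hints = _type_hints()
    for key, raw in values.items():
        kwargs[key] = _coerce(raw, hints[key])
    return WorkflowConfig(**kwargs)


def _type_hints():
    import typing

    return typing.get_type_hints(WorkflowConfig)


def write_config(config: WorkflowConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for f in fields(WorkflowConfig):
            val = getattr(config, f.name)
            if isinstance(val, (list, tuple)):
                val = " ".join(str(v) for v in val)
            fh.write(f"{f.name} = {val}\n")
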