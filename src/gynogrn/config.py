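"""Run configuration: a JSON config file validated against a schema.

A :class:`RunConfig` bundles everything a command-line run needs —
model variant, extra node clamps, the (CK, SPT) input condition, output
paths, a seed for synthetic commands and verbosity.  Files are JSON,
validated with pydantic; :func:`config_schema` exports the JSON Schema
so external tooling can validate configs without importing this
package.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Tuple

from pydantic import BaseModel, ConfigDict, Field, ValidationError, \
    field_validator

from .grn import VARIANTS

__all__ = ["ConfigError", "RunConfig", "load_config", "config_schema"]


class ConfigError(ValueError):
    """Invalid run configuration (bad JSON, unknown field, bad value)."""


class RunConfig(BaseModel):
    """Validated run configuration."""

    model_config = ConfigDict(extra="forbid")

    variant: str = "core_medial"
    clamps: List[Tuple[str, int]] = Field(default_factory=list)
    inputs: Tuple[int, int] = (1, 1)  # (CK, SPT)
    out: Optional[str] = None
    outdir: Optional[str] = None
    seed: Optional[int] = None
    verbosity: int = 0

    @field_validator("variant")
    @classmethod
    def _known_variant(cls, v):
        if v not in VARIANTS:
            raise ValueError(f"unknown variant {v!r}; expected one of "
                             f"{VARIANTS}")
        return v

    @field_validator("clamps")
    @classmethod
    def _binary_clamps(cls, v):
        for node, value in v:
            if value not in (0, 1):
                raise ValueError(f"clamp value for {node!r} must be 0 or 1")
        return v

    @field_validator("inputs")
    @classmethod
    def _binary_inputs(cls, v):
        if any(b not in (0, 1) for b in v):
            raise ValueError("inputs must be bits (CK, SPT)")
        return v


def load_config(path) -> RunConfig:
    """Load and validate a JSON config file; raises :class:`ConfigError`."""
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    try:
        return RunConfig.model_validate(payload)
    except ValidationError as exc:
        raise ConfigError(f"invalid config {path}: {exc}") from exc


def config_schema() -> dict:
    """The published JSON Schema for config files."""
    return RunConfig.model_json_schema()
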