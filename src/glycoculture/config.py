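"""Run configuration: a small YAML document validated against a fixed key
set (unknown keys are rejected so typos fail loudly)."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .bioprocess import EPO_SPECIFIC_ACTIVITY

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """Options shared by the analysis entry points."""

    input_path: str | None = None
    column_map: dict[str, str] = field(default_factory=dict)
    aliases: bool = True
    specific_activity: float = EPO_SPECIFIC_ACTIVITY  # U/µg
    reference_target: str = "PDHA2"
    reference_copies: int = 2
    ratio_decimals: int = 4
    pct_decimals: int = 2
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.specific_activity <= 0:
            raise ConfigError("specific_activity must be positive")
        if self.reference_copies < 1:
            raise ConfigError("reference_copies must be >= 1")


def load_config(path) -> RunConfig:
    """Load a YAML run configuration; unknown keys raise ``ConfigError``."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return RunConfig(**raw)
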