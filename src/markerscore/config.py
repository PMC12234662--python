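"""Run configuration: defaults, YAML loading, validation."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml


class ConfigError(ValueError):
    """Invalid or unknown configuration keys/values."""


@dataclass
class RunConfig:
    """Effective configuration of one pipeline run.

    All defaults are materialized here and echoed verbatim into the run
    report, so a report always documents the full configuration.
    """

    # paths
    counts: Optional[str] = None
    features: Optional[str] = None
    barcodes: Optional[str] = None
    clusters: Optional[str] = None
    markers: Optional[str] = None
    ontology: Optional[str] = None
    truth: Optional[str] = None
    outdir: str = "markerscore_out"

    # scope
    species: str = "human"
    tissue: Optional[str] = None
    category: str = "physiological"

    # parameters
    max_n_marker: Optional[int] = 30
    log2fc_threshold: Optional[float] = 1.0
    quantile: float = 0.75
    allow_unknown: bool = False
    scale_factor: float = 1e4
    clip: float = 10.0
    resolution: str = "cluster"  # or "cell"
    se_provided: bool = False
    top_k: int = 3
    seed: int = 0
    verbosity: str = "info"

    def __post_init__(self):
        if self.resolution not in ("cluster", "cell"):
            raise ConfigError(
                f"resolution must be 'cluster' or 'cell', got {self.resolution!r}"
            )
        if not (0.0 <= self.quantile <= 1.0):
            raise ConfigError(f"quantile must be in [0,1], got {self.quantile}")
        if self.max_n_marker is not None and self.max_n_marker < 1:
            raise ConfigError(
                f"max_n_marker must be >= 1, got {self.max_n_marker}"
            )

    @classmethod
    def field_names(cls) -> set:
        return {f.name for f in dataclasses.fields(cls)}

    @classmethod
    def from_dict(cls, values: dict) -> "RunConfig":
        unknown = set(values) - cls.field_names()
        if unknown:
            raise ConfigError(f"unknown configuration key(s): {sorted(unknown)}")
        return cls(**values)

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        """Load a YAML key-value file; keyword overrides win over the file."""
        with open(path, encoding="utf-8") as fh:
            values = yaml.safe_load(fh) or {}
        if not isinstance(values, dict):
            raise ConfigError(f"{path}: expected a mapping of keys to values")
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(values)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
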