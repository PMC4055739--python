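"""Pipeline configuration: YAML in, validated dataclass out."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from odobenus.io import DataError


class ConfigError(DataError):
    """Raised for malformed or out-of-range configuration."""


@dataclass
class PipelineConfig:
    out_dir: str = "results"
    morpho_csv: str | None = None
    fasta: str | None = None
    metadata_csv: str | None = None
    alpha: float = 0.05
    bonferroni_m: int = 9
    pca_scaling: str = "correlation"
    dfa_variance_threshold: float = 0.9
    min_group_size: int = 5
    epsilon: int = 0
    truncate_to: int | None = None
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha {self.alpha} outside (0, 1)")
        if self.bonferroni_m < 1:
            raise ConfigError("bonferroni_m must be >= 1")
        if self.pca_scaling not in ("correlation", "covariance"):
            raise ConfigError(f"unknown pca_scaling {self.pca_scaling!r}")
        if not 0 < self.dfa_variance_threshold <= 1:
            raise ConfigError("dfa_variance_threshold outside (0, 1]")
        if self.epsilon < 0:
            raise ConfigError("epsilon must be >= 0")
        if self.truncate_to is not None and self.truncate_to < 1:
            raise ConfigError("truncate_to must be positive")
        if self.fasta and not self.metadata_csv:
            raise ConfigError("fasta input requires metadata_csv")
        return self

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a YAML config; defaults applied, unknown keys rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    try:
        cfg = PipelineConfig(**raw)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from None
    return cfg.validate()


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
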