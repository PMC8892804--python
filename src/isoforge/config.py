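"""Configuration objects holding every tunable threshold, with YAML round-trip.

Defaults are the study conditions: >1 CPM transcript filter, >=95% downstream-A
intrapriming flag over 20 nt, 50 candidate ORFs of >=50 nt, 0.99 per-upstream-ATG
score decay, 1-4 kb / >=3 CPM / polyA high-confidence gene window, 25 CPM rescue
threshold, >90% dominant and >30% co-expression fractions, trypsin with up to 2
missed cleavages and a 7-50 AA detectability window.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

__all__ = [
    "ConfigError",
    "FilterConfig",
    "OrfCallConfig",
    "HighConfidenceConfig",
    "InferenceConfig",
    "PipelineConfig",
]


class ConfigError(ValueError):
    """Invalid configuration value or file."""


@dataclass
class FilterConfig:
    """Transcript-level pre-filters applied before ORF calling."""

    min_cpm: float = 1.0  # strictly-greater-than retention
    intrapriming_window_nt: int = 20
    intrapriming_a_fraction: float = 0.95

    def __post_init__(self) -> None:
        if self.min_cpm < 0:
            raise ConfigError("min_cpm must be non-negative")
        if self.intrapriming_window_nt <= 0:
            raise ConfigError("intrapriming window must be positive")
        if not 0 < self.intrapriming_a_fraction <= 1:
            raise ConfigError("intrapriming A-fraction must be in (0, 1]")


@dataclass
class OrfCallConfig:
    min_orf_len_nt: int = 50
    max_candidates: int = 50
    high_score_cutoff: float = 0.9
    upstream_atg_penalty: float = 0.99  # multiplicative decay per upstream ATG
    annotated_start_override: bool = True
    natural_sort: bool = False  # base-accession choice: plain byte order by default

    def __post_init__(self) -> None:
        if self.min_orf_len_nt <= 0 or self.max_candidates <= 0:
            raise ConfigError("ORF length and candidate limits must be positive")
        if not 0 < self.upstream_atg_penalty <= 1:
            raise ConfigError("upstream_atg_penalty must be in (0, 1]")


@dataclass
class HighConfidenceConfig:
    min_len_kb: float = 1.0
    max_len_kb: float = 4.0
    min_gene_cpm: float = 3.0
    require_polya: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_len_kb < self.max_len_kb:
            raise ConfigError("require 0 < min_len_kb < max_len_kb")


@dataclass
class InferenceConfig:
    rescue_cpm_threshold: float = 25.0
    dominant_fraction: float = 0.90
    coexpression_fraction: float = 0.30
    protease: str = "trypsin"
    missed_cleavages: int = 2
    peptide_len_min: int = 7
    peptide_len_max: int = 50
    equate_il: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.coexpression_fraction < self.dominant_fraction <= 1:
            raise ConfigError(
                "require 0 < coexpression_fraction < dominant_fraction <= 1"
            )
        if self.missed_cleavages < 0:
            raise ConfigError("missed_cleavages must be non-negative")
        if not 0 < self.peptide_len_min <= self.peptide_len_max:
            raise ConfigError("require 0 < peptide_len_min <= peptide_len_max")


@dataclass
class PipelineConfig:
    """Aggregate of all stage configurations; YAML (de)serializable."""

    filters: FilterConfig = field(default_factory=FilterConfig)
    orf_calling: OrfCallConfig = field(default_factory=OrfCallConfig)
    high_confidence: HighConfidenceConfig = field(default_factory=HighConfidenceConfig)
    inference: InferenceConfig = field(default_factory=InferenceConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        sections = {
            "filters": FilterConfig,
            "orf_calling": OrfCallConfig,
            "high_confidence": HighConfidenceConfig,
            "inference": InferenceConfig,
        }
        kwargs = {}
        for name, klass in sections.items():
            block = raw.get(name, {})
            known = {f.name for f in dataclasses.fields(klass)}
            unknown = set(block) - known
            if unknown:
                raise ConfigError(f"unknown keys in '{name}': {sorted(unknown)}")
            kwargs[name] = klass(**block)
        return cls(**kwargs)

    def to_yaml(self, path: Optional[str | Path] = None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text
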