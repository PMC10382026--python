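"""Pipeline configuration with lossless YAML round-tripping.

Holds every numeric setting the workflow depends on (marker gates, DE
alpha, enrichment top-n, elimination minimum size, Cox alpha, GSEA
permutations, seeds).  Unknown keys are rejected — no silent defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .exceptions import ConfigurationError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    marker_min_pct: float = 0.1
    marker_logfc: float = 0.25
    de_alpha: float = 0.05
    enrichment_top_n: int = 10
    list_top_genes: int = 500
    elimination_min_size: int = 3
    cox_alpha: float = 0.05
    gsea_n_perm: int = 1000
    gsea_weight: float = 1.0
    classifier_distance: str = "euclidean"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.marker_min_pct <= 1:
            raise ConfigurationError("marker_min_pct must lie in [0, 1]")
        for name in ("de_alpha", "cox_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigurationError(f"{name} must lie in (0, 1)")
        if self.elimination_min_size < 3:
            raise ConfigurationError("elimination_min_size must be >= 3")
        if self.enrichment_top_n < 1 or self.list_top_genes < 1:
            raise ConfigurationError("top-n settings must be >= 1")
        if self.gsea_n_perm < 100:
            raise ConfigurationError("gsea_n_perm must be >= 100")
        if self.classifier_distance not in ("correlation", "euclidean"):
            raise ConfigurationError("classifier_distance must be 'correlation' or 'euclidean'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        data = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)
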