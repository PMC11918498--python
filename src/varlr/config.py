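"""Run configuration: paths, thresholds, weights; YAML round-trip and hashing."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import yaml

from .errors import ConfigError
from .genotype import GenotypeConfig
from .io import config_hash
from .scoring import WeightConfig

__all__ = ["RunConfig"]

_REQUIRED = ("ontology", "gene_annotations", "disease_annotations", "disease_genes")


@dataclass
class RunConfig:
    ontology: str = ""
    gene_annotations: str = ""
    disease_annotations: str = ""
    disease_genes: str = ""
    vcf: Optional[str] = None
    ped: Optional[str] = None
    phenotypes: Optional[str] = None
    artifact_bed: Optional[str] = None
    sidecar: Optional[str] = None
    outdir: str = "out"
    case_id: str = "case"
    phenotype_source: str = "manual"
    genotype: GenotypeConfig = field(default_factory=GenotypeConfig)
    weights: WeightConfig = field(default_factory=WeightConfig)
    info_keys: Dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, data: Dict, **overrides) -> "RunConfig":
        data = dict(data)
        data.update({k: v for k, v in overrides.items() if v is not None})
        if isinstance(data.get("genotype"), dict):
            data["genotype"] = GenotypeConfig(**data["genotype"])
        if isinstance(data.get("weights"), dict):
            data["weights"] = WeightConfig(**data["weights"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data, **overrides)

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())

    def validate_paths(self, need_case: bool = True) -> None:
        missing = [k for k in _REQUIRED if not getattr(self, k)]
        if missing:
            raise ConfigError(f"missing required config paths: {missing}")
        paths = [getattr(self, k) for k in _REQUIRED]
        if need_case:
            for k in ("vcf", "ped", "phenotypes"):
                if not getattr(self, k):
                    raise ConfigError(f"missing required case input: {k}")
                paths.append(getattr(self, k))
        for k in ("artifact_bed", "sidecar"):
            if getattr(self, k):
                paths.append(getattr(self, k))
        for p in paths:
            if not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")
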