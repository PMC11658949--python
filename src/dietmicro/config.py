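"""Run configuration: one flat key-value (YAML) file, every analysis constant
defaulted to the study design value and overridable."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .associations import DEFAULT_COVARIATES


@dataclass
class PipelineConfig:
    # input tables (TSV unless noted); None means "use the generated cohort
    # in the working directory" for file inputs, or the packaged defaults for
    # the serving map and index definitions
    ffq: str | None = None
    genus_table: str | None = None          # TSV (samples x genera) or BIOM v1 JSON
    covariates: str | None = None
    biomarkers: str | None = None
    pathways: str | None = None
    serving_map: str | None = None
    index_definitions: str | None = None

    # analysis constants
    prevalence_threshold: float = 0.90      # genera kept if present in > this fraction
    depth_threshold: int = 10_000           # samples dropped strictly below
    train_fraction: float = 0.70
    cv_folds: int = 10
    fdr_cutoff: float = 0.10
    quintile_count: int = 5
    seed: int = 0
    pair_cv_folds: bool = True              # co-twins share a CV fold
    covariate_list: tuple = field(default_factory=lambda: tuple(DEFAULT_COVARIATES))

    def validate(self) -> "PipelineConfig":
        for name in ("prevalence_threshold", "train_fraction", "fdr_cutoff"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.depth_threshold < 0:
            raise ValueError("depth_threshold must be non-negative")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")
        if self.quintile_count < 2:
            raise ValueError("quintile_count must be at least 2")
        if int(self.seed) != self.seed:
            raise ValueError("seed must be an integer")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        if "covariate_list" in raw:
            raw["covariate_list"] = tuple(raw["covariate_list"])
        return cls(**raw).validate()

    def to_dict(self) -> dict:
        out = {f.name: getattr(self, f.name) for f in fields(self)}
        out["covariate_list"] = list(out["covariate_list"])
        return out
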