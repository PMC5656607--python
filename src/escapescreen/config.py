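"""Pipeline configuration: thresholds, paths and the random seed.

Loaded from a flat YAML mapping; unknown keys are rejected so typos in a
config file fail loudly instead of silently using a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import yaml

from .screen import ScreenConfig
from .types import ParameterError


@dataclass
class PipelineConfig:
    """Thresholds and file paths for a full pipeline run."""

    # screen thresholds
    min_power: float = 0.9
    ccf_prog_min: float = 0.5
    ccf_reg_max: float = 0.05
    min_nonsilent: int = 2
    min_callers: int = 2
    # LOH
    loh_min_covered_fraction: float = 1.0
    loh_rule: str = "any_sample"
    # neoantigen percentile-rank thresholds
    strong_rank: float = 0.5
    weak_rank: float = 2.0
    # expression score pseudocount
    expression_pseudocount: float = 1.0
    # randomness
    seed: int = 0
    # file paths (optional; CLI flags override)
    variants: Optional[str] = None
    segments: Optional[str] = None
    samples: Optional[str] = None
    clinical: Optional[str] = None
    gene_loci: Optional[str] = None
    out_dir: str = "escape_screen_out"

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_power <= 1.0):
            raise ParameterError("min_power must be in [0,1]")
        if not (0.0 <= self.ccf_reg_max <= self.ccf_prog_min <= 1.0):
            raise ParameterError("need 0 <= ccf_reg_max <= ccf_prog_min <= 1")
        if not (0.0 < self.loh_min_covered_fraction <= 1.0):
            raise ParameterError("loh_min_covered_fraction must be in (0,1]")
        if not (0.0 <= self.strong_rank <= self.weak_rank <= 100.0):
            raise ParameterError("need 0 <= strong_rank <= weak_rank <= 100")
        if self.expression_pseudocount < 0:
            raise ParameterError("expression_pseudocount must be >= 0")

    @property
    def screen(self) -> ScreenConfig:
        return ScreenConfig(
            min_power=self.min_power,
            ccf_prog_min=self.ccf_prog_min,
            ccf_reg_max=self.ccf_reg_max,
            min_nonsilent=self.min_nonsilent,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ParameterError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ParameterError(f"unknown config keys: {unknown}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
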