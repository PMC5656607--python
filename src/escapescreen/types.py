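"""Domain types shared across the pipeline.

Coordinates are 1-based inclusive on disk (MAF/SEG convention) and are
converted to half-open intervals only inside overlap arithmetic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import FrozenSet, Tuple


class FormatError(ValueError):
    """A file or row violates the expected tabular format."""


class ParameterError(ValueError):
    """A numeric argument is outside its documented domain."""


class DiseaseState(str, enum.Enum):
    BASELINE = "baseline"
    REGRESSION = "regression"
    PROGRESSION = "progression"


class Effect(str, enum.Enum):
    SILENT = "silent"
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE_SITE = "splice_site"
    OTHER_NONSILENT = "other_nonsilent"


#: Protein-altering effect classes ("non-silent" in the screen's sense).
NONSILENT_EFFECTS = frozenset(
    {
        Effect.MISSENSE,
        Effect.NONSENSE,
        Effect.FRAMESHIFT,
        Effect.SPLICE_SITE,
        Effect.OTHER_NONSILENT,
    }
)


class ResponseGroup(str, enum.Enum):
    RESPONDER = "responder"
    NONRESPONDER = "nonresponder"
    LONG_TERM_SURVIVOR = "long_term_survivor"


#: (chrom, pos, ref, alt) — the identity of a variant within one patient.
VariantKey = Tuple[str, int, str, str]


@dataclass(frozen=True)
class Sample:
    """One tumor biopsy with its clinical timepoint and purity/ploidy."""

    sample_id: str
    patient_id: str
    timepoint_days: int
    disease_state: DiseaseState
    purity: float
    ploidy: float

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise ParameterError(f"purity must be in (0,1], got {self.purity}")
        if self.ploidy <= 0:
            raise ParameterError(f"ploidy must be positive, got {self.ploidy}")


@dataclass(frozen=True)
class VariantCall:
    """One somatic variant in one sample, with read counts and effect class."""

    patient_id: str
    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    ref_count: int
    alt_count: int
    gene: str
    effect: Effect
    callers: FrozenSet[str] = frozenset()

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ParameterError(f"pos must be >= 1 (1-based), got {self.pos}")
        if self.alt_count < 0 or self.ref_count < 0:
            raise ParameterError("read counts must be non-negative")
        if not self.ref or not self.alt:
            raise ParameterError("ref and alt alleles must be non-empty")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def depth(self) -> int:
        return self.alt_count + self.ref_count


@dataclass(frozen=True)
class Segment:
    """Allele-specific copy-number interval (1-based inclusive)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    total_cn: float
    major_cn: int
    minor_cn: int
    copy_ratio: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ParameterError(
                f"segment start {self.start} > end {self.end} ({self.sample_id} {self.chrom})"
            )
        if self.minor_cn > self.major_cn:
            raise ParameterError(
                f"minor_cn {self.minor_cn} > major_cn {self.major_cn}"
            )
        if self.minor_cn < 0 or self.total_cn < 0:
            raise ParameterError("copy numbers must be non-negative")
        if self.copy_ratio <= 0:
            raise ParameterError("copy_ratio must be positive")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneLocus:
    """Genomic interval of a gene (1-based inclusive)."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ParameterError(f"locus start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ClinicalRecord:
    """Response group plus right-censored overall survival for one patient."""

    patient_id: str
    response_group: ResponseGroup
    os_days: float
    os_event: int

    def __post_init__(self) -> None:
        if self.os_days < 0:
            raise ParameterError(f"os_days must be >= 0, got {self.os_days}")
        if self.os_event not in (0, 1):
            raise ParameterError(f"os_event must be 0 or 1, got {self.os_event}")


# Default gene panel for LOH calling: antigen presentation and IFN-gamma
# pathway members recurrently inspected in checkpoint-blockade resistance.
DEFAULT_GENE_PANEL = (
    "B2M",
    "JAK1",
    "JAK2",
    "IFNGR1",
    "IFNGR2",
    "STAT1",
    "STAT2",
    "TAP1",
    "TAP2",
)
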