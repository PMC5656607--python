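"""Binder classification from MHC-I percentile ranks and neoantigen load.

Percentile rank is the fraction of random natural peptides predicted to
bind the HLA allele more strongly than the query peptide; lower rank
means stronger binding.  A mutant peptide is a strong binder at rank
< 0.5 and a weak binder at rank in [0.5, 2), in both cases only if the
matched wild-type peptide is itself a non-binder (rank > 2) — otherwise
the peptide is not a neoantigen.  Neoantigen load counts mutated genes
with at least one strong or weak binder, per patient.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, List

import pandas as pd

from .types import ParameterError

__all__ = [
    "BinderClass",
    "NeoantigenRecord",
    "classify_binder",
    "neoantigen_load",
    "classify_rank_table",
]

STRONG_RANK = 0.5
WEAK_RANK = 2.0
WT_NONBINDER_RANK = 2.0


class BinderClass(str, enum.Enum):
    STRONG = "strong"
    WEAK = "weak"
    NONE = "none"


def classify_binder(mut_rank: float, wt_rank: float) -> BinderClass:
    """Classify one (mutant, wild-type) percentile-rank pair."""
    for name, rank in (("mut_rank", mut_rank), ("wt_rank", wt_rank)):
        if not (0.0 <= rank <= 100.0):
            raise ParameterError(f"{name} must be a percentile in [0,100], got {rank}")
    if wt_rank <= WT_NONBINDER_RANK:
        return BinderClass.NONE
    if mut_rank < STRONG_RANK:
        return BinderClass.STRONG
    if mut_rank < WEAK_RANK:
        return BinderClass.WEAK
    return BinderClass.NONE


@dataclass(frozen=True)
class NeoantigenRecord:
    patient_id: str
    gene: str
    peptide: str
    hla_allele: str
    mut_rank: float
    wt_rank: float
    binder_class: BinderClass = field(default=BinderClass.NONE)

    def __post_init__(self) -> None:
        expected = classify_binder(self.mut_rank, self.wt_rank)
        if self.binder_class != expected:
            object.__setattr__(self, "binder_class", expected)

    @classmethod
    def from_ranks(cls, patient_id, gene, peptide, hla_allele, mut_rank, wt_rank):
        return cls(
            patient_id, gene, peptide, hla_allele, mut_rank, wt_rank,
            classify_binder(mut_rank, wt_rank),
        )


def neoantigen_load(records: Iterable[NeoantigenRecord]) -> int:
    """Number of distinct genes with at least one strong or weak binder."""
    genes = {
        r.gene
        for r in records
        if r.binder_class in (BinderClass.STRONG, BinderClass.WEAK)
    }
    return len(genes)


def classify_rank_table(df: pd.DataFrame) -> List[NeoantigenRecord]:
    """Build classified records from a rank table.

    Expects columns patient_id, gene, peptide, hla_allele, mut_rank, wt_rank.
    """
    required = ["patient_id", "gene", "peptide", "hla_allele", "mut_rank", "wt_rank"]
    for col in required:
        if col not in df.columns:
            raise ParameterError(f"rank table missing column '{col}'")
    return [
        NeoantigenRecord.from_ranks(
            row.patient_id, row.gene, row.peptide, row.hla_allele,
            float(row.mut_rank), float(row.wt_rank),
        )
        for row in df.itertuples()
    ]
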