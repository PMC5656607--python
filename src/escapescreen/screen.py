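"""Longitudinal resistance-driver screen.

A gene is a candidate acquired-resistance driver for a patient when,
across that patient's serial biopsies:

(a) it carries at least ``min_nonsilent`` distinct non-silent variants
    that are adequately powered (detection power >= ``min_power`` in
    every sample, so absence of reads is informative);
(b) each such variant is dominant in at least one progression biopsy —
    its 95% CI upper bound reaches ``ccf_prog_min`` — while its CCF point
    estimate stays at or below ``ccf_reg_max`` in every baseline and
    regression biopsy (progression-exclusivity, evaluated per variant
    because sibling escape subclones can each carry their own lesion in
    different biopsies);
(c) the gene is under LOH in every progression biopsy in which one of
    those variants is dominant, so the mutant allele is hemizygous where
    it sweeps.

The screen requires at least one progression and one non-progression
biopsy; it is a longitudinal design and is an error to run otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Set, Tuple

from .ccf import CcfEstimate
from .consensus import is_nonsilent
from .loh import LohCall
from .types import DiseaseState, ParameterError, Sample, VariantCall, VariantKey

logger = logging.getLogger(__name__)

__all__ = ["ScreenConfig", "ScreenHit", "ScreenInapplicableError", "power_filter", "screen_patient"]


class ScreenInapplicableError(ValueError):
    """The patient lacks the longitudinal structure the screen requires."""


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the resistance screen.

    ``ccf_prog_min`` (dominance) and ``ccf_reg_max`` (absence while
    responding) are the smallest thresholds consistent with the observed
    escape-subclone CCFs (0.74/0.55 dominant, 1% leakage elsewhere).
    """

    min_power: float = 0.9
    ccf_prog_min: float = 0.5
    ccf_reg_max: float = 0.05
    min_nonsilent: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_power <= 1.0):
            raise ParameterError("min_power must be in [0,1]")
        if not (0.0 <= self.ccf_reg_max <= self.ccf_prog_min <= 1.0):
            raise ParameterError("need 0 <= ccf_reg_max <= ccf_prog_min <= 1")
        if self.min_nonsilent < 1:
            raise ParameterError("min_nonsilent must be >= 1")


@dataclass(frozen=True)
class ScreenHit:
    patient_id: str
    gene: str
    n_nonsilent: int
    loh_in_progression: bool
    max_ccf_progression: float
    max_ccf_nonprogression: float
    passing_variants: Tuple[VariantKey, ...]


def power_filter(
    estimates: Sequence[CcfEstimate],
    sample_ids: Sequence[str],
    min_power: float = 0.9,
) -> Set[VariantKey]:
    """Variants with detection power >= ``min_power`` in every sample.

    Every variant must have an estimate in every sample; a missing
    (variant, sample) pair is an error naming it.
    """
    by_variant: Dict[VariantKey, Dict[str, float]] = {}
    for est in estimates:
        by_variant.setdefault(est.key, {})[est.sample_id] = est.power
    kept: Set[VariantKey] = set()
    for key, powers in by_variant.items():
        for sid in sample_ids:
            if sid not in powers:
                raise ParameterError(f"missing power for variant {key} in sample {sid}")
        if all(powers[sid] >= min_power for sid in sample_ids):
            kept.add(key)
    logger.info(
        "power filter: %d/%d variants adequately powered (min_power=%.2f)",
        len(kept), len(by_variant), min_power,
    )
    return kept


def screen_patient(
    estimates: Sequence[CcfEstimate],
    variants: Sequence[VariantCall],
    loh_calls: Sequence[LohCall],
    samples: Sequence[Sample],
    config: ScreenConfig = ScreenConfig(),
) -> List[ScreenHit]:
    """Run the resistance screen for one patient.

    ``estimates`` must cover every (variant, sample) pair (force-called
    matrix); ``loh_calls`` are per (sample, gene); ``variants`` supply
    gene and effect annotation for each variant key.
    """
    patient_ids = {s.patient_id for s in samples}
    if len(patient_ids) != 1:
        raise ParameterError(f"screen_patient expects one patient, got {sorted(patient_ids)}")
    patient_id = patient_ids.pop()

    prog = [s.sample_id for s in samples if s.disease_state == DiseaseState.PROGRESSION]
    nonprog = [s.sample_id for s in samples if s.disease_state != DiseaseState.PROGRESSION]
    if not prog or not nonprog:
        raise ScreenInapplicableError(
            f"patient {patient_id}: the screen needs >=1 progression and >=1 "
            f"non-progression sample (got {len(prog)} and {len(nonprog)})"
        )
    sample_ids = [s.sample_id for s in samples]

    gene_of: Dict[VariantKey, str] = {}
    effect_of: Dict[VariantKey, object] = {}
    for v in variants:
        gene_of.setdefault(v.key, v.gene)
        effect_of.setdefault(v.key, v.effect)

    est_by: Dict[Tuple[VariantKey, str], CcfEstimate] = {
        (e.key, e.sample_id): e for e in estimates
    }
    powered = power_filter(estimates, sample_ids, min_power=config.min_power)

    loh_by: Dict[Tuple[str, str], bool] = {
        (c.sample_id, c.gene): c.loh for c in loh_calls
    }

    per_gene: Dict[str, List[Tuple[VariantKey, Set[str], float, float]]] = {}
    for key in powered:
        if key not in gene_of or not is_nonsilent(effect_of[key]):
            continue
        # dominance on the CI upper bound: a variant counts as dominant in a
        # progression biopsy when its interval reaches ccf_prog_min
        dominant_in = {
            sid for sid in prog
            if est_by[(key, sid)].ci_high >= config.ccf_prog_min
        }
        max_prog = max(est_by[(key, sid)].ccf for sid in prog)
        max_nonprog = max(est_by[(key, sid)].ccf for sid in nonprog)
        exclusive = bool(dominant_in) and max_nonprog <= config.ccf_reg_max
        if exclusive:
            per_gene.setdefault(gene_of[key], []).append(
                (key, dominant_in, max_prog, max_nonprog)
            )

    hits: List[ScreenHit] = []
    for gene, passing in per_gene.items():
        if len(passing) < config.min_nonsilent:
            continue
        dominant_samples = set().union(*(d for _, d, _, _ in passing))
        loh_ok = all(loh_by.get((sid, gene), False) for sid in dominant_samples)
        if not loh_ok:
            continue
        hits.append(
            ScreenHit(
                patient_id=patient_id,
                gene=gene,
                n_nonsilent=len(passing),
                loh_in_progression=True,
                max_ccf_progression=max(mp for _, _, mp, _ in passing),
                max_ccf_nonprogression=max(mn for _, _, _, mn in passing),
                passing_variants=tuple(sorted(k for k, _, _, _ in passing)),
            )
        )
    hits.sort(key=lambda h: -h.max_ccf_progression)
    logger.info("screen for patient %s: %d hit(s)", patient_id, len(hits))
    return hits
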