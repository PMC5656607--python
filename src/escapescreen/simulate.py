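"""Synthetic longitudinal and cross-sectional tumor cohorts.

The generator emulates the data structures the analysis consumes, with
planted ground truth:

* serial biopsies per patient spanning baseline, regression and
  progression, with purity drawn per biopsy and read counts drawn
  binomially at the expected VAF given purity, local copy number and the
  variant's true CCF (sequencing depth Poisson around a 150x target);
* an escape scenario: a multi-megabase deletion producing LOH over the
  escape gene in every progression biopsy, optionally with two distinct
  frameshift variants whose CCFs are high in distinct progression
  biopsies (0.74 and 0.55) and near zero elsewhere — the two-sibling
  escape-subclone pattern;
* background mutations with state-independent CCFs drawn over a finite
  gene pool (so multi-mutation genes occur under the null);
* a cross-sectional validation cohort where gene-level LOH prevalence
  differs by response group (~29% in non-responders vs ~11% in
  responders/long-term survivors) and overall survival is exponential
  with a proportional hazard for LOH carriers plus independent
  exponential censoring.

All randomness flows from a single integer seed; identical (config,
seed) give identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .ccf import expected_vaf
from .types import (
    ClinicalRecord,
    DiseaseState,
    Effect,
    GeneLocus,
    ParameterError,
    ResponseGroup,
    Sample,
    Segment,
    VariantCall,
)
from . import io as esio

__all__ = [
    "SimConfig",
    "SyntheticCohort",
    "simulate_reads",
    "simulate_longitudinal_patient",
    "simulate_longitudinal_cohort",
    "simulate_validation_cohort",
    "write_cohort",
]

#: hg19 coordinates of the B2M locus on chromosome 15.
DEFAULT_ESCAPE_GENE = GeneLocus("B2M", "15", 45_003_675, 45_011_075)

_CALLERS = ("mutect", "strelka", "vardict")
_CHROM_LEN = 240_000_000


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the synthetic cohorts."""

    n_patients: int = 17
    biopsies_per_patient: int = 5
    depth_mean: float = 150.0
    purity_range: Tuple[float, float] = (0.3, 0.9)
    n_background_mutations: int = 250
    n_background_genes: int = 200
    background_clonal_fraction: float = 0.7
    background_ccf_sd: float = 0.05
    escape_gene: GeneLocus = DEFAULT_ESCAPE_GENE
    escape_scenario: str = "loh_plus_frameshift"  # none | loh_only | loh_plus_frameshift
    ccf_profiles: Dict[str, object] = field(
        default_factory=lambda: {
            "baseline": 0.0,
            "regression": 0.0,
            "progression": (0.74, 0.55),
            "progression_other": 0.01,
        }
    )
    deletion_margin_bp: int = 2_000_000
    # cross-sectional cohort
    n_nonresponders: int = 69
    n_responders: int = 26
    n_long_term: int = 10
    loh_prevalence_nonresponder: float = 0.29
    loh_prevalence_responder: float = 0.11
    survival_hazard_ratio_loh: float = 2.0
    baseline_hazard: float = 1.0 / 1000.0  # per day
    censoring_rate: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ParameterError("purity_range must lie within (0,1]")
        if self.depth_mean <= 0:
            raise ParameterError("depth_mean must be positive")
        for name in ("loh_prevalence_nonresponder", "loh_prevalence_responder", "censoring_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must be a fraction in [0,1]")
        if self.survival_hazard_ratio_loh <= 0 or self.baseline_hazard <= 0:
            raise ParameterError("hazards must be positive")
        if self.escape_scenario not in ("none", "loh_only", "loh_plus_frameshift"):
            raise ParameterError(f"unknown escape_scenario '{self.escape_scenario}'")


@dataclass
class SyntheticCohort:
    samples: List[Sample]
    variants: List[VariantCall]
    segments: List[Segment]
    clinical: List[ClinicalRecord]
    truth: Dict[str, dict]

    def extend(self, other: "SyntheticCohort") -> None:
        self.samples.extend(other.samples)
        self.variants.extend(other.variants)
        self.segments.extend(other.segments)
        self.clinical.extend(other.clinical)
        self.truth.update(other.truth)


def simulate_reads(
    ccf: float,
    purity: float,
    cn_t: float,
    multiplicity: int,
    depth: int,
    rng: np.random.Generator,
) -> Tuple[int, int]:
    """Draw (alt, ref) counts binomially at the model's expected VAF."""
    if depth < 0:
        raise ParameterError("depth must be non-negative")
    vaf = expected_vaf(purity, cn_t, multiplicity, ccf)
    alt = int(rng.binomial(depth, vaf))
    return alt, depth - alt


def _disease_states(k: int) -> List[DiseaseState]:
    """Baseline first, then regression, then progression biopsies."""
    if k < 2:
        raise ParameterError("need at least 2 biopsies (one progression, one not)")
    n_prog = max(1, (k - 1) // 2)
    n_reg = k - 1 - n_prog
    return (
        [DiseaseState.BASELINE]
        + [DiseaseState.REGRESSION] * n_reg
        + [DiseaseState.PROGRESSION] * n_prog
    )


def _sample_segments(
    sample_id: str, config: SimConfig, with_deletion: bool
) -> List[Segment]:
    """Coarse whole-chromosome segments, optionally with the escape deletion."""
    gene = config.escape_gene
    del_start = max(1, gene.start - config.deletion_margin_bp)
    del_end = gene.end + config.deletion_margin_bp
    segs: List[Segment] = []
    for c in range(1, 23):
        chrom = str(c)
        if with_deletion and chrom == gene.chrom:
            segs.append(Segment(sample_id, chrom, 1, del_start - 1, 2.0, 1, 1, 1.0))
            segs.append(Segment(sample_id, chrom, del_start, del_end, 1.0, 1, 0, 0.5))
            segs.append(Segment(sample_id, chrom, del_end + 1, _CHROM_LEN, 2.0, 1, 1, 1.0))
        else:
            segs.append(Segment(sample_id, chrom, 1, _CHROM_LEN, 2.0, 1, 1, 1.0))
    return segs


def _cn_at(segments: Sequence[Segment], chrom: str, pos: int) -> float:
    for s in segments:
        if s.chrom == chrom and s.start <= pos <= s.end:
            return s.total_cn
    return 2.0


def _draw_callers(alt: int, rng: np.random.Generator) -> frozenset:
    """Caller support as a function of evidence; weakly supported calls get one voter."""
    if alt >= 3:
        callers = {"mutect", "strelka"}
        if rng.random() < 0.5:
            callers.add("vardict")
        return frozenset(callers)
    if alt >= 1:
        return frozenset({_CALLERS[rng.integers(len(_CALLERS))]})
    return frozenset()


def simulate_longitudinal_patient(
    config: SimConfig,
    seed: Optional[int] = None,
    patient_id: str = "SimPat001",
    rng: Optional[np.random.Generator] = None,
) -> SyntheticCohort:
    """One multi-biopsy patient, optionally carrying the escape scenario."""
    if rng is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
    states = _disease_states(config.biopsies_per_patient)
    lo, hi = config.purity_range

    samples: List[Sample] = []
    segments: List[Segment] = []
    day = -14
    with_deletion = config.escape_scenario in ("loh_only", "loh_plus_frameshift")
    for i, state in enumerate(states):
        sid = f"{patient_id}-S{i + 1}"
        samples.append(
            Sample(
                sample_id=sid,
                patient_id=patient_id,
                timepoint_days=day,
                disease_state=state,
                purity=float(rng.uniform(lo, hi)),
                ploidy=2.0,
            )
        )
        segments.extend(
            _sample_segments(
                sid, config, with_deletion and state == DiseaseState.PROGRESSION
            )
        )
        day += 60

    seg_by_sample = {s.sample_id: [g for g in segments if g.sample_id == s.sample_id] for s in samples}

    # --- background mutations: state-independent CCFs over a finite gene pool
    n_bg = config.n_background_mutations
    chroms = rng.integers(1, 23, size=n_bg)
    positions = rng.integers(1, _CHROM_LEN, size=n_bg)
    gene_idx = rng.integers(config.n_background_genes, size=n_bg)
    clonal = rng.random(n_bg) < config.background_clonal_fraction
    base_ccf = np.where(clonal, 1.0, rng.uniform(0.1, 0.9, size=n_bg))
    silent = rng.random(n_bg) < 0.3

    variants: List[VariantCall] = []
    truth_ccfs: Dict[str, Dict[str, float]] = {}

    def emit(chrom, pos, ref, alt_allele, gene, effect, ccf_by_sample):
        key_str = f"{chrom}:{pos}{ref}>{alt_allele}"
        truth_ccfs[key_str] = {}
        for smp in samples:
            segs = seg_by_sample[smp.sample_id]
            cn_t = _cn_at(segs, chrom, pos)
            depth = max(1, int(rng.poisson(config.depth_mean)))
            ccf = float(np.clip(ccf_by_sample[smp.sample_id], 0.0, 1.0))
            alt_n, ref_n = simulate_reads(ccf, smp.purity, cn_t, 1, depth, rng)
            truth_ccfs[key_str][smp.sample_id] = ccf
            variants.append(
                VariantCall(
                    patient_id=patient_id,
                    sample_id=smp.sample_id,
                    chrom=chrom,
                    pos=int(pos),
                    ref=ref,
                    alt=alt_allele,
                    ref_count=ref_n,
                    alt_count=alt_n,
                    gene=gene,
                    effect=effect,
                    callers=_draw_callers(alt_n, rng),
                )
            )

    for j in range(n_bg):
        ccfs = {
            smp.sample_id: base_ccf[j] + rng.normal(0.0, config.background_ccf_sd)
            for smp in samples
        }
        emit(
            str(chroms[j]),
            int(positions[j]),
            "C",
            "T",
            f"GENE{gene_idx[j]:03d}",
            Effect.SILENT if silent[j] else Effect.MISSENSE,
            ccfs,
        )

    # --- planted escape frameshifts
    planted_keys: List[str] = []
    if config.escape_scenario == "loh_plus_frameshift":
        prog_ids = [s.sample_id for s in samples if s.disease_state == DiseaseState.PROGRESSION]
        prof = config.ccf_profiles
        planted = tuple(prof["progression"])
        gene = config.escape_gene
        for i, high_ccf in enumerate(planted):
            home = prog_ids[i % len(prog_ids)]
            pos = gene.start + 100 + 20 * i
            ccfs = {}
            for smp in samples:
                if smp.disease_state == DiseaseState.PROGRESSION:
                    ccfs[smp.sample_id] = (
                        high_ccf if smp.sample_id == home else float(prof["progression_other"])
                    )
                else:
                    ccfs[smp.sample_id] = float(prof[smp.disease_state.value])
            emit(gene.chrom, pos, "CT", "C", gene.gene, Effect.FRAMESHIFT, ccfs)
            planted_keys.append(f"{gene.chrom}:{pos}CT>C")

    os_days = float(rng.exponential(1.0 / config.baseline_hazard))
    clinical = [
        ClinicalRecord(
            patient_id=patient_id,
            response_group=ResponseGroup.NONRESPONDER,
            os_days=round(os_days, 1),
            os_event=1,
        )
    ]
    truth = {
        patient_id: {
            "scenario": config.escape_scenario,
            "escape_gene": config.escape_gene.gene if with_deletion else None,
            "planted_variants": planted_keys,
            "loh_samples": [
                s.sample_id for s in samples if s.disease_state == DiseaseState.PROGRESSION
            ]
            if with_deletion
            else [],
            "ccf": truth_ccfs,
        }
    }
    return SyntheticCohort(samples, variants, segments, clinical, truth)


def simulate_longitudinal_cohort(config: SimConfig, seed: Optional[int] = None) -> SyntheticCohort:
    """Multi-patient longitudinal cohort under one scenario."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    cohort = SyntheticCohort([], [], [], [], {})
    for i in range(config.n_patients):
        cohort.extend(
            simulate_longitudinal_patient(
                config, patient_id=f"SimPat{i + 1:03d}", rng=rng
            )
        )
    return cohort


def simulate_validation_cohort(config: SimConfig, seed: Optional[int] = None) -> SyntheticCohort:
    """Cross-sectional cohort: pre-treatment biopsy, LOH status, survival.

    LOH status is Bernoulli by response group; event times are exponential
    with the LOH hazard ratio; censoring is an independent exponential
    whose rate gives an expected censored fraction of ``censoring_rate``
    under the baseline hazard.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    groups = (
        [(ResponseGroup.NONRESPONDER, config.loh_prevalence_nonresponder)]
        * config.n_nonresponders
        + [(ResponseGroup.RESPONDER, config.loh_prevalence_responder)]
        * config.n_responders
        + [(ResponseGroup.LONG_TERM_SURVIVOR, config.loh_prevalence_responder)]
        * config.n_long_term
    )
    lo, hi = config.purity_range
    if config.censoring_rate > 0:
        censor_rate = config.baseline_hazard * config.censoring_rate / (1 - config.censoring_rate)
    else:
        censor_rate = 0.0

    cohort = SyntheticCohort([], [], [], [], {})
    for i, (group, prev) in enumerate(groups):
        pid = f"ValPat{i + 1:03d}"
        sid = f"{pid}-S1"
        loh = bool(rng.random() < prev)
        cohort.samples.append(
            Sample(sid, pid, 0, DiseaseState.BASELINE, float(rng.uniform(lo, hi)), 2.0)
        )
        cohort.segments.extend(_sample_segments(sid, config, with_deletion=loh))
        hazard = config.baseline_hazard * (config.survival_hazard_ratio_loh if loh else 1.0)
        death = rng.exponential(1.0 / hazard)
        censor = rng.exponential(1.0 / censor_rate) if censor_rate > 0 else np.inf
        cohort.clinical.append(
            ClinicalRecord(
                patient_id=pid,
                response_group=group,
                os_days=round(float(min(death, censor)), 1),
                os_event=int(death <= censor),
            )
        )
        cohort.truth[pid] = {"loh": loh, "group": group.value}
    return cohort


def write_cohort(cohort: SyntheticCohort, out_dir) -> Dict[str, Path]:
    """Write the canonical TSVs plus truth.yaml; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "samples": out / "samples.tsv",
        "variants": out / "variants.tsv",
        "segments": out / "segments.tsv",
        "clinical": out / "clinical.tsv",
        "truth": out / "truth.yaml",
    }
    esio.write_samples(cohort.samples, paths["samples"])
    esio.write_variant_table(cohort.variants, paths["variants"])
    esio.write_segments(cohort.segments, paths["segments"])
    esio.write_clinical(cohort.clinical, paths["clinical"])
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump(cohort.truth, fh, sort_keys=True)
    return paths
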