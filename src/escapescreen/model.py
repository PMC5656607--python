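"""Model/Results objects tying the pipeline stages together.

:class:`ResistanceScreenModel` is built from a cohort's variant calls,
allele-specific segments and sample annotations; ``fit()`` runs consensus
voting, force-call matrix assembly, CCF/power estimation, gene-level LOH
calling and the longitudinal screen for every eligible patient, returning
a :class:`ScreenResults` with the hits, a per-gene audit table and the
full CCF matrix.

:class:`CohortEnrichmentModel` is built from a clinical table plus a
patient-level LOH status (given directly or derived from segments);
``fit()`` returns a :class:`CohortResults` carrying the 2x2 table, the
one-sided Fisher p, and the log-rank/Kaplan-Meier survival comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .ccf import CcfEstimate, detection_power, estimate_ccf_arrays
from .cohort import (
    ContingencyTable2x2,
    SurvivalFit,
    fisher_one_sided,
    log_rank,
    loh_enrichment_endpoint,
)
from .consensus import build_force_call_matrix, consensus_vote
from .loh import LohCall, call_gene_loh, patient_loh_status
from .screen import ScreenConfig, ScreenHit, ScreenInapplicableError, screen_patient
from .simulate import SyntheticCohort
from .types import (
    ClinicalRecord,
    GeneLocus,
    ParameterError,
    Sample,
    Segment,
    VariantCall,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ResistanceScreenModel",
    "ScreenResults",
    "CohortEnrichmentModel",
    "CohortResults",
]


def _estimates_for_patient(
    variants: Sequence[VariantCall],
    segments: Sequence[Segment],
    samples: Sequence[Sample],
    min_callers: int,
    k_min: int = 3,
) -> Tuple[List[CcfEstimate], List[VariantCall]]:
    """Consensus-vote per sample, union, force-call, and estimate CCFs."""
    sample_ids = [s.sample_id for s in samples]
    purity = {s.sample_id: s.purity for s in samples}
    callers = sorted({c for v in variants for c in v.callers})
    if callers:
        calls_by_caller = {
            c: {(v.sample_id,) + v.key for v in variants if c in v.callers}
            for c in callers
        }
        kept = consensus_vote(calls_by_caller, min_callers=min_callers)
        union_keys = sorted({k[1:] for k in kept})
    else:
        union_keys = sorted({v.key for v in variants})

    counts = {(v.key, v.sample_id): (v.alt_count, v.ref_count) for v in variants}
    matrix = build_force_call_matrix(union_keys, sample_ids, counts)

    seg_by_sample: Dict[str, List[Segment]] = {sid: [] for sid in sample_ids}
    for seg in segments:
        if seg.sample_id in seg_by_sample:
            seg_by_sample[seg.sample_id].append(seg)

    def cn_at(sid: str, chrom: str, pos: int) -> float:
        for s in seg_by_sample[sid]:
            if s.chrom == chrom and s.start <= pos <= s.end:
                return s.total_cn
        return 2.0

    estimates: List[CcfEstimate] = []
    keys = matrix.variant_keys
    for sid in sample_ids:
        alt = matrix.alt[sid].to_numpy(dtype=float)
        ref = matrix.ref[sid].to_numpy(dtype=float)
        depth = alt + ref
        cn = np.array([max(cn_at(sid, k[0], k[1]), 1.0) for k in keys])
        a = purity[sid]
        vaf = alt / np.maximum(depth, 1.0)
        denom = a * cn + 2.0 * (1.0 - a)
        m = np.clip(np.round(vaf * denom / a), 1, np.maximum(1, np.round(cn))).astype(int)
        ccf, lo, hi = estimate_ccf_arrays(alt, ref, a, cn, m)
        power = detection_power(depth.astype(int), a, cn, 1, k_min=k_min)
        for j, key in enumerate(keys):
            estimates.append(
                CcfEstimate(
                    key=key,
                    sample_id=sid,
                    vaf=float(vaf[j]),
                    multiplicity=int(m[j]),
                    ccf=float(ccf[j]),
                    ci_low=float(lo[j]),
                    ci_high=float(hi[j]),
                    power=float(np.atleast_1d(power)[j]),
                )
            )
    kept_rows = [v for v in variants if v.key in set(union_keys)]
    return estimates, kept_rows


def _gene_loci_from_variants(
    variants: Sequence[VariantCall], known: Mapping[str, GeneLocus]
) -> Dict[str, GeneLocus]:
    """Locus per gene: the supplied table, else the span of its variants."""
    loci = dict(known)
    span: Dict[str, Tuple[str, int, int]] = {}
    for v in variants:
        if v.gene in loci:
            continue
        chrom, lo, hi = span.get(v.gene, (v.chrom, v.pos, v.pos))
        span[v.gene] = (chrom, min(lo, v.pos), max(hi, v.pos))
    for gene, (chrom, lo, hi) in span.items():
        loci[gene] = GeneLocus(gene, chrom, lo, hi)
    return loci


@dataclass
class ScreenResults:
    """Fitted output of :class:`ResistanceScreenModel`."""

    hits: List[ScreenHit]
    ccf_estimates: pd.DataFrame
    loh_calls: List[LohCall]
    audit: pd.DataFrame
    skipped_patients: List[str]
    config: ScreenConfig

    @property
    def hits_frame(self) -> pd.DataFrame:
        rows = [
            {
                "patient_id": h.patient_id,
                "gene": h.gene,
                "n_nonsilent": h.n_nonsilent,
                "loh_in_progression": h.loh_in_progression,
                "max_ccf_progression": h.max_ccf_progression,
                "max_ccf_nonprogression": h.max_ccf_nonprogression,
                "passing_variants": ";".join(
                    f"{c}:{p}{r}>{a}" for c, p, r, a in h.passing_variants
                ),
            }
            for h in self.hits
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "patient_id", "gene", "n_nonsilent", "loh_in_progression",
                "max_ccf_progression", "max_ccf_nonprogression", "passing_variants",
            ],
        )

    def summary(self) -> str:
        lines = [
            "Longitudinal resistance screen",
            "==============================",
            f"patients screened : {self.audit['patient_id'].nunique() if len(self.audit) else 0}",
            f"patients skipped  : {len(self.skipped_patients)}",
            f"thresholds        : power>={self.config.min_power}, "
            f"CCF_prog>={self.config.ccf_prog_min}, CCF_reg<={self.config.ccf_reg_max}, "
            f"non-silent>={self.config.min_nonsilent}",
            f"hits              : {len(self.hits)}",
        ]
        if self.hits:
            lines.append("")
            lines.append(self.hits_frame.to_string(index=False))
        return "\n".join(lines)

    def plot_ccf(self, patient_id: str, gene: str, ax=None):
        """CCF trajectories (with 95% CI bars) of a gene's variants."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.ccf_estimates
        sel = df[(df.patient_id == patient_id) & (df.gene == gene)]
        for key, grp in sel.groupby("variant"):
            grp = grp.sort_values("timepoint_days")
            ax.errorbar(
                grp["timepoint_days"], grp["ccf"],
                yerr=[grp["ccf"] - grp["ci_low"], grp["ci_high"] - grp["ccf"]],
                marker="o", capsize=3, label=str(key),
            )
        ax.set_xlabel("days from treatment start")
        ax.set_ylabel("cancer cell fraction")
        ax.set_ylim(-0.02, 1.05)
        ax.set_title(f"{patient_id} / {gene}")
        ax.legend(fontsize="small")
        return ax


class ResistanceScreenModel:
    """Longitudinal screen over one or more multi-biopsy patients."""

    def __init__(
        self,
        variants: Sequence[VariantCall],
        segments: Sequence[Segment],
        samples: Sequence[Sample],
        gene_loci: Optional[Mapping[str, GeneLocus]] = None,
        config: ScreenConfig = ScreenConfig(),
        min_callers: int = 2,
        loh_min_covered_fraction: float = 1.0,
    ) -> None:
        if not samples:
            raise ParameterError("at least one sample is required")
        self.variants = list(variants)
        self.segments = list(segments)
        self.samples = list(samples)
        self.gene_loci = dict(gene_loci or {})
        self.config = config
        self.min_callers = min_callers
        self.loh_min_covered_fraction = loh_min_covered_fraction

    @classmethod
    def from_cohort(cls, cohort: SyntheticCohort, **kwargs) -> "ResistanceScreenModel":
        return cls(cohort.variants, cohort.segments, cohort.samples, **kwargs)

    @classmethod
    def from_files(
        cls, variants_path, segments_path, samples_path, gene_loci_path=None, **kwargs
    ) -> "ResistanceScreenModel":
        from . import io as esio

        loci = None
        if gene_loci_path is not None:
            loci = {g.gene: g for g in esio.read_gene_loci(gene_loci_path)}
        return cls(
            esio.read_variant_table(variants_path),
            esio.read_segments(segments_path),
            esio.read_samples(samples_path),
            gene_loci=loci,
            **kwargs,
        )

    def fit(self) -> ScreenResults:
        by_patient: Dict[str, List[Sample]] = {}
        for s in self.samples:
            by_patient.setdefault(s.patient_id, []).append(s)

        all_hits: List[ScreenHit] = []
        est_rows: List[dict] = []
        all_loh: List[LohCall] = []
        audit_rows: List[dict] = []
        skipped: List[str] = []

        for pid, samples in sorted(by_patient.items()):
            sample_set = {s.sample_id for s in samples}
            p_variants = [v for v in self.variants if v.patient_id == pid]
            p_segments = [g for g in self.segments if g.sample_id in sample_set]
            if not p_variants:
                skipped.append(pid)
                continue
            estimates, kept_rows = _estimates_for_patient(
                p_variants, p_segments, samples, self.min_callers
            )
            loci = _gene_loci_from_variants(kept_rows, self.gene_loci)
            genes = sorted({v.gene for v in kept_rows})
            seg_by_sample = {
                s.sample_id: [g for g in p_segments if g.sample_id == s.sample_id]
                for s in samples
            }
            loh_calls = [
                call_gene_loh(seg_by_sample[sid], loci[gene], self.loh_min_covered_fraction)
                for sid in sample_set
                for gene in genes
            ]
            try:
                hits = screen_patient(estimates, kept_rows, loh_calls, samples, self.config)
            except ScreenInapplicableError:
                logger.info("patient %s lacks longitudinal structure; skipped", pid)
                skipped.append(pid)
                continue
            all_hits.extend(hits)
            all_loh.extend(loh_calls)

            gene_of = {v.key: v.gene for v in kept_rows}
            state = {s.sample_id: s.disease_state.value for s in samples}
            day = {s.sample_id: s.timepoint_days for s in samples}
            for e in estimates:
                est_rows.append(
                    {
                        "patient_id": pid,
                        "variant": f"{e.key[0]}:{e.key[1]}{e.key[2]}>{e.key[3]}",
                        "gene": gene_of.get(e.key, ""),
                        "sample_id": e.sample_id,
                        "disease_state": state[e.sample_id],
                        "timepoint_days": day[e.sample_id],
                        "vaf": e.vaf,
                        "multiplicity": e.multiplicity,
                        "ccf": e.ccf,
                        "ci_low": e.ci_low,
                        "ci_high": e.ci_high,
                        "power": e.power,
                    }
                )
            hit_genes = {h.gene for h in hits}
            for gene in genes:
                audit_rows.append(
                    {
                        "patient_id": pid,
                        "gene": gene,
                        "n_variants": sum(1 for v in kept_rows if v.gene == gene),
                        "loh_any_sample": any(
                            c.loh for c in loh_calls if c.gene == gene
                        ),
                        "hit": gene in hit_genes,
                    }
                )

        return ScreenResults(
            hits=all_hits,
            ccf_estimates=pd.DataFrame(est_rows),
            loh_calls=all_loh,
            audit=pd.DataFrame(
                audit_rows,
                columns=["patient_id", "gene", "n_variants", "loh_any_sample", "hit"],
            ),
            skipped_patients=skipped,
            config=self.config,
        )


@dataclass
class CohortResults:
    """Fitted output of :class:`CohortEnrichmentModel`."""

    table: ContingencyTable2x2
    fisher_p: float
    survival: SurvivalFit
    n_patients: int

    @property
    def loh_fraction_nonresponders(self) -> float:
        n = self.table.a + self.table.c
        return self.table.a / n if n else float("nan")

    @property
    def loh_fraction_responders(self) -> float:
        n = self.table.b + self.table.d
        return self.table.b / n if n else float("nan")

    def summary(self) -> str:
        t = self.table
        return "\n".join(
            [
                "Cohort LOH enrichment & survival",
                "================================",
                f"patients                  : {self.n_patients}",
                f"LOH | non-responders      : {t.a}/{t.a + t.c} "
                f"({100 * self.loh_fraction_nonresponders:.1f}%)",
                f"LOH | responders + LTS    : {t.b}/{t.b + t.d} "
                f"({100 * self.loh_fraction_responders:.1f}%)",
                f"one-sided Fisher exact p  : {self.fisher_p:.4f}",
                f"log-rank statistic        : {self.survival.statistic:.3f}",
                f"log-rank p (chi2, 1 df)   : {self.survival.p:.4f}",
            ]
        )

    def plot_km(self, ax=None):
        return self.survival.plot(ax=ax, colors={"LOH": "red", "no LOH": "black"})


class CohortEnrichmentModel:
    """Cross-sectional endpoint: LOH enrichment in non-responders + survival."""

    def __init__(
        self,
        clinical: Sequence[ClinicalRecord],
        patient_loh: Mapping[str, bool],
    ) -> None:
        self.clinical = list(clinical)
        self.patient_loh = dict(patient_loh)

    @classmethod
    def from_cohort(
        cls,
        cohort: SyntheticCohort,
        locus: GeneLocus,
        min_covered_fraction: float = 1.0,
        rule: str = "any_sample",
    ) -> "CohortEnrichmentModel":
        """Derive each patient's LOH status from the cohort's segments."""
        by_patient: Dict[str, List[str]] = {}
        for s in cohort.samples:
            by_patient.setdefault(s.patient_id, []).append(s.sample_id)
        seg_by_sample: Dict[str, List[Segment]] = {}
        for seg in cohort.segments:
            seg_by_sample.setdefault(seg.sample_id, []).append(seg)
        status = {
            pid: patient_loh_status(
                [
                    call_gene_loh(seg_by_sample.get(sid, []), locus, min_covered_fraction)
                    for sid in sids
                ],
                rule=rule,
            )
            for pid, sids in by_patient.items()
        }
        return cls(cohort.clinical, status)

    def fit(self) -> CohortResults:
        table, p, fit = loh_enrichment_endpoint(self.clinical, self.patient_loh)
        return CohortResults(
            table=table, fisher_p=p, survival=fit, n_patients=len(self.clinical)
        )
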