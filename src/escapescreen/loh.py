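"""Gene-level loss-of-heterozygosity calls from allele-specific segments.

A gene has LOH in a sample when the union of segments with minor allele
copy number zero covers at least ``min_covered_fraction`` of the gene
interval (default: the whole gene).  Complete loss of both copies
(total copy number zero over the same fraction) is flagged separately,
since biallelic loss of an antigen-presentation gene is the terminal
escape event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, List, Mapping, Sequence, Tuple

from .types import GeneLocus, ParameterError, Segment

logger = logging.getLogger(__name__)

__all__ = ["LohCall", "call_gene_loh", "patient_loh_status", "resolve_overlaps"]


@dataclass(frozen=True)
class LohCall:
    sample_id: str
    gene: str
    loh: bool
    covered_fraction: float
    mean_copy_ratio: float
    both_copies_lost: bool = False


def resolve_overlaps(segments: Sequence[Segment]) -> List[Segment]:
    """Clip overlapping same-sample, same-chromosome segments first-wins.

    Segments are processed in (start, end) order; any part of a later
    segment that falls inside an earlier one is discarded.
    """
    out: List[Segment] = []
    by_key: dict = {}
    for seg in sorted(segments, key=lambda s: (s.sample_id, s.chrom, s.start, s.end)):
        key = (seg.sample_id, seg.chrom)
        last_end = by_key.get(key, 0)
        if seg.start > last_end:
            out.append(seg)
            by_key[key] = seg.end
        elif seg.end > last_end:
            clipped = Segment(
                sample_id=seg.sample_id,
                chrom=seg.chrom,
                start=last_end + 1,
                end=seg.end,
                total_cn=seg.total_cn,
                major_cn=seg.major_cn,
                minor_cn=seg.minor_cn,
                copy_ratio=seg.copy_ratio,
            )
            out.append(clipped)
            by_key[key] = seg.end
        # else: fully contained in an earlier segment; drop
    return out


def _overlap(seg: Segment, locus: GeneLocus) -> int:
    """Overlap length in bp between a segment and the locus (same chrom)."""
    lo = max(seg.start, locus.start)
    hi = min(seg.end, locus.end)
    return max(0, hi - lo + 1)


def call_gene_loh(
    segments: Iterable[Segment],
    locus: GeneLocus,
    min_covered_fraction: float = 1.0,
) -> LohCall:
    """Call LOH for one gene in one sample from that sample's segments."""
    if not (0.0 < min_covered_fraction <= 1.0):
        raise ParameterError("min_covered_fraction must be in (0,1]")
    segs = [s for s in resolve_overlaps(list(segments)) if s.chrom == locus.chrom]
    sample_ids = {s.sample_id for s in segs}
    if len(sample_ids) > 1:
        raise ParameterError(
            f"call_gene_loh expects segments of one sample, got {sorted(sample_ids)}"
        )
    sample_id = sample_ids.pop() if sample_ids else ""
    if not segs:
        logger.warning(
            "no segments on chromosome %s for gene %s: treated as no LOH evidence",
            locus.chrom, locus.gene,
        )
        return LohCall(sample_id, locus.gene, False, 0.0, float("nan"), False)

    loh_bp = sum(_overlap(s, locus) for s in segs if s.minor_cn == 0)
    homdel_bp = sum(_overlap(s, locus) for s in segs if s.total_cn == 0)
    covered = loh_bp / locus.length
    homdel_frac = homdel_bp / locus.length

    weights = [(s.copy_ratio, _overlap(s, locus)) for s in segs if _overlap(s, locus) > 0]
    total_w = sum(w for _, w in weights)
    mean_cr = (
        sum(cr * w for cr, w in weights) / total_w if total_w > 0 else float("nan")
    )
    return LohCall(
        sample_id=sample_id,
        gene=locus.gene,
        loh=covered >= min_covered_fraction - 1e-12,
        covered_fraction=covered,
        mean_copy_ratio=mean_cr,
        both_copies_lost=homdel_frac >= min_covered_fraction - 1e-12,
    )


def patient_loh_status(
    loh_calls: Sequence[LohCall], rule: str = "any_sample"
) -> bool:
    """Aggregate per-sample LOH calls to a patient-level status."""
    if not loh_calls:
        raise ParameterError("patient_loh_status requires at least one sample call")
    if rule == "any_sample":
        return any(c.loh for c in loh_calls)
    if rule == "all_samples":
        return all(c.loh for c in loh_calls)
    raise ParameterError(f"unknown aggregation rule '{rule}'")
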