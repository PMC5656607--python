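"""Readers and writers for the pipeline's tabular formats.

All files are tab-separated with a header line; ``#``-prefixed comment
lines are permitted.  Variant positions and segment intervals are 1-based
inclusive on disk.  ``write_*(read_*(path))`` is byte-identical for files
in canonical column order.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, List, Sequence, Union

import pandas as pd

from .types import (
    ClinicalRecord,
    DiseaseState,
    Effect,
    FormatError,
    GeneLocus,
    ParameterError,
    ResponseGroup,
    Sample,
    Segment,
    VariantCall,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

VARIANT_COLUMNS = [
    "patient_id",
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "ref_count",
    "alt_count",
    "gene",
    "effect",
    "callers",
]
SEGMENT_COLUMNS = [
    "sample_id",
    "chrom",
    "start",
    "end",
    "total_cn",
    "major_cn",
    "minor_cn",
    "copy_ratio",
]
CLINICAL_COLUMNS = ["patient_id", "response_group", "os_days", "os_event"]
SAMPLE_COLUMNS = [
    "sample_id",
    "patient_id",
    "timepoint_days",
    "disease_state",
    "purity",
    "ploidy",
]
GENE_LOCUS_COLUMNS = ["gene", "chrom", "start", "end"]


def _read_table(path: PathLike, required: Sequence[str], what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{what} file not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{what} file {path} is missing required column '{col}'")
    return df


def _row_int(row: pd.Series, col: str, line: int, what: str) -> int:
    try:
        return int(row[col])
    except (TypeError, ValueError):
        raise FormatError(
            f"{what} line {line}: column '{col}' is not an integer ({row[col]!r})"
        ) from None


def _row_float(row: pd.Series, col: str, line: int, what: str) -> float:
    try:
        return float(row[col])
    except (TypeError, ValueError):
        raise FormatError(
            f"{what} line {line}: column '{col}' is not numeric ({row[col]!r})"
        ) from None


def _fmt(value: float) -> str:
    """Format a float compactly and reproducibly (0.5 not 0.500000)."""
    return format(float(value), "g")


def read_variant_table(path: PathLike) -> List[VariantCall]:
    """Read a MAF-like TSV of per-sample somatic variant calls."""
    df = _read_table(path, VARIANT_COLUMNS, "variant")
    out: List[VariantCall] = []
    for i, row in df.iterrows():
        line = int(i) + 2  # header is line 1
        try:
            effect = Effect(row["effect"])
        except ValueError:
            raise FormatError(
                f"variant line {line}: unknown effect '{row['effect']}'"
            ) from None
        callers = frozenset(c for c in str(row["callers"]).split(";") if c)
        try:
            out.append(
                VariantCall(
                    patient_id=row["patient_id"],
                    sample_id=row["sample_id"],
                    chrom=row["chrom"],
                    pos=_row_int(row, "pos", line, "variant"),
                    ref=row["ref"],
                    alt=row["alt"],
                    ref_count=_row_int(row, "ref_count", line, "variant"),
                    alt_count=_row_int(row, "alt_count", line, "variant"),
                    gene=row["gene"],
                    effect=effect,
                    callers=callers,
                )
            )
        except ParameterError as exc:
            raise FormatError(f"variant line {line}: {exc}") from None
    logger.info("read %d variant calls from %s", len(out), path)
    return out


def write_variant_table(variants: Iterable[VariantCall], path: PathLike) -> None:
    rows = [
        [
            v.patient_id,
            v.sample_id,
            v.chrom,
            str(v.pos),
            v.ref,
            v.alt,
            str(v.ref_count),
            str(v.alt_count),
            v.gene,
            v.effect.value,
            ";".join(sorted(v.callers)),
        ]
        for v in variants
    ]
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_segments(path: PathLike) -> List[Segment]:
    """Read a SEG-like TSV of allele-specific copy-number segments.

    Segments are returned sorted by (sample_id, chrom, start); overlapping
    segments within one sample are reported as a warning (downstream LOH
    calling resolves overlaps first-wins).
    """
    df = _read_table(path, SEGMENT_COLUMNS, "segment")
    out: List[Segment] = []
    for i, row in df.iterrows():
        line = int(i) + 2
        try:
            out.append(
                Segment(
                    sample_id=row["sample_id"],
                    chrom=row["chrom"],
                    start=_row_int(row, "start", line, "segment"),
                    end=_row_int(row, "end", line, "segment"),
                    total_cn=_row_float(row, "total_cn", line, "segment"),
                    major_cn=_row_int(row, "major_cn", line, "segment"),
                    minor_cn=_row_int(row, "minor_cn", line, "segment"),
                    copy_ratio=_row_float(row, "copy_ratio", line, "segment"),
                )
            )
        except ParameterError as exc:
            raise FormatError(f"segment line {line}: {exc}") from None
    out.sort(key=lambda s: (s.sample_id, s.chrom, s.start, s.end))
    for prev, cur in zip(out, out[1:]):
        if (
            prev.sample_id == cur.sample_id
            and prev.chrom == cur.chrom
            and cur.start <= prev.end
        ):
            logger.warning(
                "overlapping segments in sample %s on %s: [%d,%d] and [%d,%d]",
                cur.sample_id, cur.chrom, prev.start, prev.end, cur.start, cur.end,
            )
    logger.info("read %d segments from %s", len(out), path)
    return out


def write_segments(segments: Iterable[Segment], path: PathLike) -> None:
    # canonical order matches the reader's sort, so write o read is stable
    segments = sorted(segments, key=lambda s: (s.sample_id, s.chrom, s.start, s.end))
    rows = [
        [
            s.sample_id,
            s.chrom,
            str(s.start),
            str(s.end),
            _fmt(s.total_cn),
            str(s.major_cn),
            str(s.minor_cn),
            _fmt(s.copy_ratio),
        ]
        for s in segments
    ]
    pd.DataFrame(rows, columns=SEGMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_clinical(path: PathLike) -> List[ClinicalRecord]:
    """Read the clinical table (response group + right-censored survival)."""
    df = _read_table(path, CLINICAL_COLUMNS, "clinical")
    out: List[ClinicalRecord] = []
    for i, row in df.iterrows():
        line = int(i) + 2
        try:
            group = ResponseGroup(row["response_group"])
        except ValueError:
            raise FormatError(
                f"clinical line {line}: unknown response_group '{row['response_group']}'"
            ) from None
        try:
            out.append(
                ClinicalRecord(
                    patient_id=row["patient_id"],
                    response_group=group,
                    os_days=_row_float(row, "os_days", line, "clinical"),
                    os_event=_row_int(row, "os_event", line, "clinical"),
                )
            )
        except ParameterError as exc:
            raise FormatError(f"clinical line {line}: {exc}") from None
    logger.info("read %d clinical records from %s", len(out), path)
    return out


def write_clinical(records: Iterable[ClinicalRecord], path: PathLike) -> None:
    rows = [
        [r.patient_id, r.response_group.value, _fmt(r.os_days), str(r.os_event)]
        for r in records
    ]
    pd.DataFrame(rows, columns=CLINICAL_COLUMNS).to_csv(path, sep="\t", index=False)


def read_samples(path: PathLike) -> List[Sample]:
    """Read the sample table (purity, ploidy, timepoint, disease state)."""
    df = _read_table(path, SAMPLE_COLUMNS, "sample")
    out: List[Sample] = []
    for i, row in df.iterrows():
        line = int(i) + 2
        try:
            state = DiseaseState(row["disease_state"])
        except ValueError:
            raise FormatError(
                f"sample line {line}: unknown disease_state '{row['disease_state']}'"
            ) from None
        try:
            out.append(
                Sample(
                    sample_id=row["sample_id"],
                    patient_id=row["patient_id"],
                    timepoint_days=_row_int(row, "timepoint_days", line, "sample"),
                    disease_state=state,
                    purity=_row_float(row, "purity", line, "sample"),
                    ploidy=_row_float(row, "ploidy", line, "sample"),
                )
            )
        except ParameterError as exc:
            raise FormatError(f"sample line {line}: {exc}") from None
    ids = [s.sample_id for s in out]
    if len(ids) != len(set(ids)):
        raise FormatError(f"sample file {path}: duplicate sample_id values")
    logger.info("read %d samples from %s", len(out), path)
    return out


def write_samples(samples: Iterable[Sample], path: PathLike) -> None:
    rows = [
        [
            s.sample_id,
            s.patient_id,
            str(s.timepoint_days),
            s.disease_state.value,
            _fmt(s.purity),
            _fmt(s.ploidy),
        ]
        for s in samples
    ]
    pd.DataFrame(rows, columns=SAMPLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gene_loci(path: PathLike) -> List[GeneLocus]:
    """Read the 4-column gene locus table (gene, chrom, start, end)."""
    df = _read_table(path, GENE_LOCUS_COLUMNS, "gene locus")
    out: List[GeneLocus] = []
    for i, row in df.iterrows():
        line = int(i) + 2
        try:
            out.append(
                GeneLocus(
                    gene=row["gene"],
                    chrom=row["chrom"],
                    start=_row_int(row, "start", line, "gene locus"),
                    end=_row_int(row, "end", line, "gene locus"),
                )
            )
        except ParameterError as exc:
            raise FormatError(f"gene locus line {line}: {exc}") from None
    return out


def write_gene_loci(loci: Iterable[GeneLocus], path: PathLike) -> None:
    rows = [[g.gene, g.chrom, str(g.start), str(g.end)] for g in loci]
    pd.DataFrame(rows, columns=GENE_LOCUS_COLUMNS).to_csv(path, sep="\t", index=False)
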