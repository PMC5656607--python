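"""Cohort-level endpoints and closed-form assay summaries.

The enrichment endpoint tests whether gene-level LOH is over-represented
among non-responders with a one-sided Fisher exact test built directly
from the hypergeometric pmf; the survival endpoint compares overall
survival between LOH carriers and non-carriers with a two-group log-rank
test (hypergeometric variance at each distinct event time, chi-square p
on 1 df) and Kaplan-Meier product-limit curves.  Also provided: gene-set
expression scores (geometric mean of TPM + 1), the four-level IHC tumor
staining bins, droplet-digital-PCR fractional abundance, and the in vivo
two-clone competition score.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .types import ClinicalRecord, ParameterError, ResponseGroup

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable2x2",
    "SurvivalFit",
    "CompetitionObservation",
    "DdpcrCounts",
    "IhcLevel",
    "fisher_one_sided",
    "km_curve",
    "log_rank",
    "loh_enrichment_endpoint",
    "expression_score",
    "ihc_bin",
    "ddpcr_fractional_abundance",
    "competition_score",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows: LOH yes/no; columns: non-responders / responders (+ long-term)."""

    a: int  # LOH, non-responder
    b: int  # LOH, responder or long-term survivor
    c: int  # no LOH, non-responder
    d: int  # no LOH, responder or long-term survivor

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ParameterError("contingency cells must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class SurvivalFit:
    """Two-group log-rank result with Kaplan-Meier curves.

    ``curves`` maps group label to a DataFrame with columns
    (time, survival, at_risk); ``event_table`` holds per-group observed
    and expected event counts.
    """

    statistic: float
    p: float
    curves: Dict[str, pd.DataFrame]
    event_table: pd.DataFrame

    def plot(self, ax=None, colors: Mapping[str, str] = None):
        """Step plot of the KM curves (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for label, curve in self.curves.items():
            color = None if colors is None else colors.get(label)
            ax.step(
                np.concatenate([[0.0], curve["time"].to_numpy()]),
                np.concatenate([[1.0], curve["survival"].to_numpy()]),
                where="post", label=str(label), color=color,
            )
        ax.set_xlabel("time (days)")
        ax.set_ylabel("overall survival")
        ax.set_ylim(0, 1.02)
        ax.legend()
        return ax


@dataclass(frozen=True)
class CompetitionObservation:
    """Flow-cytometry percentages of knockout and wild-type clones."""

    ko_sample_pct: float
    ko_baseline_pct: float
    wt_sample_pct: float
    wt_baseline_pct: float

    def __post_init__(self) -> None:
        for name in ("ko_sample_pct", "ko_baseline_pct", "wt_sample_pct", "wt_baseline_pct"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ParameterError(f"{name} must be a percentage in [0,100], got {v}")
        if self.ko_baseline_pct <= 0 or self.wt_baseline_pct <= 0:
            raise ParameterError("baseline percentages must be positive")


@dataclass(frozen=True)
class DdpcrCounts:
    n_mut: int
    n_wt: int

    def __post_init__(self) -> None:
        if self.n_mut < 0 or self.n_wt < 0:
            raise ParameterError("droplet counts must be non-negative")


class IhcLevel(str, enum.Enum):
    MINIMAL = "minimal"
    LOW = "low"
    INTERMEDIATE = "intermediate"
    HIGH = "high"


def fisher_one_sided(table: ContingencyTable2x2) -> float:
    """One-sided Fisher exact p for LOH enrichment in non-responders.

    Exact hypergeometric upper-tail sum over tables with the observed
    margins and first cell >= a.  Degenerate margins (an empty row or
    column) give p = 1 with a warning.
    """
    N = table.n
    K = table.a + table.b  # LOH row margin
    n = table.a + table.c  # non-responder column margin
    if N == 0 or K == 0 or K == N or n == 0 or n == N:
        warnings.warn("degenerate 2x2 margins: Fisher test undefined, returning p=1")
        return 1.0
    return float(stats.hypergeom.sf(table.a - 1, N, K, n))


def km_curve(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate.

    Returns one row per distinct event time with columns
    (time, survival, at_risk).  Censored subjects leave the risk set just
    after their censoring time.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ParameterError("empty group in survival analysis")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    rows = []
    surv = 1.0
    n = times.size
    i = 0
    while i < n:
        t = times[i]
        d = 0
        at_risk = n - i
        while i < n and times[i] == t:
            d += events[i]
            i += 1
        if d > 0:
            surv *= 1.0 - d / at_risk
            rows.append((t, surv, at_risk))
    return pd.DataFrame(rows, columns=["time", "survival", "at_risk"])


def _logrank_stat(times, events, group) -> float:
    """Two-group log-rank chi-square statistic (vectorized over event times)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group, dtype=int)  # 1 = group of interest
    order = np.argsort(times, kind="stable")
    times, events, group = times[order], events[order], group[order]
    uniq, idx = np.unique(times, return_index=True)
    # at-risk counts just before each distinct time
    n_total = times.size - idx
    cum_g1 = np.concatenate([[0], np.cumsum(group)])
    n1 = group.sum() - cum_g1[idx]
    # deaths at each distinct time, overall and in group 1
    d_total = np.add.reduceat(events, idx)
    d1 = np.add.reduceat(events * group, idx)
    mask = (d_total > 0) & (n_total > 1)
    n_t, n1_t, d_t, d1_t = n_total[mask], n1[mask], d_total[mask], d1[mask]
    expected = d_t * n1_t / n_t
    var = d_t * (n1_t / n_t) * (1 - n1_t / n_t) * (n_t - d_t) / (n_t - 1)
    v = var.sum()
    if v <= 0:
        return 0.0
    return float((d1_t - expected).sum() ** 2 / v)


def log_rank(
    group1: Sequence[Tuple[float, int]],
    group2: Sequence[Tuple[float, int]],
    labels: Tuple[str, str] = ("group1", "group2"),
) -> SurvivalFit:
    """Two-group log-rank test with KM curves.

    Each group is a sequence of (os_days, os_event) pairs; event = 1 for
    death, 0 for right-censoring.  Tie handling uses the hypergeometric
    variance at each distinct event time; p is two-sided from chi-square
    with one degree of freedom.
    """
    g1 = np.asarray(list(group1), dtype=float)
    g2 = np.asarray(list(group2), dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise ParameterError("both survival groups must be non-empty")
    times = np.concatenate([g1[:, 0], g2[:, 0]])
    events = np.concatenate([g1[:, 1], g2[:, 1]]).astype(int)
    if events.sum() == 0:
        raise ParameterError("log-rank test requires at least one event")
    group = np.concatenate([np.ones(len(g1), dtype=int), np.zeros(len(g2), dtype=int)])
    stat = _logrank_stat(times, events, group)
    p = float(stats.chi2.sf(stat, df=1))
    curves = {
        labels[0]: km_curve(g1[:, 0], g1[:, 1].astype(int)),
        labels[1]: km_curve(g2[:, 0], g2[:, 1].astype(int)),
    }
    event_table = pd.DataFrame(
        {
            "n": [len(g1), len(g2)],
            "observed": [int(g1[:, 1].sum()), int(g2[:, 1].sum())],
        },
        index=list(labels),
    )
    return SurvivalFit(statistic=stat, p=p, curves=curves, event_table=event_table)


def loh_enrichment_endpoint(
    clinical: Sequence[ClinicalRecord],
    patient_loh: Mapping[str, bool],
) -> Tuple[ContingencyTable2x2, float, SurvivalFit]:
    """Cross-sectional endpoint: LOH enrichment plus survival split by LOH.

    Responders and long-term survivors are pooled into the non-case
    column.  Every clinical patient must have an LOH status.
    """
    missing = [r.patient_id for r in clinical if r.patient_id not in patient_loh]
    if missing:
        raise ParameterError(f"patients without LOH status: {missing[:10]}")
    a = b = c = d = 0
    loh_surv, wt_surv = [], []
    for rec in clinical:
        loh = bool(patient_loh[rec.patient_id])
        noncase = rec.response_group in (
            ResponseGroup.RESPONDER,
            ResponseGroup.LONG_TERM_SURVIVOR,
        )
        if loh and not noncase:
            a += 1
        elif loh and noncase:
            b += 1
        elif not loh and not noncase:
            c += 1
        else:
            d += 1
        (loh_surv if loh else wt_surv).append((rec.os_days, rec.os_event))
    table = ContingencyTable2x2(a, b, c, d)
    p = fisher_one_sided(table)
    if loh_surv and wt_surv:
        fit = log_rank(loh_surv, wt_surv, labels=("LOH", "no LOH"))
    else:
        # one LOH stratum is empty: no survival contrast to test
        warnings.warn("degenerate LOH split: survival comparison undefined, p=1")
        present = loh_surv or wt_surv
        label = "LOH" if loh_surv else "no LOH"
        curve = km_curve([t for t, _ in present], [e for _, e in present])
        fit = SurvivalFit(
            statistic=0.0,
            p=1.0,
            curves={label: curve},
            event_table=pd.DataFrame(
                {"n": [len(present)], "observed": [sum(e for _, e in present)]},
                index=[label],
            ),
        )
    logger.info(
        "enrichment endpoint: table=(%d,%d,%d,%d) fisher_p=%.4g logrank_p=%.4g",
        a, b, c, d, p, fit.p,
    )
    return table, p, fit


def expression_score(tpm: Mapping[str, float], gene_set: Iterable[str]) -> float:
    """Geometric mean of (TPM + 1) over the genes of a set found in ``tpm``.

    The +1 pseudocount keeps zero-expression genes from annihilating the
    mean; the score is reported on that shifted scale.
    """
    gene_set = list(gene_set)
    if not gene_set:
        raise ParameterError("gene set must be non-empty")
    found = [g for g in gene_set if g in tpm]
    dropped = [g for g in gene_set if g not in tpm]
    if dropped:
        warnings.warn(f"genes missing from expression table: {dropped}")
    if not found:
        raise ParameterError("no gene of the set found in the expression table")
    values = np.asarray([tpm[g] for g in found], dtype=float)
    if np.any(values < 0):
        raise ParameterError("TPM values must be non-negative")
    return float(np.exp(np.mean(np.log(values + 1.0))))


def ihc_bin(tumor_fraction_pct: float) -> IhcLevel:
    """Four-level staining bin for the B2M-positive tumor-cell fraction.

    Bins are [0,10), [10,50), [50,80), [80,100]; the shared endpoints of
    the printed ranges are assigned to the upper bin, with the top bin
    closed at 100.
    """
    x = float(tumor_fraction_pct)
    if not (0.0 <= x <= 100.0):
        raise ParameterError(f"tumor fraction must be in [0,100], got {x}")
    if x < 10:
        return IhcLevel.MINIMAL
    if x < 50:
        return IhcLevel.LOW
    if x < 80:
        return IhcLevel.INTERMEDIATE
    return IhcLevel.HIGH


def ddpcr_fractional_abundance(counts: DdpcrCounts) -> float:
    """Fractional abundance (%) of mutant droplet events: Nmut/(Nmut+Nwt)*100."""
    total = counts.n_mut + counts.n_wt
    if total == 0:
        raise ParameterError("fractional abundance undefined for zero droplet events")
    return 100.0 * counts.n_mut / total


def competition_score(obs: CompetitionObservation) -> float:
    """Percentage depletion of the knockout clone relative to wild type.

    (1 - (KO sample % / KO baseline %) / (WT sample % / WT baseline %)) x 100.
    """
    if obs.wt_sample_pct == 0:
        raise ParameterError("competition score undefined when the WT clone is absent")
    ko_ratio = obs.ko_sample_pct / obs.ko_baseline_pct
    wt_ratio = obs.wt_sample_pct / obs.wt_baseline_pct
    return (1.0 - ko_ratio / wt_ratio) * 100.0
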