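"""Cancer cell fraction estimation and detection power.

The model relates the variant allele fraction (VAF) observed in a bulk
tumor biopsy to the fraction of cancer cells carrying the variant (CCF)
under an allelic copy-number model with diploid normal contamination:

    E[VAF] = CCF * alpha * m / (alpha * c_t + 2 * (1 - alpha))

where ``alpha`` is tumor purity, ``c_t`` the local total copy number in
cancer cells, and ``m`` the number of mutated copies per mutated cancer
cell (multiplicity).  The map is linear in CCF, so a binomial confidence
interval on the VAF transfers directly to the CCF scale.

Detection power is the probability of seeing at least ``k_min`` variant
reads for a clonal variant (CCF = 1) at the given depth, purity and local
copy number — a binomial-tail stand-in for a full error-model calculation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import stats

from .types import ParameterError, VariantKey

__all__ = [
    "CcfEstimate",
    "expected_vaf",
    "estimate_multiplicity",
    "estimate_ccf",
    "estimate_ccf_arrays",
    "detection_power",
    "clopper_pearson",
]


@dataclass(frozen=True)
class CcfEstimate:
    """CCF point estimate with a 95% CI and detection power for one variant x sample."""

    key: VariantKey
    sample_id: str
    vaf: float
    multiplicity: int
    ccf: float
    ci_low: float
    ci_high: float
    power: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.ccf <= self.ci_high):
            raise ParameterError("CI must bracket the point estimate")
        if not (0.0 <= self.power <= 1.0):
            raise ParameterError("power must be in [0,1]")


def _check_domain(purity: float, cn_t: float, m: int) -> None:
    if not (0.0 < purity <= 1.0):
        raise ParameterError(f"purity must be in (0,1], got {purity}")
    if cn_t <= 0:
        raise ParameterError(f"local total copy number must be > 0, got {cn_t}")
    if m < 1:
        raise ParameterError(f"multiplicity must be >= 1, got {m}")


def expected_vaf(purity: float, cn_t: float, m: int, ccf: float) -> float:
    """Expected VAF of a variant at the given CCF under the allelic model."""
    _check_domain(purity, cn_t, m)
    if not (0.0 <= ccf <= 1.0):
        raise ParameterError(f"ccf must be in [0,1], got {ccf}")
    vaf = ccf * purity * m / (purity * cn_t + 2.0 * (1.0 - purity))
    if vaf > 1.0 + 1e-12:
        raise ParameterError(
            f"expected VAF {vaf:.4f} > 1: multiplicity {m} inconsistent with cn_t {cn_t}"
        )
    return min(vaf, 1.0)


def estimate_multiplicity(vaf: float, purity: float, cn_t: float) -> int:
    """Integer multiplicity that best explains the observed VAF for a clonal variant.

    Rounds ``vaf * (purity*cn_t + 2*(1-purity)) / purity`` and clamps the
    result to [1, max(1, round(cn_t))].
    """
    _check_domain(purity, cn_t, 1)
    m = round(vaf * (purity * cn_t + 2.0 * (1.0 - purity)) / purity)
    return int(min(max(m, 1), max(1, round(cn_t))))


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> Tuple[float, float]:
    """Exact (Clopper-Pearson) two-sided binomial CI for a proportion."""
    if n <= 0:
        raise ParameterError("Clopper-Pearson requires n > 0")
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2.0, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return lo, hi


def estimate_ccf(
    alt: int,
    ref: int,
    purity: float,
    cn_t: float,
    m: Optional[int] = None,
    sample_id: str = "",
    key: VariantKey = ("", 1, "N", "N"),
    k_min: int = 3,
    alpha: float = 0.05,
) -> CcfEstimate:
    """Estimate CCF from read counts by inverting the expected-VAF model.

    When ``m`` is not given it is chosen with :func:`estimate_multiplicity`.
    The CI is the exact binomial interval on the VAF mapped through the
    linear inverse and clamped to [0,1].
    """
    n = alt + ref
    if n <= 0:
        raise ParameterError("cannot estimate a CCF from zero total reads")
    _check_domain(purity, cn_t, 1)
    vaf = alt / n
    if m is None:
        m = estimate_multiplicity(vaf, purity, cn_t)
    scale = (purity * cn_t + 2.0 * (1.0 - purity)) / (purity * m)
    ccf = float(np.clip(vaf * scale, 0.0, 1.0))
    lo, hi = clopper_pearson(alt, n, alpha=alpha)
    ci_low = float(np.clip(lo * scale, 0.0, 1.0))
    ci_high = float(np.clip(hi * scale, 0.0, 1.0))
    power = detection_power(n, purity, cn_t, m, k_min=k_min)
    return CcfEstimate(
        key=key,
        sample_id=sample_id,
        vaf=vaf,
        multiplicity=int(m),
        ccf=ccf,
        ci_low=min(ci_low, ccf),
        ci_high=max(ci_high, ccf),
        power=power,
    )


def estimate_ccf_arrays(alt, ref, purity, cn_t, m, alpha: float = 0.05):
    """Vectorized CCF point estimates and CIs; returns (ccf, ci_low, ci_high).

    All arguments broadcast; total depth must be positive everywhere.
    """
    alt = np.asarray(alt, dtype=float)
    ref = np.asarray(ref, dtype=float)
    purity = np.asarray(purity, dtype=float)
    cn_t = np.asarray(cn_t, dtype=float)
    m = np.asarray(m, dtype=float)
    n = alt + ref
    if np.any(n <= 0):
        raise ParameterError("cannot estimate a CCF from zero total reads")
    vaf = alt / n
    scale = (purity * cn_t + 2.0 * (1.0 - purity)) / (purity * m)
    ccf = np.clip(vaf * scale, 0.0, 1.0)
    with np.errstate(invalid="ignore"):
        lo = np.where(alt == 0, 0.0, stats.beta.ppf(alpha / 2.0, alt, n - alt + 1))
        hi = np.where(alt == n, 1.0, stats.beta.ppf(1 - alpha / 2.0, alt + 1, n - alt))
    ci_low = np.minimum(np.clip(lo * scale, 0.0, 1.0), ccf)
    ci_high = np.maximum(np.clip(hi * scale, 0.0, 1.0), ccf)
    return ccf, ci_low, ci_high


def detection_power(depth, purity, cn_t, m: int = 1, k_min: int = 3):
    """P(at least ``k_min`` variant reads) for a clonal variant at this depth.

    Binomial tail at the expected clonal VAF; broadcasts over array inputs.
    """
    if k_min < 1:
        raise ParameterError("k_min must be >= 1")
    p = (
        np.asarray(purity, dtype=float)
        * np.asarray(m, dtype=float)
        / (
            np.asarray(purity, dtype=float) * np.asarray(cn_t, dtype=float)
            + 2.0 * (1.0 - np.asarray(purity, dtype=float))
        )
    )
    if np.any(p < 0) or np.any(p > 1 + 1e-12):
        raise ParameterError("clonal VAF outside [0,1]; check purity/cn_t/m")
    out = stats.binom.sf(k_min - 1, np.asarray(depth, dtype=int), np.minimum(p, 1.0))
    return float(out) if np.ndim(out) == 0 else out
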