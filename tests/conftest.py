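import numpy as np
import pytest

from escapescreen import (
    CcfEstimate,
    DiseaseState,
    Effect,
    GeneLocus,
    LohCall,
    Sample,
    VariantCall,
)

B2M_LOCUS = GeneLocus("B2M", "15", 45_003_675, 45_011_075)


def make_estimate(key, sample_id, ccf, power=0.99, half_width=0.05):
    """CcfEstimate with a symmetric CI clipped to [0,1]."""
    return CcfEstimate(
        key=key,
        sample_id=sample_id,
        vaf=ccf / 4.0,
        multiplicity=1,
        ccf=ccf,
        ci_low=max(0.0, ccf - half_width),
        ci_high=min(1.0, ccf + half_width),
        power=power,
    )


@pytest.fixture
def escape_patient_fixture():
    """Deterministic worked example: two escape frameshifts dominant in
    distinct progression biopsies (CCF 0.74 / 0.55), near zero elsewhere,
    with LOH over the gene in every progression biopsy, plus a clonal
    background passenger present at all timepoints."""
    states = [
        DiseaseState.BASELINE,
        DiseaseState.REGRESSION,
        DiseaseState.REGRESSION,
        DiseaseState.PROGRESSION,
        DiseaseState.PROGRESSION,
    ]
    samples = [
        Sample(f"PatA-S{i+1}", "PatA", -14 + 60 * i, st, 0.6, 2.0)
        for i, st in enumerate(states)
    ]
    prog = [s.sample_id for s in samples if s.disease_state == DiseaseState.PROGRESSION]
    nonprog = [s.sample_id for s in samples if s.disease_state != DiseaseState.PROGRESSION]

    fs1 = ("15", 45_003_775, "CT", "C")  # dominant in first progression biopsy
    fs2 = ("15", 45_003_795, "GA", "G")  # dominant in second progression biopsy
    passenger = ("3", 1_000_000, "C", "T")

    variants = [
        VariantCall("PatA", prog[0], *fs1[:2], fs1[2], fs1[3], 80, 40, "B2M", Effect.FRAMESHIFT),
        VariantCall("PatA", prog[1], *fs2[:2], fs2[2], fs2[3], 90, 30, "B2M", Effect.FRAMESHIFT),
        VariantCall("PatA", samples[0].sample_id, *passenger[:2], passenger[2], passenger[3], 100, 40, "GENE001", Effect.MISSENSE),
    ]

    estimates = []
    for sid in [s.sample_id for s in samples]:
        estimates.append(make_estimate(fs1, sid, 0.74 if sid == prog[0] else (0.01 if sid == prog[1] else 0.0)))
        estimates.append(make_estimate(fs2, sid, 0.55 if sid == prog[1] else (0.01 if sid == prog[0] else 0.0)))
        estimates.append(make_estimate(passenger, sid, 1.0))

    loh_calls = [
        LohCall(sid, "B2M", loh=sid in prog, covered_fraction=1.0 if sid in prog else 0.0, mean_copy_ratio=0.5 if sid in prog else 1.0)
        for sid in [s.sample_id for s in samples]
    ] + [
        LohCall(sid, "GENE001", loh=False, covered_fraction=0.0, mean_copy_ratio=1.0)
        for sid in [s.sample_id for s in samples]
    ]
    return {
        "samples": samples,
        "variants": variants,
        "estimates": estimates,
        "loh_calls": loh_calls,
        "fs_keys": (fs1, fs2),
        "prog": prog,
        "nonprog": nonprog,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
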