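"""Longitudinal resistance screen: worked example, perturbations, brute force."""

import dataclasses
import itertools

import numpy as np
import pytest

from escapescreen import (
    CcfEstimate,
    DiseaseState,
    Effect,
    ParameterError,
    Sample,
    ScreenConfig,
    ScreenInapplicableError,
    VariantCall,
    power_filter,
    screen_patient,
)
from escapescreen.loh import LohCall

from conftest import make_estimate


def test_worked_example_yields_exactly_the_escape_gene(escape_patient_fixture):
    f = escape_patient_fixture
    hits = screen_patient(f["estimates"], f["variants"], f["loh_calls"], f["samples"])
    assert len(hits) == 1
    hit = hits[0]
    assert hit.gene == "B2M"
    assert hit.n_nonsilent == 2
    assert hit.loh_in_progression
    assert hit.max_ccf_progression == pytest.approx(0.74)
    assert set(hit.passing_variants) == set(f["fs_keys"])


def test_ccf_in_regression_sample_breaks_exclusivity(escape_patient_fixture):
    f = escape_patient_fixture
    reg_sample = f["nonprog"][1]
    fs1 = f["fs_keys"][0]
    estimates = [
        make_estimate(fs1, e.sample_id, 0.6) if (e.key, e.sample_id) == (fs1, reg_sample) else e
        for e in f["estimates"]
    ]
    assert screen_patient(estimates, f["variants"], f["loh_calls"], f["samples"]) == []


def test_removing_loh_removes_the_hit(escape_patient_fixture):
    f = escape_patient_fixture
    no_loh = [
        dataclasses.replace(c, loh=False, covered_fraction=0.0) if c.gene == "B2M" else c
        for c in f["loh_calls"]
    ]
    assert screen_patient(f["estimates"], f["variants"], no_loh, f["samples"]) == []


def test_underpowered_sample_removes_the_hit(escape_patient_fixture):
    """Power 0.85 in one sample fails the >=0.9-everywhere filter."""
    f = escape_patient_fixture
    fs1 = f["fs_keys"][0]
    weak_sample = f["nonprog"][0]
    estimates = [
        dataclasses.replace(e, power=0.85)
        if (e.key, e.sample_id) == (fs1, weak_sample)
        else e
        for e in f["estimates"]
    ]
    assert screen_patient(estimates, f["variants"], f["loh_calls"], f["samples"]) == []


def test_screen_requires_longitudinal_structure(escape_patient_fixture):
    f = escape_patient_fixture
    only_prog = [s for s in f["samples"] if s.disease_state == DiseaseState.PROGRESSION]
    est = [e for e in f["estimates"] if e.sample_id in {s.sample_id for s in only_prog}]
    with pytest.raises(ScreenInapplicableError):
        screen_patient(est, f["variants"], f["loh_calls"], only_prog)


def test_single_lesion_evidence_allowed_by_config(escape_patient_fixture):
    """min_nonsilent=1 admits a gene carrying a single exclusive variant."""
    f = escape_patient_fixture
    fs1 = f["fs_keys"][0]
    one_variant_est = [e for e in f["estimates"] if e.key != f["fs_keys"][1]]
    variants = [v for v in f["variants"] if v.key != f["fs_keys"][1]]
    assert screen_patient(one_variant_est, variants, f["loh_calls"], f["samples"]) == []
    hits = screen_patient(
        one_variant_est, variants, f["loh_calls"], f["samples"],
        ScreenConfig(min_nonsilent=1),
    )
    assert [h.gene for h in hits] == ["B2M"]
    assert hits[0].passing_variants == (fs1,)


# ---------------------------------------------------------------- power filter

def _powers_to_estimates(powers_by_variant):
    ests = []
    for key, powers in powers_by_variant.items():
        for i, p in enumerate(powers):
            ests.append(make_estimate(key, f"S{i}", 0.5, power=p))
    return ests


def test_power_filter_requires_threshold_in_all_samples():
    k1, k2 = ("1", 1, "C", "T"), ("1", 2, "C", "T")
    ests = _powers_to_estimates({k1: [0.95, 0.99, 0.91], k2: [0.95, 0.89, 0.99]})
    kept = power_filter(ests, ["S0", "S1", "S2"], min_power=0.9)
    assert kept == {k1}
    assert power_filter(ests, ["S0", "S1", "S2"], min_power=0.0) == {k1, k2}


def test_power_filter_names_missing_pair():
    k1 = ("1", 1, "C", "T")
    ests = _powers_to_estimates({k1: [0.95]})
    with pytest.raises(ParameterError, match="S1"):
        power_filter(ests, ["S0", "S1"])


# ------------------------------------------------- brute force & monotonicity

def _random_cohort(rng, n_genes=4, n_samples=4):
    states = [DiseaseState.BASELINE, DiseaseState.REGRESSION] + [
        DiseaseState.PROGRESSION
    ] * (n_samples - 2)
    samples = [
        Sample(f"S{i}", "P", i * 30, st, 0.6, 2.0) for i, st in enumerate(states)
    ]
    variants, estimates, loh_calls = [], [], []
    for g in range(n_genes):
        gene = f"G{g}"
        loh_flags = {s.sample_id: bool(rng.random() < 0.5) for s in samples}
        for s in samples:
            loh_calls.append(
                LohCall(s.sample_id, gene, loh_flags[s.sample_id],
                        1.0 if loh_flags[s.sample_id] else 0.0, 1.0)
            )
        for j in range(rng.integers(1, 4)):
            key = ("1", 1000 * g + j + 1, "C", "T")
            effect = Effect.MISSENSE if rng.random() < 0.8 else Effect.SILENT
            variants.append(VariantCall("P", samples[0].sample_id, *key[:2], key[2], key[3], 50, 10, gene, effect))
            for s in samples:
                ccf = float(rng.choice([0.0, 0.02, 0.2, 0.6, 0.9]))
                power = float(rng.choice([0.99, 0.95, 0.7]))
                estimates.append(make_estimate(key, s.sample_id, ccf, power=power))
    return samples, variants, estimates, loh_calls


def _brute_hits(estimates, variants, loh_calls, samples, cfg):
    """Straight-line re-evaluation from raw tables: every gene, every variant."""
    from escapescreen.consensus import is_nonsilent

    prog = [s.sample_id for s in samples if s.disease_state == DiseaseState.PROGRESSION]
    nonprog = [s.sample_id for s in samples if s.disease_state != DiseaseState.PROGRESSION]
    est = {(e.key, e.sample_id): e for e in estimates}
    loh = {(c.sample_id, c.gene): c.loh for c in loh_calls}
    genes = sorted({v.gene for v in variants})
    hits = set()
    for gene in genes:
        keys = sorted({v.key for v in variants if v.gene == gene and is_nonsilent(v.effect)})
        passing, dominant = [], set()
        for k in keys:
            if any(est[(k, s)].power < cfg.min_power for s in prog + nonprog):
                continue
            dom = {s for s in prog if est[(k, s)].ci_high >= cfg.ccf_prog_min}
            quiet = all(est[(k, s)].ccf <= cfg.ccf_reg_max for s in nonprog)
            if dom and quiet:
                passing.append(k)
                dominant |= dom
        # enumerate subsets: some admissible subset of size >= min_nonsilent must
        # exist, and the LOH criterion applies to all dominant-sample biopsies
        found = any(
            len(sub) >= cfg.min_nonsilent
            for r in range(cfg.min_nonsilent, len(passing) + 1)
            for sub in itertools.combinations(passing, r)
        )
        if found and all(loh.get((s, gene), False) for s in dominant):
            hits.add(gene)
    return hits


def test_screen_matches_brute_force_on_random_cohorts(rng):
    cfg = ScreenConfig()
    for _ in range(40):
        samples, variants, estimates, loh_calls = _random_cohort(rng)
        fast = {h.gene for h in screen_patient(estimates, variants, loh_calls, samples, cfg)}
        assert fast == _brute_hits(estimates, variants, loh_calls, samples, cfg)


def test_tightening_thresholds_never_adds_hits(rng):
    loose = ScreenConfig(min_power=0.8, ccf_prog_min=0.4, ccf_reg_max=0.1, min_nonsilent=1)
    tighter = [
        ScreenConfig(min_power=0.8, ccf_prog_min=0.7, ccf_reg_max=0.1, min_nonsilent=1),
        ScreenConfig(min_power=0.8, ccf_prog_min=0.4, ccf_reg_max=0.01, min_nonsilent=1),
        ScreenConfig(min_power=0.8, ccf_prog_min=0.4, ccf_reg_max=0.1, min_nonsilent=2),
        ScreenConfig(min_power=0.98, ccf_prog_min=0.4, ccf_reg_max=0.1, min_nonsilent=1),
    ]
    for _ in range(20):
        samples, variants, estimates, loh_calls = _random_cohort(rng)
        base = {h.gene for h in screen_patient(estimates, variants, loh_calls, samples, loose)}
        for cfg in tighter:
            strict = {h.gene for h in screen_patient(estimates, variants, loh_calls, samples, cfg)}
            assert strict <= base
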