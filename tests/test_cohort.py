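"""Fisher enrichment, log-rank/KM survival, and closed-form assay scores."""

import math

import numpy as np
import pytest

from escapescreen import (
    ClinicalRecord,
    CompetitionObservation,
    ContingencyTable2x2,
    DdpcrCounts,
    IhcLevel,
    ParameterError,
    ResponseGroup,
    competition_score,
    ddpcr_fractional_abundance,
    expression_score,
    fisher_one_sided,
    ihc_bin,
    km_curve,
    log_rank,
    loh_enrichment_endpoint,
)


def enumerate_fisher(a, b, c, d):
    """Oracle: exact upper-tail sum over fixed-margin tables via binomials."""
    N, K, n = a + b + c + d, a + b, a + c
    denom = math.comb(N, n)
    lo, hi = max(0, K + n - N), min(K, n)
    return sum(math.comb(K, k) * math.comb(N - K, n - k) for k in range(a, hi + 1)) / denom


def test_printed_cohort_table_p_value():
    """20/69 vs 4/36 LOH split: exact one-sided p = 0.0304 (prints as 0.03)."""
    t = ContingencyTable2x2(20, 4, 49, 32)
    p = fisher_one_sided(t)
    assert p == pytest.approx(enumerate_fisher(20, 4, 49, 32), rel=1e-12)
    assert round(p, 2) == 0.03


def test_fisher_degenerate_margins_return_one():
    with pytest.warns(UserWarning):
        assert fisher_one_sided(ContingencyTable2x2(0, 0, 10, 10)) == 1.0


def test_fisher_extreme_table_closed_form():
    # all 5 LOH carriers in the non-responder column of a 5/5 split
    assert fisher_one_sided(ContingencyTable2x2(5, 0, 0, 5)) == pytest.approx(1 / 252)


def test_fisher_matches_enumeration_on_random_tables(rng):
    for _ in range(200):
        a, b, c, d = (int(x) for x in rng.integers(0, 15, size=4))
        t = ContingencyTable2x2(a, b, c, d)
        if min(a + b, c + d, a + c, b + d) == 0 or t.n == 0:
            continue
        assert fisher_one_sided(t) == pytest.approx(enumerate_fisher(a, b, c, d), rel=1e-10)


# ------------------------------------------------------------------- survival

def test_identical_groups_give_null_statistic():
    g = [(100, 1), (200, 1), (300, 0), (400, 1)]
    fit = log_rank(g, list(g))
    assert fit.statistic == pytest.approx(0.0, abs=1e-12)
    assert fit.p == pytest.approx(1.0)


def test_log_rank_rejects_empty_group_and_no_events():
    with pytest.raises(ParameterError):
        log_rank([], [(1, 1)])
    with pytest.raises(ParameterError):
        log_rank([(5, 0)], [(7, 0)])


def test_log_rank_invariant_to_group_order():
    rng = np.random.default_rng(5)
    g1 = [(float(t), int(e)) for t, e in zip(rng.exponential(300, 40), rng.random(40) < 0.7)]
    g2 = [(float(t), int(e)) for t, e in zip(rng.exponential(150, 30), rng.random(30) < 0.7)]
    f12, f21 = log_rank(g1, g2), log_rank(g2, g1)
    assert f12.statistic == pytest.approx(f21.statistic)
    assert f12.p == pytest.approx(f21.p)


def test_log_rank_matches_lifelines():
    """Independent oracle: lifelines on tied, censored data."""
    from lifelines.statistics import logrank_test

    rng = np.random.default_rng(7)
    t1 = np.round(rng.exponential(300, 60), -1)  # coarse rounding forces ties
    t2 = np.round(rng.exponential(200, 45), -1)
    e1 = (rng.random(60) < 0.7).astype(int)
    e2 = (rng.random(45) < 0.7).astype(int)
    ours = log_rank(list(zip(t1, e1)), list(zip(t2, e2)))
    ref = logrank_test(t1, t2, event_observed_A=e1, event_observed_B=e2)
    assert ours.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
    assert ours.p == pytest.approx(ref.p_value, rel=1e-9)


def test_km_without_censoring_equals_empirical_survival():
    times = [10.0, 20.0, 20.0, 35.0, 50.0]
    curve = km_curve(times, [1] * 5)
    n = len(times)
    for t, s in zip(curve["time"], curve["survival"]):
        assert s == pytest.approx(sum(x > t for x in times) / n)


def test_km_matches_lifelines_with_censoring():
    from lifelines import KaplanMeierFitter

    rng = np.random.default_rng(11)
    t = rng.exponential(100, 50)
    e = (rng.random(50) < 0.6).astype(int)
    ours = km_curve(t, e)
    kmf = KaplanMeierFitter().fit(t, e)
    for time, surv in zip(ours["time"], ours["survival"]):
        assert surv == pytest.approx(kmf.predict(time), rel=1e-9)


# ------------------------------------------------------------------- endpoint

def _clin(pid, group, days=500.0, event=1):
    return ClinicalRecord(pid, group, days, event)


def test_endpoint_reproduces_marginal_counts():
    clinical, loh = [], {}
    i = 0
    for n, group, has_loh in [
        (20, ResponseGroup.NONRESPONDER, True),
        (49, ResponseGroup.NONRESPONDER, False),
        (4, ResponseGroup.RESPONDER, True),
        (22, ResponseGroup.RESPONDER, False),
        (10, ResponseGroup.LONG_TERM_SURVIVOR, False),
    ]:
        for _ in range(n):
            pid = f"P{i}"; i += 1
            clinical.append(_clin(pid, group, days=200.0 + i, event=1))
            loh[pid] = has_loh
    table, p, fit = loh_enrichment_endpoint(clinical, loh)
    assert (table.a, table.b, table.c, table.d) == (20, 4, 49, 32)
    assert round(p, 2) == 0.03
    assert set(fit.curves) == {"LOH", "no LOH"}


def test_endpoint_degenerate_all_negative():
    clinical = [_clin("P1", ResponseGroup.NONRESPONDER), _clin("P2", ResponseGroup.RESPONDER)]
    with pytest.warns(UserWarning):
        table, p, _ = loh_enrichment_endpoint(clinical, {"P1": False, "P2": False})
    assert p == 1.0 and table.a + table.b == 0


def test_endpoint_lists_unmatched_patients():
    clinical = [_clin("P1", ResponseGroup.RESPONDER)]
    with pytest.raises(ParameterError, match="P1"):
        loh_enrichment_endpoint(clinical, {})


def test_endpoint_p_decreases_with_cohort_size():
    from escapescreen import CohortEnrichmentModel, DEFAULT_ESCAPE_GENE, SimConfig
    from escapescreen.simulate import simulate_validation_cohort

    med_ps = []
    for scale in (0.5, 1.0, 4.0):
        ps = []
        for rep in range(5):
            cfg = SimConfig(
                n_nonresponders=int(69 * scale),
                n_responders=int(26 * scale),
                n_long_term=int(10 * scale),
                seed=100 * rep + int(10 * scale),
            )
            cohort = simulate_validation_cohort(cfg)
            res = CohortEnrichmentModel.from_cohort(cohort, DEFAULT_ESCAPE_GENE).fit()
            ps.append(res.fisher_p)
        med_ps.append(np.median(ps))
    assert med_ps[2] < med_ps[0]


# ----------------------------------------------------------------- expression

def test_expression_score_values():
    assert expression_score({"a": 0.0, "b": 0.0}, ["a", "b"]) == pytest.approx(1.0)
    assert expression_score({"a": 3.0, "b": 8.0}, ["a", "b"]) == pytest.approx(6.0)
    assert expression_score({"g": 10.0}, ["g"]) == pytest.approx(11.0)


def test_expression_score_missing_genes():
    with pytest.warns(UserWarning, match="missing"):
        s = expression_score({"a": 3.0}, ["a", "zzz"])
    assert s == pytest.approx(4.0)
    with pytest.raises(ParameterError):
        expression_score({"a": 3.0}, ["zzz"])


def test_expression_score_is_monotone():
    base = expression_score({"a": 2.0, "b": 5.0}, ["a", "b"])
    assert expression_score({"a": 4.0, "b": 5.0}, ["a", "b"]) > base


# ------------------------------------------------------------- closed formulas

@pytest.mark.parametrize(
    "pct,level",
    [
        (0, IhcLevel.MINIMAL), (5, IhcLevel.MINIMAL), (10, IhcLevel.LOW),
        (49.9, IhcLevel.LOW), (50, IhcLevel.INTERMEDIATE), (80, IhcLevel.HIGH),
        (100, IhcLevel.HIGH),
    ],
)
def test_ihc_bins(pct, level):
    assert ihc_bin(pct) is level


def test_ihc_bin_domain():
    with pytest.raises(ParameterError):
        ihc_bin(120)


@pytest.mark.parametrize("mut,wt,expected", [(0, 100, 0.0), (50, 50, 50.0), (25, 75, 25.0)])
def test_ddpcr_fractional_abundance(mut, wt, expected):
    assert ddpcr_fractional_abundance(DdpcrCounts(mut, wt)) == pytest.approx(expected)


def test_ddpcr_zero_total_is_error():
    with pytest.raises(ParameterError):
        ddpcr_fractional_abundance(DdpcrCounts(0, 0))


@pytest.mark.parametrize(
    "obs,expected",
    [
        (CompetitionObservation(50, 50, 50, 50), 0.0),      # unchanged ratios
        (CompetitionObservation(0, 50, 100, 50), 100.0),    # KO fully depleted
        (CompetitionObservation(25, 50, 75, 50), 100 * (1 - 0.5 / 1.5)),
    ],
)
def test_competition_score(obs, expected):
    assert competition_score(obs) == pytest.approx(expected)


def test_competition_score_division_by_zero():
    with pytest.raises(ParameterError):
        competition_score(CompetitionObservation(10, 50, 0, 50))
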