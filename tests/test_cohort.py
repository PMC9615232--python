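"""Cohort aggregation, proportion tests, NT strata, impact tabulation."""

from math import comb

import pytest

from pestriage.cohort import (
    CohortError, fixture_summary, load_count_fixture, nt_strata_rates,
    rate_pct, summarize_cohort, tabulate_impact, two_proportion_test,
)
from pestriage.simulate import SimulationConfig, simulate_cohort
from pestriage.triage import run_cohort


@pytest.fixture(scope="module")
def small_run():
    cohort = simulate_cohort(SimulationConfig(n_cases=120, seed=9))
    results = run_cohort(
        cohort.cases, cohort.variants_by_case, cohort.kb_v1, cohort.kb_v2,
        cohort.events_by_case, cohort.reanalysis_requests,
    )
    return cohort, results


def test_summary_conservation(small_run):
    cohort, results = small_run
    s = summarize_cohort(results, cohort.cases)
    assert sum(s.per_tier.values()) == s.n_cases == len(cohort.cases)
    assert s.total_positive == s.per_tier["positive"]
    assert sum(k for k, _ in s.per_category.values()) == s.total_positive
    assert sum(n for _, n in s.per_category.values()) == s.n_cases
    assert sum(n for _, n in s.per_arm.values()) == s.n_cases


def test_duplicate_case_ids_fatal(small_run):
    cohort, results = small_run
    with pytest.raises(CohortError, match="duplicate"):
        summarize_cohort(list(results) + [results[0]], cohort.cases)


def test_empty_cohort_rates_are_null():
    s = summarize_cohort([], [])
    assert s.positive_rate() is None and s.n_cases == 0


def test_single_step2_positive(small_run):
    cohort, results = small_run
    pos2 = [r for r in results if r.tier == "positive" and r.detection_step == 2]
    if pos2:
        one = summarize_cohort(pos2[:1], cohort.cases)
        assert one.per_step_positive == {2: 1}
        assert one.positive_rate() == 100.0


def test_rate_rounding_matches_reporting_style():
    assert rate_pct(187, 1618) == 11.6
    assert rate_pct(229, 1618) == 14.2
    assert rate_pct(1, 3) == 33.3
    assert rate_pct(0, 0) is None


# ------------------------------------------------------- two-proportion test

def test_large_cohort_difference_is_significant():
    stat, p, method = two_proportion_test(98, 565, 131, 1053)
    assert method == "chi2" and p < 0.01


def test_identical_proportions_p_one():
    _, p, _ = two_proportion_test(5, 10, 5, 10)
    assert p == pytest.approx(1.0)


def _fisher_oracle(k1, n1, k2, n2):
    """Exhaustive hypergeometric enumeration of the two-sided Fisher p."""
    row1, row2 = n1, n2
    col1 = k1 + k2
    total = n1 + n2

    def table_prob(a):
        b = row1 - a
        c = col1 - a
        d = row2 - c
        if min(b, c, d) < 0:
            return None
        return comb(row1, a) * comb(row2, c) / comb(total, col1)

    p_obs = table_prob(k1)
    p = 0.0
    for a in range(0, min(row1, col1) + 1):
        pa = table_prob(a)
        if pa is not None and pa <= p_obs * (1 + 1e-9):
            p += pa
    return p


def test_fisher_matches_hypergeometric_enumeration():
    k1, n1, k2, n2 = 2, 8, 6, 9
    stat, p, method = two_proportion_test(k1, n1, k2, n2)
    assert method == "fisher"
    assert p == pytest.approx(_fisher_oracle(k1, n1, k2, n2), rel=1e-9)


def test_fisher_symmetric_under_group_swap():
    _, p1, _ = two_proportion_test(2, 8, 6, 9)
    _, p2, _ = two_proportion_test(6, 9, 2, 8)
    assert p1 == pytest.approx(p2)


def test_chi2_converges_to_fisher_with_scale():
    """For a fixed effect, the chi-square p approaches the exact Fisher p as
    counts grow; at cells of a few hundred the two agree within 0.005."""
    from scipy.stats import fisher_exact

    diffs = []
    for f in (1, 5, 25):
        k1, n1, k2, n2 = 30 * f, 100 * f, 45 * f, 100 * f
        _, p_chi, method = two_proportion_test(k1, n1, k2, n2)
        assert method == "chi2"
        _, p_f = fisher_exact([[k1, n1 - k1], [k2, n2 - k2]])
        diffs.append(abs(p_chi - p_f))
    assert diffs[0] > diffs[1] > diffs[2]
    assert diffs[-1] < 0.005


def test_invalid_counts_raise():
    with pytest.raises(CohortError):
        two_proportion_test(5, 4, 1, 10)


# --------------------------------------------------------------- NT strata

def test_nt_strata_on_constructed_cohort(small_run):
    cohort, results = small_run
    strata = nt_strata_rates(cohort.cases, results)
    for name, rec in strata.items():
        if name == "isolated_trend":
            continue
        assert rec["rate"] == rate_pct(rec["k"], rec["n"])
    iso_cases = [c for c in cohort.cases
                 if c.malformation_category == "increased_NT" and c.nt_mm >= 3.5]
    if "isolated_total" in strata:
        assert strata["isolated_total"]["n"] == len(iso_cases)


def test_nt_strata_empty_without_measurements(small_run):
    cohort, results = small_run
    import dataclasses
    stripped = [dataclasses.replace(c, nt_mm=None) for c in cohort.cases
                if c.malformation_category != "increased_NT"]
    assert nt_strata_rates(stripped, results) == {}


# ------------------------------------------------------------------ impact

def test_impact_buckets(small_run):
    cohort, results = small_run
    outcomes = {}
    for i, r in enumerate(results):
        if i % 7 == 0:
            continue  # lost to follow-up
        if r.tier == "positive":
            outcomes[r.case_id] = {"decision": "termination", "timing": "after",
                                   "reason": "es_result"}
        elif r.tier == "negative":
            outcomes[r.case_id] = {"decision": "termination", "timing": "before",
                                   "reason": "anomaly"}
        else:
            outcomes[r.case_id] = {"decision": "continuation",
                                   "reason": "inherited_from_parent"}
    tab = tabulate_impact(results, outcomes)
    total = sum(tab.tier_total(t) for t in tab.per_tier)
    assert total == len(results)
    k, n = tab.impact_fraction()
    assert 0 <= k <= n == len(results)
    pos = tab.per_tier.get("positive", {})
    assert pos.get("termination_prior_to_result", 0) == 0


def test_unknown_reason_goes_unclassified(small_run):
    cohort, results = small_run
    pos = [r for r in results if r.tier == "positive"][:1]
    tab = tabulate_impact(pos, {
        pos[0].case_id: {"decision": "termination", "timing": "after",
                         "reason": "mystery"},
    })
    assert tab.per_tier["positive"]["unclassified"] == 1


# -------------------------------------------------------- printed fixture

def test_fixture_rates_recompute_to_printed_precision():
    """Every printed rate in the packaged count fixture equals k/n to one
    decimal percent."""
    c = load_count_fixture()
    s = fixture_summary(c)
    assert s["step_positive_rate"] == {"1": 11.6, "2": 1.7, "3": 0.9}
    assert s["overall_positive_rate"] == 14.2
    assert s["overall_inconclusive_rate"] == 8.1
    assert s["family_history_rate"]["significant"] == 48.0
    assert s["nt_rate"]["isolated_3p5_4p9"] == 3.8
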