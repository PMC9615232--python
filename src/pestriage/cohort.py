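"""Cohort-level aggregation: step-wise yields, stratified diagnostic rates,
two-proportion tests, NT strata, and clinical-impact tabulation.

Rates are always recomputed from (k, n) count pairs and rounded half-up to
one decimal percent, matching clinical-report style.  The packaged
``cohort_counts.json`` fixture carries the printed count structure of a
published 1618-trio prenatal exome cohort for replay.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
from scipy import stats


class CohortError(ValueError):
    pass


def rate_pct(k: int, n: int) -> float | None:
    """k/n as a percent rounded half-up to one decimal; None for empty n."""
    if n == 0:
        return None
    return float(
        (Decimal(k) / Decimal(n) * 100).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class CohortSummary:
    n_cases: int
    per_step_positive: dict
    per_step_inconclusive: dict
    per_tier: dict
    per_category: dict  # category -> (k, n)
    per_arm: dict  # arm -> (k, n)
    family_history_strata: dict  # {"significant": (k, n), "sporadic": (k, n)}
    inheritance_mix: dict
    nt_strata: dict = field(default_factory=dict)
    high_risk_vus: int = 0

    @property
    def total_positive(self) -> int:
        return sum(self.per_step_positive.values())

    @property
    def total_inconclusive(self) -> int:
        return sum(self.per_step_inconclusive.values())

    def positive_rate(self) -> float | None:
        return rate_pct(self.total_positive, self.n_cases)

    def inconclusive_rate(self) -> float | None:
        return rate_pct(self.total_inconclusive, self.n_cases)

    def step_rates(self) -> dict:
        return {s: rate_pct(k, self.n_cases) for s, k in self.per_step_positive.items()}

    def step_shares(self) -> dict:
        """Share of positives attributable to each detection step, in percent."""
        tot = self.total_positive
        return {s: rate_pct(k, tot) for s, k in self.per_step_positive.items()}


def _inheritance_class(finding) -> str | None:
    """Map a positive finding onto the AD/AR/XL de-novo/inherited grid."""
    entry, pattern = finding.entry, finding.pattern.pattern
    if entry is None or not entry.inheritance_modes:
        return None
    if entry.x_linked:
        if pattern == "de_novo":
            return "XL_de_novo"
        return "XL_maternal"
    if "AR" in entry.inheritance_modes and pattern in (
        "homozygous_recessive", "compound_heterozygous",
    ):
        return "AR"
    if pattern == "de_novo":
        return "AD_de_novo"
    return "AD_inherited"


def summarize_cohort(results, cases) -> CohortSummary:
    """Aggregate per-case triage results into the cohort summary."""
    ids = [r.case_id for r in results]
    if len(set(ids)) != len(ids):
        raise CohortError("duplicate case ids in results")
    case_by_id = {c.case_id: c for c in cases}
    if set(ids) - set(case_by_id):
        raise CohortError("results reference unknown cases")

    per_step_pos = Counter()
    per_step_inc = Counter()
    per_tier = Counter({t: 0 for t in (
        "positive", "inconclusive", "incidental_finding", "secondary_finding",
        "candidate_gene", "negative",
    )})
    cat_n, cat_k = Counter(), Counter()
    arm_n, arm_k = Counter(), Counter()
    fh_n, fh_k = Counter(), Counter()
    inh = Counter()
    hr_vus = 0
    for r in results:
        c = case_by_id[r.case_id]
        per_tier[r.tier] += 1
        cat_n[c.malformation_category] += 1
        arm_n[c.cohort_arm] += 1
        stratum = "significant" if c.family_history.significant else (
            "other_history" if c.family_history.has_history else "sporadic"
        )
        fh_n[stratum] += 1
        if r.tier == "positive":
            per_step_pos[r.detection_step] += 1
            cat_k[c.malformation_category] += 1
            arm_k[c.cohort_arm] += 1
            fh_k[stratum] += 1
            pos_findings = r.findings_for_tier("positive")
            if pos_findings:
                cls = _inheritance_class(pos_findings[0])
                if cls:
                    inh[cls] += 1
        elif r.tier == "inconclusive":
            per_step_inc[r.detection_step] += 1
            hr_vus += int(r.high_risk_vus)
    return CohortSummary(
        n_cases=len(results),
        per_step_positive=dict(per_step_pos),
        per_step_inconclusive=dict(per_step_inc),
        per_tier=dict(per_tier),
        per_category={cat: (cat_k[cat], n) for cat, n in cat_n.items()},
        per_arm={arm: (arm_k[arm], n) for arm, n in arm_n.items()},
        family_history_strata={s: (fh_k[s], n) for s, n in fh_n.items()},
        inheritance_mix=dict(inh),
        high_risk_vus=hr_vus,
    )


def two_proportion_test(k1: int, n1: int, k2: int, n2: int):
    """Compare two proportions: Fisher's exact two-sided test when any
    expected cell is below 5, else the chi-square test without continuity
    correction.  Returns (statistic, p_value, method)."""
    for k, n in ((k1, n1), (k2, n2)):
        if not (0 <= k <= n) or n <= 0:
            raise CohortError(f"invalid counts k={k}, n={n}")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    if table.sum() == 0:
        raise CohortError("empty table")
    expected = stats.contingency.expected_freq(table)
    if (expected < 5).any():
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        return float(odds), float(p), "fisher"
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p), "chi2"


def nt_strata_rates(cases, results) -> dict:
    """Diagnostic rates by nuchal-translucency stratum.

    Strata: isolated increased NT >=3.5mm (sub-binned 3.5-4.9 and >=5.0)
    versus increased NT associated with other anomalies (3.0-3.4 and
    >=3.5).  A rank-correlation trend across the isolated bins is included
    when computable.
    """
    pos = {r.case_id for r in results if r.tier == "positive"}
    counts = {s: [0, 0] for s in (
        "isolated_total", "isolated_3p5_4p9", "isolated_ge5p0",
        "associated_3p0_3p4", "associated_ge3p5",
    )}
    iso_points = []
    for c in cases:
        if c.nt_mm is None:
            continue
        isolated = c.malformation_category == "increased_NT"
        hit = c.case_id in pos
        if isolated and c.nt_mm >= 3.5:
            for s in ("isolated_total",
                      "isolated_3p5_4p9" if c.nt_mm < 5.0 else "isolated_ge5p0"):
                counts[s][0] += int(hit)
                counts[s][1] += 1
            iso_points.append((c.nt_mm, int(hit)))
        elif not isolated:
            if 3.0 <= c.nt_mm < 3.5:
                s = "associated_3p0_3p4"
            elif c.nt_mm >= 3.5:
                s = "associated_ge3p5"
            else:
                continue
            counts[s][0] += int(hit)
            counts[s][1] += 1
    out = {
        s: {"k": k, "n": n, "rate": rate_pct(k, n)}
        for s, (k, n) in counts.items() if n
    }
    if len(iso_points) >= 3 and len({x for x, _ in iso_points}) > 1 and \
            len({y for _, y in iso_points}) > 1:
        xs, ys = zip(*iso_points)
        rho, p = stats.spearmanr(xs, ys)
        out["isolated_trend"] = {"rho": float(rho), "p": float(p)}
    return out


IMPACT_BUCKETS = (
    "termination_due_to_result",
    "termination_prior_to_result",
    "continuation_due_to_result",
    "continuation_other",
    "birth_before_report",
    "lost_to_follow_up",
    "in_pregnancy",
    "unclassified",
)

_ES_REASONS = frozenset({"es_result", "es_result_and_anomaly", "inherited_from_parent"})


@dataclass(frozen=True)
class ImpactTabulation:
    per_tier: dict  # tier -> {bucket: count}
    impact_numerator_rule: str = "reason_references_result"

    def tier_total(self, tier: str) -> int:
        return sum(self.per_tier.get(tier, {}).values())

    def impact_fraction(self) -> tuple:
        """(k, n): cases whose recorded decision cites the sequencing result."""
        k = n = 0
        for buckets in self.per_tier.values():
            n += sum(buckets.values())
            k += buckets.get("termination_due_to_result", 0)
            k += buckets.get("continuation_due_to_result", 0)
        return k, n


def tabulate_impact(results, outcomes) -> ImpactTabulation:
    """Bucket per-case pregnancy outcomes by result tier.

    *outcomes* maps case_id -> {"decision": termination|continuation|
    birth_before_report|in_pregnancy|none, "timing": before|after,
    "reason": code}.  Missing outcomes fall into lost-to-follow-up;
    unknown reason codes are held as unclassified.
    """
    log = logging.getLogger(__name__)
    per_tier = {}
    for r in results:
        buckets = per_tier.setdefault(r.tier, Counter({b: 0 for b in IMPACT_BUCKETS}))
        rec = outcomes.get(r.case_id)
        if rec is None:
            buckets["lost_to_follow_up"] += 1
            continue
        decision = rec.get("decision", "none")
        timing = rec.get("timing", "after")
        reason = rec.get("reason", "")
        if decision == "termination":
            if timing == "before":
                buckets["termination_prior_to_result"] += 1
            elif reason in _ES_REASONS:
                buckets["termination_due_to_result"] += 1
            else:
                log.warning("unknown termination reason %r for %s", reason, r.case_id)
                buckets["unclassified"] += 1
        elif decision == "continuation":
            if reason in _ES_REASONS:
                buckets["continuation_due_to_result"] += 1
            else:
                buckets["continuation_other"] += 1
        elif decision == "birth_before_report":
            buckets["birth_before_report"] += 1
        elif decision == "in_pregnancy":
            buckets["in_pregnancy"] += 1
        else:
            buckets["lost_to_follow_up"] += 1
    return ImpactTabulation(per_tier={t: dict(b) for t, b in per_tier.items()})


# ------------------------------------------------------------ printed fixture

def load_count_fixture() -> dict:
    """The packaged printed-count structure of the reference cohort."""
    text = resources.files("pestriage.data").joinpath("cohort_counts.json").read_text()
    return json.loads(text)


def fixture_summary(counts: dict | None = None) -> dict:
    """Recompute every headline rate of the reference cohort from its
    printed (k, n) counts."""
    c = counts or load_count_fixture()
    n = c["n_cases"]
    tot_pos = sum(v["positive"] for v in c["per_step"].values())
    tot_inc = sum(v["inconclusive"] for v in c["per_step"].values())
    inh = c["inheritance_mix"]
    ad = inh["AD_de_novo"] + inh["AD_inherited"]
    ar = inh["AR"]
    xl = inh["XL_de_novo"] + inh["XL_maternal"]
    fh = c["family_history"]
    arms = c["arm_positive"]
    nt = c["nt_strata"]
    stat, p, method = two_proportion_test(*arms["retrospective"], *arms["prospective"])
    return {
        "n_cases": n,
        "step_positive_rate": {
            s: rate_pct(v["positive"], n) for s, v in c["per_step"].items()
        },
        "step_inconclusive_rate": {
            s: rate_pct(v["inconclusive"], n) for s, v in c["per_step"].items()
        },
        "total_positive": tot_pos,
        "total_inconclusive": tot_inc,
        "overall_positive_rate": rate_pct(tot_pos, n),
        "overall_inconclusive_rate": rate_pct(tot_inc, n),
        "step_share_of_positives": {
            s: rate_pct(v["positive"], tot_pos) for s, v in c["per_step"].items()
        },
        "inheritance_share": {
            "AD": rate_pct(ad, tot_pos),
            "AR": rate_pct(ar, tot_pos),
            "XL": rate_pct(xl, tot_pos),
        },
        "family_history_rate": {
            "significant": rate_pct(*fh["significant"]),
            "sporadic": rate_pct(*fh["sporadic"]),
        },
        "arm_rate": {a: rate_pct(*kn) for a, kn in arms.items()},
        "arm_test": {"statistic": stat, "p": p, "method": method},
        "nt_rate": {
            s: rate_pct(k, nn) for s, (k, nn) in nt.items() if k is not None
        },
    }
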