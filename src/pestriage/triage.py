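"""Three-step prenatal exome triage and five-tier result assignment.

Step 1 screens by genotype only: known-P/LP alleles, extremely rare null
changes, and rare variants with a causal-prone inheritance pattern (de
novo, homozygous, compound heterozygous, hemizygous).  Step 2 reviews rare
protein-altering variants in disease genes whose phenotype annotations
match the initial clinical indications, adding phenotype-informed evidence
(co-segregation, literature, phenotype specificity).  Step 3 reanalyzes on
new phenotypes, a new knowledge-base version, or orthogonal evidence
events (intragenic CNVs, focused Sanger second alleles).

Results are classified per case into positive / inconclusive / incidental
finding / secondary finding / candidate gene / negative, with a high-risk
flag for phenotype-consistent VUS carrying deleteriousness, literature, or
family-recurrence support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from . import acmg
from .acmg import Classification, combine, auto_assign
from .inheritance import (
    FamilyHistory, InheritancePattern, deduce_single, phase_compound_het,
    segregation_check,
)
from .knowledge_base import (
    CATEGORY_HEAD_TERMS, MALFORMATION_CATEGORIES, GeneDiseaseEntry,
    HPOOntology, KnowledgeBaseVersion, hpo_ancestors,
)
from .trio_io import Pedigree, VariantObservation

#: rarity ceiling for step-1/step-2 candidate variants
RARE_AF = 1e-3

STAGES = ("initial", "late_prenatal", "postnatal")
_STAGE_RANK = {s: i for i, s in enumerate(STAGES)}

TIERS = (
    "positive", "inconclusive", "incidental_finding", "secondary_finding",
    "candidate_gene", "negative",
)
_TIER_RANK = {t: i for i, t in enumerate(TIERS)}

#: ancestors too generic to support a superclass phenotype match
_GENERIC_TERMS = frozenset({"HP:0000001", "HP:0000118"})


class TriageError(ValueError):
    pass


@dataclass(frozen=True)
class FetalCase:
    case_id: str
    pedigree: Pedigree
    phenotypes: tuple  # ((HPO term, stage in STAGES), ...)
    malformation_category: str
    nt_mm: float | None = None
    family_history: FamilyHistory = field(default_factory=FamilyHistory)
    cohort_arm: str = "prospective"
    gestational_age_weeks: float = 25.0

    def __post_init__(self):
        if self.malformation_category not in MALFORMATION_CATEGORIES:
            raise TriageError(f"bad malformation category {self.malformation_category!r}")
        if not self.phenotypes:
            raise TriageError(f"{self.case_id}: phenotype list must be non-empty")
        for term, stage in self.phenotypes:
            if stage not in STAGES:
                raise TriageError(f"{self.case_id}: bad phenotype stage {stage!r}")
        if self.malformation_category == "increased_NT" and (
            self.nt_mm is None or self.nt_mm < 3.0
        ):
            raise TriageError(f"{self.case_id}: increased_NT requires nt_mm >= 3.0")
        if self.cohort_arm not in ("retrospective", "prospective"):
            raise TriageError(f"bad cohort arm {self.cohort_arm!r}")

    def terms_at(self, stage: str = "initial") -> frozenset:
        """Phenotype terms observed at or before *stage*."""
        cut = _STAGE_RANK[stage]
        return frozenset(t for t, s in self.phenotypes if _STAGE_RANK[s] <= cut)


@dataclass(frozen=True)
class MatchLevel:
    level: str  # exact | superclass | literature | none
    matched_terms: frozenset = frozenset()

    def __post_init__(self):
        if self.level not in ("exact", "superclass", "literature", "none"):
            raise TriageError(f"bad match level {self.level!r}")
        if self.level == "exact" and not self.matched_terms:
            raise TriageError("exact match requires matched terms")

    @property
    def matched(self) -> bool:
        return self.level != "none"


NO_MATCH = MatchLevel("none")


@dataclass(frozen=True)
class VariantFinding:
    variant: VariantObservation
    classification: Classification
    pattern: InheritancePattern
    match: MatchLevel
    tier: str
    entry: GeneDiseaseEntry | None = None
    detection_step: int | None = None
    evidence: tuple = ()


@dataclass(frozen=True)
class CaseResult:
    case_id: str
    tier: str
    detection_step: int | None  # 1 | 2 | 3 | None (negative)
    findings: tuple = ()  # VariantFinding, all reviewed variants
    high_risk_vus: bool = False
    history: tuple = ()  # (timestamp, old_tier, new_tier, trigger)
    shortlist_size: int = 0
    reviewed_total: int = 0

    def __post_init__(self):
        if self.tier not in TIERS:
            raise TriageError(f"bad tier {self.tier!r}")
        if (self.detection_step is None) != (self.tier == "negative"):
            raise TriageError("detection_step is None exactly for negative results")

    def findings_for_tier(self, tier: str):
        return [f for f in self.findings if f.tier == tier]


# ------------------------------------------------------------------- matching

def _informative_closure(terms, ontology: HPOOntology) -> frozenset:
    out = set()
    for t in terms:
        out.add(t)
        out |= hpo_ancestors(t, ontology)
    return frozenset(out - _GENERIC_TERMS)


def step2_phenotype_match(
    entry: GeneDiseaseEntry, case: FetalCase, ontology: HPOOntology,
    stage: str = "initial",
) -> MatchLevel:
    """Phenotype relevance of a disease gene for a case.

    ``exact`` on a shared HPO term; ``superclass`` when the gene's
    annotations and the case's terms meet in a non-generic ancestor (the
    entry annotates an organ-system class subsuming a case term, or vice
    versa); ``literature`` when the knowledge base links the gene to a case
    term through prior reported cases only.
    """
    case_terms = case.terms_at(stage)
    exact = entry.hpo_terms & case_terms
    if exact:
        return MatchLevel("exact", frozenset(exact))
    entry_closure = _informative_closure(entry.hpo_terms, ontology)
    case_closure = _informative_closure(case_terms, ontology)
    shared = entry_closure & case_closure
    if shared:
        return MatchLevel("superclass", frozenset(shared))
    lit = entry.literature_hpo & case_terms
    if lit:
        return MatchLevel("literature", frozenset(lit))
    return NO_MATCH


def best_match(
    kb: KnowledgeBaseVersion, gene_symbol: str, case: FetalCase,
    stage: str = "initial",
):
    """Best (match, entry) over all KB entries of a gene; (NO_MATCH, first
    entry or None) when nothing matches."""
    order = {"exact": 0, "superclass": 1, "literature": 2, "none": 3}
    best = (NO_MATCH, None)
    for entry in kb.entries_for_gene(gene_symbol):
        m = step2_phenotype_match(entry, case, kb.ontology, stage)
        if best[1] is None or order[m.level] < order[best[0].level]:
            best = (m, entry)
    return best


# ------------------------------------------------------------------ tier rule

def assign_tier(
    classification: Classification,
    match: MatchLevel,
    entry: GeneDiseaseEntry | None,
    pattern: InheritancePattern,
    variant: VariantObservation,
) -> str:
    """Five-tier assignment for one classified, phenotype-matched variant."""
    if classification.is_plp:
        if match.matched:
            return "positive"
        if entry is not None and entry.sf_list:
            return "secondary_finding"
        if entry is not None and entry.onset_class == "childhood":
            return "incidental_finding"
        return "negative"
    if classification.label == "VUS":
        if match.matched and entry is not None and entry.gene_status == "established":
            return "inconclusive"
        if (
            variant.deleterious_predicted
            and variant.pop_af is None
            and entry is not None
            and entry.gene_status == "undefined"
            and entry.paralog_or_model_support
        ):
            return "candidate_gene"
    return "negative"


def flag_high_risk_vus(result: CaseResult) -> bool:
    """High-risk inconclusive: phenotype-consistent VUS with deleteriousness,
    literature, or a prior similarly affected fetus in the family."""
    if result.tier != "inconclusive":
        return False
    for f in result.findings_for_tier("inconclusive"):
        if f.match.level not in ("exact", "superclass"):
            continue
        if (
            f.variant.deleterious_predicted
            or f.variant.literature_reported
            or (f.entry is not None and bool(f.entry.literature_hpo))
        ):
            return True
    return False


def _prior_affected_fetus(case: FetalCase) -> bool:
    return case.family_history.significant


# ------------------------------------------------------------------- pipeline

def _is_rare(variant: VariantObservation, rare_af: float) -> bool:
    return variant.pop_af is None or variant.pop_af < rare_af


def _protein_altering(variant: VariantObservation) -> bool:
    return variant.consequence not in ("synonymous", "other")


def step1_genotype_screen(
    case: FetalCase,
    variants,
    kb: KnowledgeBaseVersion,
    rare_af: float = RARE_AF,
    denovo_af_demote: float = 1e-3,
):
    """Genotype-driven shortlist: known P/LP alleles, rare null changes, and
    rare variants with a captured inheritance pattern.  Phenotype data are
    not consulted.  Returns (shortlist entries, pattern map)."""
    ped = case.pedigree
    carried = [
        v for v in variants
        if v.quality_pass and v.genotype(ped.proband_id) in ("0/1", "1/1", "1")
    ]
    patterns = {v.key: deduce_single(v, ped, denovo_af_demote) for v in carried}
    # gene-level comp-het phasing upgrades the per-variant patterns
    by_gene = {}
    for v in carried:
        by_gene.setdefault(v.gene_symbol, []).append(v)
    for gene, vs in by_gene.items():
        for pair in phase_compound_het(vs, ped, denovo_af_demote):
            if pair.pattern == "compound_heterozygous":
                for key, _origin in pair.origin_detail:
                    patterns[key] = pair
    shortlist = []
    for v in carried:
        if not _is_rare(v, rare_af):
            continue
        pattern = patterns[v.key]
        captured = (
            v.known_plp
            or (v.is_null and _protein_altering(v))
            or (pattern.captured and _protein_altering(v))
        )
        if captured:
            shortlist.append((v, pattern))
    return shortlist, patterns


def _classify(
    variant, pattern, entry, case, kb, match, step: int,
    relative_genotypes=None, extra_codes=(),
):
    """Evidence assignment and combining for one variant at a given step."""
    history = segregation_check(
        variant, case.pedigree,
        relative_genotypes=relative_genotypes,
        has_history=case.family_history.has_history,
        phenotype_similar=case.family_history.significant,
    )
    in_trans = False
    if pattern.pattern == "compound_heterozygous":
        partners = [k for k, _ in pattern.origin_detail if k != variant.key]
        in_trans = bool(partners)
    codes = list(auto_assign(
        variant, pattern, entry, history, in_trans_with_plp=in_trans,
        expert_codes=extra_codes,
    ))
    # phenotype-driven review adds PP4 when the gene matches the presentation
    # at the specific-term level (steps 2 and 3 only: step 1 is phenotype-blind)
    if step >= 2 and match.level == "exact":
        if not any(c.base == "PP4" for c in codes):
            codes.append(acmg.EvidenceCode("PP4", "supporting"))
    classification = combine(codes)
    # P/LP is only assertable against an established gene-disease link;
    # variants in undefined or unknown genes are capped at VUS
    if classification.is_plp and (entry is None or entry.gene_status != "established"):
        classification = Classification(
            "VUS", "undefined_gene", classification.evidence_summary
        )
    return classification, tuple(codes)


def analyze_case(
    case: FetalCase,
    variants,
    kb: KnowledgeBaseVersion,
    rare_af: float = RARE_AF,
    stage: str = "initial",
    event_codes_by_gene=None,
    extra_findings=(),
) -> CaseResult:
    """Run steps 1 and 2 for one case and assign the case-level tier.

    ``stage`` limits which phenotype observations are visible (reanalysis
    passes a later stage).  ``event_codes_by_gene`` and ``extra_findings``
    carry reanalysis evidence events into the classification.
    """
    ped = case.pedigree
    event_codes_by_gene = event_codes_by_gene or {}
    shortlist, patterns = step1_genotype_screen(case, variants, kb, rare_af)
    shortlist_keys = {v.key for v, _ in shortlist}
    findings = []

    # --- step 1: classify the genotype-driven shortlist
    for v, pattern in shortlist:
        match, entry = best_match(kb, v.gene_symbol, case, stage)
        classification, codes = _classify(
            v, pattern, entry, case, kb, match, step=1,
            extra_codes=tuple(event_codes_by_gene.get(v.gene_symbol, ())),
        )
        tier = assign_tier(classification, match, entry, pattern, v)
        findings.append(VariantFinding(
            variant=v, classification=classification, pattern=pattern,
            match=match, tier=tier, entry=entry, detection_step=1,
            evidence=codes,
        ))

    # --- step 2: phenotype-driven comprehensive review of rare variants in
    # matching disease genes that the genotype screen did not capture
    carried = [
        v for v in variants
        if v.quality_pass and v.genotype(ped.proband_id) in ("0/1", "1/1", "1")
    ]
    reviewed_step2 = 0
    for v in carried:
        if v.key in shortlist_keys or not _is_rare(v, rare_af):
            continue
        if not _protein_altering(v):
            continue
        if v.gene_symbol not in kb.genes():
            continue
        match, entry = best_match(kb, v.gene_symbol, case, stage)
        if not match.matched:
            continue
        reviewed_step2 += 1
        pattern = patterns.get(v.key, deduce_single(v, ped))
        classification, codes = _classify(
            v, pattern, entry, case, kb, match, step=2,
            extra_codes=tuple(event_codes_by_gene.get(v.gene_symbol, ())),
        )
        tier = assign_tier(classification, match, entry, pattern, v)
        findings.append(VariantFinding(
            variant=v, classification=classification, pattern=pattern,
            match=match, tier=tier, entry=entry, detection_step=2,
            evidence=codes,
        ))

    findings.extend(extra_findings)

    case_tier = "negative"
    detection_step = None
    for f in findings:
        if _TIER_RANK[f.tier] < _TIER_RANK[case_tier]:
            case_tier = f.tier
            detection_step = f.detection_step
    result = CaseResult(
        case_id=case.case_id,
        tier=case_tier,
        detection_step=detection_step,
        findings=tuple(findings),
        shortlist_size=len(shortlist),
        reviewed_total=len(shortlist) + reviewed_step2,
    )
    if result.tier == "inconclusive":
        hr = flag_high_risk_vus(result) or (
            _prior_affected_fetus(case)
            and any(
                f.match.level in ("exact", "superclass")
                for f in result.findings_for_tier("inconclusive")
            )
        )
        result = replace(result, high_risk_vus=hr)
    return result


# ----------------------------------------------------------------- reanalysis

def _event_finding(event, case, kb, stage) -> VariantFinding | None:
    """Turn an intragenic-CNV evidence event into a P/LP finding."""
    entries = kb.entries_for_gene(event.gene_symbol)
    if not entries:
        return None
    match, entry = best_match(kb, event.gene_symbol, case, stage)
    codes = tuple(
        c if isinstance(c, acmg.EvidenceCode) else acmg.parse_code(c, source="event")
        for c in event.classification_payload
    )
    classification = combine(codes) if codes else Classification("P", "event:cnv")
    placeholder = VariantObservation(
        chrom=event.gene_symbol, pos=1, ref="N", alt="<DEL>",
        gene_symbol=event.gene_symbol, consequence="other",
        genotypes={case.pedigree.proband_id: "0/1"},
    )
    pattern = InheritancePattern("unresolved")
    tier = assign_tier(classification, match, entry, pattern, placeholder)
    return VariantFinding(
        variant=placeholder, classification=classification, pattern=pattern,
        match=match, tier=tier, entry=entry, detection_step=3,
        evidence=codes,
    )


def step3_reanalyze(
    result: CaseResult,
    case: FetalCase,
    variants,
    kb_new: KnowledgeBaseVersion,
    events=(),
    kb_old_tag: str | None = None,
    rare_af: float = RARE_AF,
    timestamp: str = "reanalysis",
) -> CaseResult:
    """Reanalysis on new phenotypes, a new KB version, or evidence events.

    With no trigger the input result is returned unchanged (idempotent).
    Tier transitions are appended to the result history; findings that
    become positive only now are attributed to detection step 3, while a
    previously assigned tier keeps its original step.
    """
    new_phenotypes = bool(case.terms_at("postnatal") - case.terms_at("initial"))
    kb_changed = kb_old_tag is not None and kb_old_tag != kb_new.version_tag
    events = tuple(events)
    if not (new_phenotypes or kb_changed or events):
        return result

    event_codes = {}
    extra_findings = []
    for event in events:
        if event.kind == "second_allele_sanger":
            codes = tuple(
                c if isinstance(c, acmg.EvidenceCode) else acmg.parse_code(c, source="event")
                for c in event.classification_payload
            ) or (acmg.EvidenceCode("PM3", "moderate", source="event"),)
            event_codes[event.gene_symbol] = event_codes.get(event.gene_symbol, ()) + codes
        elif event.kind == "intragenic_cnv":
            finding = _event_finding(event, case, kb_new, "postnatal")
            if finding is None:
                logging.getLogger(__name__).warning(
                    "event for gene %s absent from KB, held", event.gene_symbol
                )
                continue
            extra_findings.append(finding)

    renewed = analyze_case(
        case, variants, kb_new, rare_af=rare_af, stage="postnatal",
        event_codes_by_gene=event_codes, extra_findings=tuple(extra_findings),
    )

    # step attribution: keep the original step for findings whose tier was
    # already assigned before reanalysis; new or upgraded ones become step 3
    prior_step = result.detection_step
    if renewed.tier == result.tier:
        detection_step = prior_step
    elif renewed.tier == "negative":
        detection_step = None
    else:
        detection_step = 3
    history = result.history
    if renewed.tier != result.tier:
        trigger = (
            "new_phenotype" if new_phenotypes else
            ("kb_update" if kb_changed else "evidence_event")
        )
        history = history + ((timestamp, result.tier, renewed.tier, trigger),)
    findings = tuple(
        replace(f, detection_step=3)
        if renewed.tier != result.tier and f.tier == renewed.tier
        else f
        for f in renewed.findings
    )
    return replace(
        renewed,
        detection_step=detection_step,
        findings=findings,
        history=history,
    )


def run_cohort(
    cases,
    variants_by_case: dict,
    kb: KnowledgeBaseVersion,
    kb_new: KnowledgeBaseVersion | None = None,
    events_by_case: dict | None = None,
    reanalysis_requests=frozenset(),
    rare_af: float = RARE_AF,
) -> list:
    """Run the full three-step workflow over a cohort.

    Every case gets the step-1/step-2 analysis against *kb*.  Reanalysis
    (step 3) runs for cases with late/postnatal phenotypes, pending
    evidence events, or an explicit physician request; requested cases are
    re-screened against *kb_new* when provided.
    """
    events_by_case = events_by_case or {}
    results = []
    for case in cases:
        variants = variants_by_case[case.case_id]
        result = analyze_case(case, variants, kb, rare_af=rare_af)
        events = events_by_case.get(case.case_id, ())
        new_pheno = bool(case.terms_at("postnatal") - case.terms_at("initial"))
        requested = case.case_id in reanalysis_requests
        if new_pheno or events or requested:
            kb_re = kb_new if (requested and kb_new is not None) else kb
            result = step3_reanalyze(
                result, case, variants, kb_re, events=events,
                kb_old_tag=kb.version_tag, rare_af=rare_af,
            )
        results.append(result)
    return results


def reclassify_nt_category(case: FetalCase, ontology: HPOOntology) -> FetalCase:
    """Re-bin an increased-NT case whose late phenotypes localize to organ
    systems: one system -> that category, two or more -> multisystem."""
    if case.malformation_category != "increased_NT":
        return case
    late_terms = case.terms_at("postnatal") - case.terms_at("initial")
    head_to_cat = {
        head: cat for cat, head in CATEGORY_HEAD_TERMS.items()
        if cat != "increased_NT"
    }
    systems = set()
    for term in late_terms:
        closure = {term} | hpo_ancestors(term, ontology)
        for head in closure & set(head_to_cat):
            systems.add(head_to_cat[head])
    if not systems:
        return case
    new_cat = systems.pop() if len(systems) == 1 else "multisystem"
    return replace(case, malformation_category=new_cat)
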