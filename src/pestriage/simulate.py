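"""Synthetic trio-cohort generator with planted truth.

Emulates the statistical structure the triage pipeline assumes: a cohort
of fetus–mother–father trios in which a configurable fraction carries a
planted diagnostic variant drawn from the bundled knowledge base with a
realistic inheritance-mode mix (AD de novo, AR biallelic, X-linked), a
step-discoverability mix (genotype-driven, phenotype-driven, reanalysis),
and planted VUS / incidental-finding / secondary-finding / candidate-gene
cases, on a background of common or synonymous variants that a triage run
must rule out.

Genome coordinates are synthetic (one contig per autosomal gene, a shared
``chrX`` contig for X-linked genes); there is no reference-sequence,
coverage, or sequencing-error modelling.  Each case draws from its own
random stream keyed by (seed, case index), so cohorts are reproducible
under case-order shuffling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .inheritance import FamilyHistory
from .knowledge_base import (
    CATEGORY_HEAD_TERMS, KnowledgeBaseVersion, hpo_ancestors, packaged_kb,
    packaged_ontology,
)
from .triage import FetalCase
from .trio_io import EvidenceEvent, Pedigree, VariantObservation, write_ped, write_trio_vcf

_REST = (1.0 - (0.179 + 0.162 + 0.128 + 0.114)) / 7.0

DEFAULT_CATEGORY_WEIGHTS = {
    "cardiovascular": 0.179,
    "central_nervous": 0.162,
    "skeletal": 0.128,
    "urogenital": 0.114,
    "facial": _REST,
    "chest": _REST,
    "abdominal": _REST,
    "multisystem": _REST,
    "isolated_hydrops": _REST,
    "FGR": _REST,
    "increased_NT": _REST,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters of the emulated cohort.

    Defaults follow the reference cohort: 14.2% of cases carry a
    diagnostic variant, discoverable at steps 1/2/3 in proportions
    0.817/0.122/0.061, with an AD/AR/XL mix of 0.751/0.175/0.074 among
    positives; 8.1% VUS, 0.5% incidental and 0.8% secondary findings,
    1.9% candidate-gene cases; ~34 background variants ruled out per case.
    """

    n_cases: int = 200
    seed: int = 0
    category_weights: dict = field(default_factory=lambda: dict(DEFAULT_CATEGORY_WEIGHTS))
    causal_fraction: float = 0.142
    step_mix: tuple = (0.817, 0.122, 0.061)
    inheritance_mix: tuple = (0.751, 0.175, 0.074)  # AD, AR, XL among positives
    vus_fraction: float = 0.081
    if_fraction: float = 0.005
    sf_fraction: float = 0.008
    candidate_fraction: float = 0.019
    background_variants_per_case: int = 34
    late_phenotype_prob: float = 0.18
    family_history_prob: float = 0.083
    significant_history_frac: float = 0.75
    retrospective_frac: float = 0.349  # 565/1618
    xl_maternal_frac: float = 0.59  # 10/17 maternally inherited among XL
    ar_comphet_frac: float = 0.6
    nt_measured_prob: float = 0.4

    def __post_init__(self):
        for name, probs in (
            ("category_weights", tuple(self.category_weights.values())),
            ("step_mix", self.step_mix),
            ("inheritance_mix", self.inheritance_mix),
        ):
            if abs(sum(probs) - 1.0) > 1e-6:
                raise ValueError(f"{name} must sum to 1 (got {sum(probs):.6f})")
        fracs = (
            self.causal_fraction, self.vus_fraction, self.if_fraction,
            self.sf_fraction, self.candidate_fraction, self.late_phenotype_prob,
            self.family_history_prob,
        )
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("all fractions must lie in [0, 1]")
        if sum(fracs[:5]) > 1.0:
            raise ValueError("case-class fractions exceed 1")


@dataclass(frozen=True)
class TruthRecord:
    case_id: str
    planted_tier: str  # positive/inconclusive/incidental_finding/...
    planted_variants: tuple = ()  # variant keys
    planted_pattern: str | None = None
    planted_step: int | None = None
    planted_gene: str | None = None
    late_phenotype: bool = False
    flavor: str = ""


@dataclass(frozen=True)
class SyntheticCohort:
    config: SimulationConfig
    cases: tuple  # FetalCase
    variants_by_case: dict  # case_id -> list of VariantObservation
    events_by_case: dict  # case_id -> tuple of EvidenceEvent
    reanalysis_requests: frozenset  # case ids with a physician-request trigger
    truth: tuple  # TruthRecord
    kb_v1: KnowledgeBaseVersion
    kb_v2: KnowledgeBaseVersion


class SimulationError(ValueError):
    pass


# ------------------------------------------------------------- gene pools

def _entry_category(entry, ontology) -> str | None:
    head_to_cat = {v: k for k, v in CATEGORY_HEAD_TERMS.items()}
    for term in sorted(entry.hpo_terms):
        closure = {term} | hpo_ancestors(term, ontology)
        for head in sorted(closure & set(head_to_cat)):
            return head_to_cat[head]
    return None


def _build_pools(kb: KnowledgeBaseVersion, kb_v2: KnowledgeBaseVersion):
    onto = kb.ontology
    pools = {"AD": {}, "AR": {}, "XL": {}, "step2": {}}
    if_pool, sf_pool, cand_pool = [], [], []
    for e in kb.entries:
        cat = _entry_category(e, onto)
        if e.gene_status == "undefined":
            if e.paralog_or_model_support:
                cand_pool.append(e)
            continue
        if e.sf_list:
            sf_pool.append(e)
            continue
        if e.onset_class == "childhood":
            if "AD" in e.inheritance_modes:
                if_pool.append(e)
            continue
        if cat is None:
            continue
        if e.x_linked and e.lof_mechanism:
            pools["XL"].setdefault(cat, []).append(e)
        if "AD" in e.inheritance_modes and e.lof_mechanism:
            pools["AD"].setdefault(cat, []).append(e)
        if "AD" in e.inheritance_modes:
            pools["step2"].setdefault(cat, []).append(e)
        if "AR" in e.inheritance_modes and e.lof_mechanism:
            pools["AR"].setdefault(cat, []).append(e)
    new_genes = [
        e for e in kb_v2.entries
        if e.gene_symbol not in kb.genes() and e.gene_status == "established"
    ]
    for mode in ("AD", "AR"):
        if not pools[mode]:
            raise SimulationError(f"knowledge base lacks genes for mode {mode}")
    if not pools["XL"]:
        raise SimulationError("knowledge base lacks X-linked genes")
    return pools, if_pool, sf_pool, cand_pool, new_genes


def _pick_category(rng, weights: dict, allowed=None) -> str:
    cats = [c for c in weights if allowed is None or c in allowed]
    w = np.array([weights[c] for c in cats], dtype=float)
    w = w / w.sum()
    return cats[rng.choice(len(cats), p=w)]


# ------------------------------------------------------------ variant forge

_BASES = ("A", "C", "G", "T")


def _contig(entry) -> str:
    return "chrX" if entry.x_linked else entry.gene_symbol


class _VariantForge:
    """Deterministic synthetic variant builder (one per call, unique pos)."""

    def __init__(self, rng, samples):
        self.rng = rng
        self.samples = samples
        self._pos = {}

    def _next_pos(self, contig: str) -> int:
        self._pos[contig] = self._pos.get(contig, 1000) + int(self.rng.integers(50, 500))
        return self._pos[contig]

    def make(self, gene: str, contig: str, consequence: str, genotypes: dict,
             pop_af=None, deleterious=False, known_plp=False, literature=False):
        ref = _BASES[int(self.rng.integers(4))]
        alt = _BASES[(_BASES.index(ref) + 1 + int(self.rng.integers(3))) % 4]
        gts = {s: genotypes.get(s, "0/0") for s in self.samples}
        return VariantObservation(
            chrom=contig, pos=self._next_pos(contig), ref=ref, alt=alt,
            gene_symbol=gene, consequence=consequence, pop_af=pop_af,
            genotypes=gts, deleterious_predicted=deleterious,
            known_plp=known_plp, literature_reported=literature,
        )


# ------------------------------------------------------------- case builder

_NULL_CHOICES = ("nonsense", "frameshift", "splice_donor_acceptor")


def _case_terms(rng, entry, n=2):
    terms = sorted(entry.hpo_terms)
    k = min(n, len(terms))
    idx = rng.choice(len(terms), size=k, replace=False)
    return [terms[i] for i in sorted(idx)]


def _category_noise_term(rng, ontology, category: str, exclude=()):
    """A leaf term under the category head, excluding given terms."""
    head = CATEGORY_HEAD_TERMS.get(category)
    if head is None:  # multisystem: any head
        head = CATEGORY_HEAD_TERMS[
            sorted(CATEGORY_HEAD_TERMS)[int(rng.integers(len(CATEGORY_HEAD_TERMS)))]
        ]
    pool = sorted(
        t for t in ontology.terms
        if head in hpo_ancestors(t, ontology) and t not in exclude
    )
    return pool[int(rng.integers(len(pool)))] if pool else head


def _superclass_terms(rng, ontology, entry):
    """Terms sharing the entry's organ system but absent from its annotations."""
    cat = _entry_category(entry, ontology)
    term = _category_noise_term(
        rng, ontology, cat or "central_nervous", exclude=entry.hpo_terms
    )
    return [term]


def simulate_case(index: int, config: SimulationConfig, pools, if_pool, sf_pool,
                  cand_pool, new_genes, ontology):
    """Generate one trio: case metadata, variants, events, truth record."""
    rng = np.random.default_rng([config.seed, index])
    cid = f"SYN{index:05d}"
    pro, fat, mot = f"{cid}P", f"{cid}F", f"{cid}M"
    samples = [pro, fat, mot]

    # case class
    classes = ("positive", "inconclusive", "incidental_finding",
               "secondary_finding", "candidate_gene", "negative")
    probs = np.array([
        config.causal_fraction, config.vus_fraction, config.if_fraction,
        config.sf_fraction, config.candidate_fraction, 0.0,
    ])
    probs[-1] = 1.0 - probs.sum()
    planted_tier = classes[rng.choice(len(classes), p=probs)]

    arm = "retrospective" if rng.random() < config.retrospective_frac else "prospective"
    sex = "male" if rng.random() < 0.5 else "female"
    relatives = []
    affected_parents = set()
    phenos = []  # (term, stage)
    variants = []
    events = ()
    requests = set()
    family_history = FamilyHistory()
    planted_step = None
    pattern = None
    flavor = ""
    gene_entry = None
    planted_keys = ()
    category = None
    late = False

    step_rng = rng  # alias, single stream per case

    def finish_background(forge):
        n_bg = int(step_rng.poisson(config.background_variants_per_case))
        bg_genes = [f"BG{int(step_rng.integers(1, 60)):02d}" for _ in range(n_bg)]
        for g in bg_genes:
            if step_rng.random() < 0.7:
                # common protein-altering variant, inherited
                carrier = fat if step_rng.random() < 0.5 else mot
                variants.append(forge.make(
                    g, g, "missense",
                    {pro: "0/1", carrier: "0/1"},
                    pop_af=float(step_rng.uniform(0.01, 0.2)),
                ))
            else:
                # rare synonymous change
                carrier = fat if step_rng.random() < 0.5 else mot
                variants.append(forge.make(
                    g, g, "synonymous",
                    {pro: "0/1", carrier: "0/1"},
                    pop_af=None if step_rng.random() < 0.5 else 1e-5,
                ))

    forge = _VariantForge(rng, samples)

    if planted_tier == "positive":
        planted_step = 1 + int(rng.choice(3, p=np.array(config.step_mix)))
        if planted_step == 1:
            mode = ("AD", "AR", "XL")[int(rng.choice(3, p=np.array(config.inheritance_mix)))]
            if mode == "XL":
                sex = "male"
            category = _pick_category(rng, config.category_weights, allowed=pools[mode])
            entries = pools[mode][category]
            gene_entry = entries[int(rng.integers(len(entries)))]
            contig = _contig(gene_entry)
            if mode == "AD":
                consequence = (
                    _NULL_CHOICES[int(rng.integers(3))] if rng.random() < 0.5 else "missense"
                )
                v = forge.make(
                    gene_entry.gene_symbol, contig, consequence,
                    {pro: "0/1"}, pop_af=None, deleterious=True,
                )
                variants.append(v)
                pattern, planted_keys = "de_novo", (v.key,)
            elif mode == "AR":
                consequence = _NULL_CHOICES[int(rng.integers(3))]
                if rng.random() < config.ar_comphet_frac:
                    v1 = forge.make(gene_entry.gene_symbol, contig, consequence,
                                    {pro: "0/1", fat: "0/1"}, pop_af=None)
                    v2 = forge.make(gene_entry.gene_symbol, contig,
                                    _NULL_CHOICES[int(rng.integers(3))],
                                    {pro: "0/1", mot: "0/1"}, pop_af=None)
                    variants.extend([v1, v2])
                    pattern, planted_keys = "compound_heterozygous", (v1.key, v2.key)
                else:
                    v = forge.make(gene_entry.gene_symbol, contig, consequence,
                                   {pro: "1/1", fat: "0/1", mot: "0/1"}, pop_af=None)
                    variants.append(v)
                    pattern, planted_keys = "homozygous_recessive", (v.key,)
            else:  # XL, male proband
                consequence = _NULL_CHOICES[int(rng.integers(3))]
                if rng.random() < config.xl_maternal_frac:
                    v = forge.make(gene_entry.gene_symbol, "chrX", consequence,
                                   {pro: "1", fat: "0", mot: "0/1"}, pop_af=None)
                    pattern = "hemizygous"
                else:
                    v = forge.make(gene_entry.gene_symbol, "chrX", consequence,
                                   {pro: "1", fat: "0", mot: "0/0"}, pop_af=None)
                    pattern = "de_novo"
                variants.append(v)
                planted_keys = (v.key,)
            for t in _case_terms(rng, gene_entry):
                phenos.append((t, "initial"))
        elif planted_step == 2:
            category = _pick_category(rng, config.category_weights, allowed=pools["step2"])
            entries = pools["step2"][category]
            gene_entry = entries[int(rng.integers(len(entries)))]
            contig = _contig(gene_entry)
            from_father = rng.random() < 0.5
            carrier, carrier_name = (fat, "father") if from_father else (mot, "mother")
            if rng.random() < 9 / 28:
                # family co-segregation: affected carrier parent + grandparent
                flavor = "cosegregation"
                affected_parents.add(carrier_name)
                gid = f"{cid}G1"
                relatives.append((gid, "grandparent", True))
                samples.append(gid)
                v = forge.make(gene_entry.gene_symbol, contig, "missense",
                               {pro: "0/1", carrier: "0/1", gid: "0/1"},
                               pop_af=None, deleterious=True)
                family_history = FamilyHistory(True, True, frozenset({carrier, gid}))
                for t in _case_terms(rng, gene_entry):
                    phenos.append((t, "initial"))
            else:
                # literature-supported variant, atypical (superclass) phenotype
                flavor = "literature"
                v = forge.make(gene_entry.gene_symbol, contig, "missense",
                               {pro: "0/1", carrier: "0/1"},
                               pop_af=None, deleterious=True, literature=True)
                for t in _superclass_terms(rng, ontology, gene_entry):
                    phenos.append((t, "initial"))
            variants.append(v)
            pattern = "inherited_paternal" if from_father else "inherited_maternal"
            planted_keys = (v.key,)
        else:  # step 3
            u = rng.random()
            if u < 0.5 and if_pool:
                # incidental finding upgraded by a late phenotype
                flavor = "late_phenotype"
                late = True
                gene_entry = if_pool[int(rng.integers(len(if_pool)))]
                category = _pick_category(rng, config.category_weights)
                v = forge.make(gene_entry.gene_symbol, _contig(gene_entry),
                               _NULL_CHOICES[int(rng.integers(3))],
                               {pro: "0/1"}, pop_af=None)
                variants.append(v)
                pattern, planted_keys = "de_novo", (v.key,)
                phenos.append((_category_noise_term(rng, ontology, category), "initial"))
                for t in _case_terms(rng, gene_entry, n=1):
                    phenos.append((t, "late_prenatal"))
            elif u < 0.8 and new_genes:
                # disease gene established only in the newer KB version
                flavor = "new_gene"
                gene_entry = new_genes[int(rng.integers(len(new_genes)))]
                category = _entry_category(gene_entry, ontology) or "multisystem"
                v = forge.make(gene_entry.gene_symbol, _contig(gene_entry),
                               _NULL_CHOICES[int(rng.integers(3))],
                               {pro: "0/1"}, pop_af=None, deleterious=True)
                variants.append(v)
                pattern, planted_keys = "de_novo", (v.key,)
                requests.add(cid)
                for t in _case_terms(rng, gene_entry):
                    phenos.append((t, "initial"))
            else:
                # second allele found by focused Sanger sequencing
                flavor = "second_allele_sanger"
                category = _pick_category(rng, config.category_weights, allowed=pools["AR"])
                entries = pools["AR"][category]
                gene_entry = entries[int(rng.integers(len(entries)))]
                carrier = fat if rng.random() < 0.5 else mot
                v = forge.make(gene_entry.gene_symbol, _contig(gene_entry),
                               "missense", {pro: "0/1", carrier: "0/1"},
                               pop_af=None, deleterious=True)
                variants.append(v)
                pattern = "inherited_paternal" if carrier == fat else "inherited_maternal"
                planted_keys = (v.key,)
                events = (EvidenceEvent(
                    case_id=cid, kind="second_allele_sanger",
                    gene_symbol=gene_entry.gene_symbol,
                    description="second allele confirmed by focused Sanger analysis",
                    classification_payload=("PM3",),
                ),)
                for t in _case_terms(rng, gene_entry):
                    phenos.append((t, "initial"))

    elif planted_tier == "inconclusive":
        u = rng.random()
        if u < 0.46:  # single het in an AR disease gene, no second allele
            flavor = "ar_single_het"
            category = _pick_category(rng, config.category_weights, allowed=pools["AR"])
            entries = pools["AR"][category]
            gene_entry = entries[int(rng.integers(len(entries)))]
            carrier = fat if rng.random() < 0.5 else mot
            v = forge.make(gene_entry.gene_symbol, _contig(gene_entry), "missense",
                           {pro: "0/1", carrier: "0/1"}, pop_af=None, deleterious=True)
            pattern = "inherited_paternal" if carrier == fat else "inherited_maternal"
        else:  # inherited AD missense from an unaffected parent
            flavor = "ad_inherited_vus"
            category = _pick_category(rng, config.category_weights, allowed=pools["step2"])
            entries = pools["step2"][category]
            gene_entry = entries[int(rng.integers(len(entries)))]
            carrier = fat if rng.random() < 0.5 else mot
            v = forge.make(gene_entry.gene_symbol, _contig(gene_entry), "missense",
                           {pro: "0/1", carrier: "0/1"}, pop_af=None,
                           deleterious=bool(rng.random() < 0.5))
            pattern = "inherited_paternal" if carrier == fat else "inherited_maternal"
        variants.append(v)
        planted_keys = (v.key,)
        for t in _case_terms(rng, gene_entry):
            phenos.append((t, "initial"))

    elif planted_tier in ("incidental_finding", "secondary_finding"):
        pool = if_pool if planted_tier == "incidental_finding" else sf_pool
        gene_entry = pool[int(rng.integers(len(pool)))]
        category = _pick_category(rng, config.category_weights)
        v = forge.make(gene_entry.gene_symbol, _contig(gene_entry),
                       _NULL_CHOICES[int(rng.integers(3))],
                       {pro: "0/1"}, pop_af=None)
        variants.append(v)
        pattern, planted_keys = "de_novo", (v.key,)
        phenos.append((_category_noise_term(rng, ontology, category), "initial"))

    elif planted_tier == "candidate_gene":
        gene_entry = cand_pool[int(rng.integers(len(cand_pool)))]
        category = _pick_category(rng, config.category_weights)
        v = forge.make(gene_entry.gene_symbol, gene_entry.gene_symbol,
                       "missense", {pro: "0/1"}, pop_af=None, deleterious=True)
        variants.append(v)
        pattern, planted_keys = "de_novo", (v.key,)
        phenos.append((_category_noise_term(rng, ontology, category), "initial"))

    else:  # negative
        category = _pick_category(rng, config.category_weights)
        phenos.append((_category_noise_term(rng, ontology, category), "initial"))

    # multisystem cases carry terms from a second organ system
    if category == "multisystem":
        extra = _category_noise_term(rng, ontology, "abdominal")
        first_heads = {t for t, _ in phenos}
        if extra not in first_heads:
            phenos.append((extra, "initial"))

    # late noise phenotypes on non-reanalysis cases
    if not late and planted_tier != "positive" and rng.random() < config.late_phenotype_prob:
        late = True
        phenos.append((_category_noise_term(rng, ontology, category), "late_prenatal"))

    # family history on the remaining cases
    if not family_history.has_history and rng.random() < config.family_history_prob:
        family_history = FamilyHistory(
            True, bool(rng.random() < config.significant_history_frac), frozenset()
        )

    # nuchal translucency
    nt_mm = None
    if category == "increased_NT":
        nt_mm = float(np.round(rng.uniform(3.5, 6.5), 1))
    elif rng.random() < config.nt_measured_prob:
        nt_mm = float(np.round(
            rng.uniform(3.0, 3.4) if rng.random() < 0.9 else rng.uniform(3.5, 5.5), 1
        ))

    finish_background(forge)

    ped = Pedigree(
        proband_id=pro, father_id=fat, mother_id=mot, proband_sex=sex,
        extra_relatives=tuple(relatives),
        affected_parents=frozenset(affected_parents),
    )
    case = FetalCase(
        case_id=cid, pedigree=ped, phenotypes=tuple(phenos),
        malformation_category=category, nt_mm=nt_mm,
        family_history=family_history, cohort_arm=arm,
    )
    truth = TruthRecord(
        case_id=cid, planted_tier=planted_tier, planted_variants=planted_keys,
        planted_pattern=pattern, planted_step=planted_step,
        planted_gene=gene_entry.gene_symbol if gene_entry else None,
        late_phenotype=late, flavor=flavor,
    )
    return case, variants, events, frozenset(requests), truth


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort with its planted truth table."""
    ontology = packaged_ontology()
    kb_v1 = packaged_kb("v1", ontology)
    kb_v2 = packaged_kb("v2", ontology)
    pools, if_pool, sf_pool, cand_pool, new_genes = _build_pools(kb_v1, kb_v2)
    cases, vbc, ebc, truth = [], {}, {}, []
    requests = set()
    for i in range(config.n_cases):
        case, variants, events, req, rec = simulate_case(
            i, config, pools, if_pool, sf_pool, cand_pool, new_genes, ontology
        )
        cases.append(case)
        vbc[case.case_id] = variants
        if events:
            ebc[case.case_id] = events
        requests |= req
        truth.append(rec)
    return SyntheticCohort(
        config=config, cases=tuple(cases), variants_by_case=vbc,
        events_by_case=ebc, reanalysis_requests=frozenset(requests),
        truth=tuple(truth), kb_v1=kb_v1, kb_v2=kb_v2,
    )


# ------------------------------------------------------------------ file I/O

def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write the cohort as per-case VCF+PED, a metadata JSON, and truth TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = []
    for case in cohort.cases:
        ped = case.pedigree
        samples = list(ped.trio_ids) + [sid for sid, _, _ in ped.extra_relatives]
        write_trio_vcf(out / f"{case.case_id}.vcf",
                       cohort.variants_by_case[case.case_id], samples)
        write_ped(out / f"{case.case_id}.ped", ped, family_id=case.case_id)
        meta.append({
            "case_id": case.case_id,
            "phenotypes": [list(p) for p in case.phenotypes],
            "malformation_category": case.malformation_category,
            "nt_mm": case.nt_mm,
            "family_history": {
                "has_history": case.family_history.has_history,
                "significant": case.family_history.significant,
            },
            "cohort_arm": case.cohort_arm,
            "reanalysis_requested": case.case_id in cohort.reanalysis_requests,
            "events": [
                {"kind": e.kind, "gene": e.gene_symbol,
                 "codes": list(e.classification_payload)}
                for e in cohort.events_by_case.get(case.case_id, ())
            ],
        })
    (out / "cases.json").write_text(json.dumps(meta, indent=1) + "\n")
    with open(out / "truth.tsv", "w") as fh:
        fh.write("case_id\tplanted_tier\tplanted_variants\tplanted_pattern\t"
                 "planted_step\tplanted_gene\tlate_phenotype\tflavor\n")
        for r in cohort.truth:
            fh.write("\t".join([
                r.case_id, r.planted_tier, ",".join(r.planted_variants),
                r.planted_pattern or "", str(r.planted_step or ""),
                r.planted_gene or "", str(int(r.late_phenotype)), r.flavor,
            ]) + "\n")


def write_fixture_tables(out_dir) -> dict:
    """Copy the packaged printed-count and classification-replay fixtures
    into *out_dir*; returns the written paths."""
    from importlib import resources

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    for name in ("acmg_code_replay.tsv", "cohort_counts.json"):
        text = resources.files("pestriage.data").joinpath(name).read_text()
        (out / name).write_text(text)
        written[name] = out / name
    return written
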