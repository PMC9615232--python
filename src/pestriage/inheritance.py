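"""Allele origin and zygosity deduction from trio genotypes.

This is the engine behind the genotype-driven screening step: de novo,
homozygous-recessive, compound-heterozygous (with gene-level phasing by
parental origin) and hemizygous patterns are deduced without phenotype
input.  Apparent de novo calls at a non-trivial population frequency are
demoted to unresolved as likely genotyping artifacts; male chrX
heterozygous calls are treated as genotype errors.
"""

from __future__ import annotations

from dataclasses import dataclass

from .trio_io import Pedigree, VariantObservation

#: population AF above which an apparent de novo call is distrusted
DENOVO_AF_DEMOTE = 1e-3

PATTERNS = frozenset({
    "de_novo", "homozygous_recessive", "compound_heterozygous", "hemizygous",
    "inherited_paternal", "inherited_maternal", "inherited_biparental",
    "unresolved",
})
CAPTURE_PATTERNS = frozenset({
    "de_novo", "homozygous_recessive", "compound_heterozygous", "hemizygous",
})


@dataclass(frozen=True)
class InheritancePattern:
    pattern: str
    origin_detail: tuple = ()  # comp-het: ((variant key, parental origin), ...)
    mendelian_error: bool = False

    def __post_init__(self):
        if self.pattern not in PATTERNS:
            raise ValueError(f"bad inheritance pattern {self.pattern!r}")

    @property
    def captured(self) -> bool:
        """True when the pattern alone marks the variant as potentially causal."""
        return self.pattern in CAPTURE_PATTERNS


@dataclass(frozen=True)
class FamilyHistory:
    has_history: bool = False
    significant: bool = False  # prior affected relative with similar phenotype
    affected_carriers: frozenset = frozenset()

    def __post_init__(self):
        if self.significant and not self.has_history:
            raise ValueError("significant family history implies has_history")


def _carries(gt: str) -> bool:
    return gt in ("0/1", "1/1", "1")


def deduce_single(
    variant: VariantObservation,
    ped: Pedigree,
    denovo_af_demote: float = DENOVO_AF_DEMOTE,
) -> InheritancePattern:
    """Deduce the inheritance pattern of one variant from its trio genotypes.

    Degenerate inputs (missing genotypes, male X heterozygotes, Mendelian
    inconsistencies) map to ``unresolved`` rather than raising.
    """
    pro = variant.genotype(ped.proband_id)
    fat = variant.genotype(ped.father_id)
    mot = variant.genotype(ped.mother_id)
    if "missing" in (pro, fat, mot):
        return InheritancePattern("unresolved")

    male_x = variant.on_chrx and ped.proband_sex == "male"
    if male_x:
        if pro in ("0/1", "1/1"):  # male X het call = genotype error
            return InheritancePattern("unresolved")
        if pro != "1":
            return InheritancePattern("unresolved")
        if _carries(mot):
            return InheritancePattern("hemizygous", origin_detail=((variant.key, "maternal"),))
        # absent in the carrier parent: de novo on the X
        if variant.pop_af is not None and variant.pop_af > denovo_af_demote:
            return InheritancePattern("unresolved")
        return InheritancePattern("de_novo", origin_detail=((variant.key, "de_novo"),))

    if pro == "1/1":
        fat_c, mot_c = _carries(fat), _carries(mot)
        if fat_c and mot_c:
            return InheritancePattern("homozygous_recessive",
                                      origin_detail=((variant.key, "biparental"),))
        # homozygote impossible given parental genotypes
        return InheritancePattern("unresolved", mendelian_error=True)

    if pro == "0/1":
        fat_c, mot_c = _carries(fat), _carries(mot)
        if fat_c and mot_c:
            return InheritancePattern("inherited_biparental")
        if fat_c:
            return InheritancePattern("inherited_paternal",
                                      origin_detail=((variant.key, "paternal"),))
        if mot_c:
            return InheritancePattern("inherited_maternal",
                                      origin_detail=((variant.key, "maternal"),))
        if variant.pop_af is not None and variant.pop_af > denovo_af_demote:
            return InheritancePattern("unresolved")  # likely artifact
        return InheritancePattern("de_novo", origin_detail=((variant.key, "de_novo"),))

    return InheritancePattern("unresolved")


_ORIGIN_OF = {
    "inherited_paternal": "paternal",
    "inherited_maternal": "maternal",
    "de_novo": "de_novo",
}


def phase_compound_het(variants_in_gene, ped: Pedigree,
                       denovo_af_demote: float = DENOVO_AF_DEMOTE) -> list:
    """Flag in-trans pairs among heterozygous proband variants of one gene.

    A pair is in trans when the two variants have distinct parental origins,
    or when one is inherited and the other apparent de novo.  Pairs on the
    same parental haplotype (cis) are not flagged; pairs involving an
    ambiguous-origin variant come back unresolved.  Output pairs are
    unordered (symmetric in input order).
    """
    hets = [
        v for v in variants_in_gene
        if v.genotype(ped.proband_id) == "0/1"
    ]
    singles = {v.key: deduce_single(v, ped, denovo_af_demote) for v in hets}
    out = []
    for i in range(len(hets)):
        for j in range(i + 1, len(hets)):
            a, b = hets[i], hets[j]
            pa, pb = singles[a.key], singles[b.key]
            oa = _ORIGIN_OF.get(pa.pattern)
            ob = _ORIGIN_OF.get(pb.pattern)
            if oa is None or ob is None:
                out.append(InheritancePattern(
                    "unresolved",
                    origin_detail=tuple(sorted([(a.key, "unknown"), (b.key, "unknown")])),
                ))
            elif oa != ob:
                out.append(InheritancePattern(
                    "compound_heterozygous",
                    origin_detail=tuple(sorted([(a.key, oa), (b.key, ob)])),
                ))
            # same-parent pair: cis by origin, not flagged
    return out


_FIRST_SECOND_DEGREE = frozenset({"sibling", "uncle", "aunt", "grandparent"})


def segregation_check(
    variant: VariantObservation,
    ped: Pedigree,
    relative_genotypes: dict | None = None,
    has_history: bool = False,
    phenotype_similar: bool = False,
) -> FamilyHistory:
    """Co-segregation of a variant with affected status in the family.

    ``significant`` requires an affected 1st/2nd-degree relative (including
    a parent) carrying the allele plus the case-level similar-phenotype
    flag.  An unaffected carrier parent argues against dominant causality
    and is surfaced via ``affected_carriers`` being empty despite carriage.
    """
    relative_genotypes = relative_genotypes or {}
    carriers = set()
    for parent, sample_id in (("father", ped.father_id), ("mother", ped.mother_id)):
        if parent in ped.affected_parents and _carries(variant.genotype(sample_id)):
            carriers.add(sample_id)
    for sid, relation, affected in ped.extra_relatives:
        if relation not in _FIRST_SECOND_DEGREE or not affected:
            continue
        gt = relative_genotypes.get(sid, variant.genotype(sid))
        if _carries(gt):
            carriers.add(sid)
    any_history = has_history or bool(ped.affected_parents) or any(
        aff for _, _, aff in ped.extra_relatives
    )
    return FamilyHistory(
        has_history=any_history,
        significant=bool(carriers) and phenotype_similar and any_history,
        affected_carriers=frozenset(carriers),
    )
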