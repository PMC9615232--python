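import pytest

from pestriage import FamilyHistory, Pedigree, VariantObservation
from pestriage.knowledge_base import packaged_kb, packaged_ontology


@pytest.fixture(scope="session")
def ontology():
    return packaged_ontology()


@pytest.fixture(scope="session")
def kb(ontology):
    return packaged_kb("v1", ontology)


@pytest.fixture(scope="session")
def kb_v2(ontology):
    return packaged_kb("v2", ontology)


@pytest.fixture
def trio_ped():
    return Pedigree(
        proband_id="P1", father_id="F1", mother_id="M1", proband_sex="male"
    )


def make_variant(
    chrom="NFIA", pos=1000, ref="A", alt="T", gene="NFIA",
    consequence="missense", pro="0/1", fat="0/0", mot="0/0",
    ped=None, pop_af=None, **kw,
):
    ids = ped.trio_ids if ped is not None else ("P1", "F1", "M1")
    return VariantObservation(
        chrom=chrom, pos=pos, ref=ref, alt=alt, gene_symbol=gene,
        consequence=consequence, pop_af=pop_af,
        genotypes={ids[0]: pro, ids[1]: fat, ids[2]: mot},
        **kw,
    )


@pytest.fixture
def variant_factory():
    return make_variant


@pytest.fixture
def significant_history():
    return FamilyHistory(has_history=True, significant=True)
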