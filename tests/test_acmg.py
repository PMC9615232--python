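"""Evidence-token parsing, combining rules, and rule-based auto-assignment."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pestriage.acmg import (
    EvidenceCode, EvidenceParseError, auto_assign, combine, label_rank,
    parse_code, parse_code_set,
)
from pestriage.inheritance import FamilyHistory, InheritancePattern

from conftest import make_variant


@pytest.mark.parametrize("token,base,strength", [
    ("PS2_PM", "PS2", "moderate"),
    ("PVS1", "PVS1", "very_strong"),
    ("PP1_PS", "PP1", "strong"),
    ("PM2_PP", "PM2", "supporting"),
    ("PS2_PVS", "PS2", "very_strong"),
    ("BA1", "BA1", "stand_alone"),
    ("BS1", "BS1", "strong"),
    ("BP4", "BP4", "supporting"),
])
def test_parse_code(token, base, strength):
    code = parse_code(token)
    assert (code.base, code.strength) == (base, strength)


@pytest.mark.parametrize("token", ["PS9", "XX1", "PS2_XX", "PVS1_", "", "PM2 PP3"])
def test_malformed_token_raises(token):
    with pytest.raises(EvidenceParseError):
        parse_code(token)


def test_benign_base_rejects_moderate_strength():
    with pytest.raises(EvidenceParseError):
        parse_code("BS1_PM")


def test_pathogenic_base_rejects_stand_alone():
    with pytest.raises(EvidenceParseError):
        parse_code("PS2_SA")


def test_token_round_trip():
    for tok in ("PS2_PM", "PVS1", "PP1_PS", "BA1", "PM1_PP"):
        assert parse_code(tok).token == tok


@pytest.mark.parametrize("codes,label", [
    ("PVS1, PS2, PM2", "P"),
    ("PS2, PM1, PM2, PP3", "LP"),
    ("PVS1, PM2", "LP"),           # SVI very-strong + moderate provision
    ("PVS1_PS, PS2", "P"),         # two strongs
    ("PM1, PM2, PP3, PP4", "LP"),  # 2 moderate + 2 supporting
    ("PS2, PM2, PP3, PP2", "LP"),
    ("BA1", "B"),
    ("BS1, BS2", "B"),
    ("BS1, BP1", "LB"),
    ("BP1, BP2", "LB"),
    ("PM2", "VUS"),
    ("", "VUS"),
])
def test_combine_worked_examples(codes, label):
    assert combine(parse_code_set(codes)).label == label


def test_conflicting_evidence_is_vus():
    codes = parse_code_set("PVS1, PS2, BS1, BS2")
    got = combine(codes)
    assert got.label == "VUS" and got.rule_fired == "conflict"


# ---------------------------------------------------------------- oracle

def _oracle_label(vs, s, m, p, sa, bs, bp):
    """Independent brute-force statement of the combining rule list."""
    pathogenic = None
    if vs >= 2:
        pathogenic = "P"
    elif vs == 1 and (s >= 1 or m >= 2 or (m == 1 and p >= 1) or p >= 2):
        pathogenic = "P"
    elif s >= 2:
        pathogenic = "P"
    elif s == 1 and (m >= 3 or (m == 2 and p >= 2) or (m == 1 and p >= 4)):
        pathogenic = "P"
    elif vs == 1 and m == 1:
        pathogenic = "LP"
    elif s == 1 and 1 <= m <= 2:
        pathogenic = "LP"
    elif s == 1 and p >= 2:
        pathogenic = "LP"
    elif m >= 3:
        pathogenic = "LP"
    elif m == 2 and p >= 2:
        pathogenic = "LP"
    elif m == 1 and p >= 4:
        pathogenic = "LP"
    benign = None
    if sa >= 1 or bs >= 2:
        benign = "B"
    elif (bs == 1 and bp >= 1) or bp >= 2:
        benign = "LB"
    if pathogenic and benign:
        return "VUS"
    return pathogenic or benign or "VUS"


_PATH_CODES = {
    "very_strong": ["PVS1", "PS1_PVS", "PS2_PVS", "PS3_PVS", "PS4_PVS"],
    "strong": ["PS1", "PS2", "PS3", "PS4", "PP1_PS"],
    "moderate": ["PM1", "PM2", "PM3", "PM4", "PM5"],
    "supporting": ["PP1", "PP2", "PP3", "PP4", "PP5"],
}
_BENIGN_CODES = {
    "stand_alone": ["BA1", "BS1_SA", "BS2_SA", "BS3_SA", "BS4_SA"],
    "strong": ["BS1", "BS2", "BS3", "BS4", "BP1_PS"],
    "supporting": ["BP1", "BP2", "BP3", "BP4", "BP5"],
}


def _codes_for(vs, s, m, p, sa, bs, bp):
    toks = (
        _PATH_CODES["very_strong"][:vs] + _PATH_CODES["strong"][:s]
        + _PATH_CODES["moderate"][:m] + _PATH_CODES["supporting"][:p]
        + _BENIGN_CODES["stand_alone"][:sa] + _BENIGN_CODES["strong"][:bs]
        + _BENIGN_CODES["supporting"][:bp]
    )
    return tuple(parse_code(t) for t in toks)


def _all_multisets(max_total=5):
    for counts in itertools.product(range(max_total + 1), repeat=7):
        vs, s, m, p, sa, bs, bp = counts
        if vs + s + m + p <= max_total and sa + bs + bp <= max_total:
            yield counts


def test_combine_matches_enumeration_oracle():
    """Exhaustive agreement with the independent enumerator over all
    effective-strength multisets of size <= 5 per side."""
    n = 0
    for counts in _all_multisets(5):
        expected = _oracle_label(*counts)
        got = combine(_codes_for(*counts)).label
        assert got == expected, (counts, got, expected)
        n += 1
    assert n > 1000


def test_monotonicity_of_added_evidence():
    """Adding pathogenic evidence never lowers the label and adding benign
    evidence never raises it, with the conflict state treated as VUS."""
    extra_path = parse_code("PP5")
    extra_benign = parse_code("BP5")
    for counts in _all_multisets(4):
        vs, s, m, p, sa, bs, bp = counts
        base = combine(_codes_for(*counts)).label
        more_path = combine(_codes_for(vs, s, m, p + 1, sa, bs, bp)).label
        more_benign = combine(_codes_for(vs, s, m, p, sa, bs, bp + 1)).label
        base_conflicted = base == "VUS"
        if more_path != "VUS":  # conflict exception applies symmetrically
            assert label_rank(more_path) <= label_rank(base) or base_conflicted
        if more_benign != "VUS":
            assert label_rank(more_benign) >= label_rank(base) or base_conflicted


_ALL_TOKENS = sum(_PATH_CODES.values(), []) + sum(_BENIGN_CODES.values(), [])


@settings(max_examples=200, deadline=None)
@given(st.lists(st.sampled_from(_ALL_TOKENS), max_size=8))
def test_combine_is_order_invariant_and_tokens_round_trip(tokens):
    codes = tuple(parse_code(t) for t in tokens)
    assert combine(codes).label == combine(tuple(reversed(codes))).label
    for c in codes:
        assert parse_code(c.token) == parse_code(c.token.strip())
        again = parse_code(c.token)
        assert (again.base, again.strength) == (c.base, c.strength)


# ------------------------------------------------------------- auto_assign

def test_auto_de_novo_nonsense_in_lof_gene_reaches_p(kb, trio_ped):
    entry = kb.entries_for_gene("NFIA")[0]
    v = make_variant(consequence="nonsense", pro="0/1", fat="0/0", mot="0/0")
    pattern = InheritancePattern("de_novo")
    codes = auto_assign(v, pattern, entry)
    bases = {c.base for c in codes}
    assert {"PVS1", "PS2", "PM2"} <= bases
    assert combine(codes).label == "P"


def test_auto_inherited_missense_with_segregation(kb, trio_ped):
    entry = kb.entries_for_gene("CRYAA")[0]
    v = make_variant(gene="CRYAA", consequence="missense", pro="0/1",
                     fat="0/1", mot="0/0", deleterious_predicted=True)
    pattern = InheritancePattern("inherited_paternal")
    history = FamilyHistory(True, True, frozenset({"F1"}))
    codes = auto_assign(v, pattern, entry, history)
    bases = {c.base for c in codes}
    assert {"PM2", "PP1", "PP3"} <= bases and "PS2" not in bases


def test_auto_common_synonymous_triggers_nothing(kb, trio_ped):
    v = make_variant(consequence="synonymous", pro="0/1", fat="0/1",
                     mot="0/0", pop_af=0.2)
    codes = auto_assign(v, InheritancePattern("inherited_paternal"),
                        kb.entries_for_gene("NFIA")[0])
    assert codes == ()


def test_expert_codes_override_auto_on_same_base(kb):
    v = make_variant(consequence="nonsense", pro="0/1", fat="0/0", mot="0/0")
    expert = (EvidenceCode("PM2", "supporting", source="expert"),)
    codes = auto_assign(v, InheritancePattern("de_novo"),
                        kb.entries_for_gene("NFIA")[0], expert_codes=expert)
    pm2 = [c for c in codes if c.base == "PM2"]
    assert len(pm2) == 1 and pm2[0].strength == "supporting" and pm2[0].source == "expert"
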