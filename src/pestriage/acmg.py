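"""Strength-modified ACMG evidence codes and five-level combining.

Evidence tokens use the ``BASE`` or ``BASE_STRENGTH`` grammar seen in
clinical reports (e.g. ``PS2_PM`` = criterion PS2 applied at Moderate
strength, ``PP1_PS`` = PP1 upgraded to Strong).  Combining follows the
standard pathogenic/benign combining rules over *effective* (applied)
strengths, extended with the ClinGen SVI provision that one Very Strong
plus one Moderate reaches Likely Pathogenic.  Satisfying both a pathogenic
and a benign rule is treated as conflicting evidence and yields VUS.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
import re

PATHOGENIC_BASES = frozenset(
    {"PVS1"} | {f"PS{i}" for i in range(1, 5)} | {f"PM{i}" for i in range(1, 7)}
    | {f"PP{i}" for i in range(1, 6)}
)
BENIGN_BASES = frozenset(
    {"BA1"} | {f"BS{i}" for i in range(1, 5)} | {f"BP{i}" for i in range(1, 8)}
)

NATIVE_STRENGTH = {
    "PVS": "very_strong", "PS": "strong", "PM": "moderate", "PP": "supporting",
    "BA": "stand_alone", "BS": "strong", "BP": "supporting",
}
SUFFIX_STRENGTH = {
    "PVS": "very_strong", "PS": "strong", "PM": "moderate", "PP": "supporting",
    "SA": "stand_alone",
}
PATHOGENIC_STRENGTHS = frozenset({"very_strong", "strong", "moderate", "supporting"})
BENIGN_STRENGTHS = frozenset({"stand_alone", "strong", "supporting"})

LABELS = ("P", "LP", "VUS", "LB", "B")  # total order, most to least pathogenic
_LABEL_RANK = {lab: i for i, lab in enumerate(LABELS)}

_TOKEN_RE = re.compile(r"^([A-Z]+\d+)(?:_(PVS|PS|PM|PP|SA))?$")


class EvidenceParseError(ValueError):
    """Malformed ACMG evidence token."""


@dataclass(frozen=True)
class EvidenceCode:
    base: str
    strength: str
    source: str = "auto"  # auto | expert | event

    def __post_init__(self):
        if self.base in PATHOGENIC_BASES:
            if self.strength not in PATHOGENIC_STRENGTHS:
                raise EvidenceParseError(
                    f"{self.base}: pathogenic codes take pathogenic-side strengths, "
                    f"not {self.strength!r}"
                )
        elif self.base in BENIGN_BASES:
            if self.strength not in BENIGN_STRENGTHS:
                raise EvidenceParseError(
                    f"{self.base}: benign codes take stand_alone/strong/supporting, "
                    f"not {self.strength!r}"
                )
        else:
            raise EvidenceParseError(f"unknown ACMG base code {self.base!r}")
        if self.source not in ("auto", "expert", "event"):
            raise EvidenceParseError(f"bad evidence source {self.source!r}")

    @property
    def pathogenic_side(self) -> bool:
        return self.base in PATHOGENIC_BASES

    @property
    def token(self) -> str:
        native = NATIVE_STRENGTH[re.match(r"[A-Z]+", self.base).group(0)]
        if self.strength == native:
            return self.base
        suffix = {v: k for k, v in SUFFIX_STRENGTH.items()}[self.strength]
        return f"{self.base}_{suffix}"


def parse_code(token: str, source: str = "expert") -> EvidenceCode:
    """Parse one ``BASE`` / ``BASE_SUFFIX`` token; bare tokens get the base
    code's native strength."""
    token = token.strip()
    m = _TOKEN_RE.match(token)
    if not m:
        raise EvidenceParseError(f"malformed ACMG evidence token {token!r}")
    base, suffix = m.groups()
    if base not in PATHOGENIC_BASES | BENIGN_BASES:
        raise EvidenceParseError(f"malformed ACMG evidence token {token!r}")
    if suffix is None:
        strength = NATIVE_STRENGTH[re.match(r"[A-Z]+", base).group(0)]
    else:
        strength = SUFFIX_STRENGTH[suffix]
    return EvidenceCode(base=base, strength=strength, source=source)


def parse_code_set(text: str, source: str = "expert") -> tuple:
    """Parse a comma-separated code list like ``"PVS1_PS, PS2, PM2"``."""
    return tuple(parse_code(tok, source) for tok in text.split(",") if tok.strip())


@dataclass(frozen=True)
class Classification:
    label: str
    rule_fired: str
    evidence_summary: tuple = ()  # sorted ((side, strength), count) pairs

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"bad classification label {self.label!r}")

    @property
    def is_plp(self) -> bool:
        return self.label in ("P", "LP")


def label_rank(label: str) -> int:
    """Position in the P > LP > VUS > LB > B total order (0 = P)."""
    return _LABEL_RANK[label]


def _strength_counts(codes):
    path = Counter()
    benign = Counter()
    for c in codes:
        (path if c.pathogenic_side else benign)[c.strength] += 1
    return path, benign


def _pathogenic_rule(vs: int, s: int, m: int, p: int) -> str | None:
    """Strongest pathogenic rule satisfied by effective-strength counts.

    Counts are read as at-least thresholds, which keeps the outcome
    monotone under added evidence.
    """
    if vs >= 2:
        return "P:2VS"
    if vs >= 1 and (s >= 1 or m >= 2 or (m >= 1 and p >= 1) or p >= 2):
        return "P:VS+"
    if s >= 2:
        return "P:2S"
    if s >= 1 and (m >= 3 or (m >= 2 and p >= 2) or (m >= 1 and p >= 4)):
        return "P:S+"
    if vs >= 1 and m >= 1:
        return "LP:VS+M"  # SVI provision
    if s >= 1 and m >= 1:
        return "LP:S+M"
    if s >= 1 and p >= 2:
        return "LP:S+2P"
    if m >= 3:
        return "LP:3M"
    if m >= 2 and p >= 2:
        return "LP:2M+2P"
    if m >= 1 and p >= 4:
        return "LP:M+4P"
    return None


def _benign_rule(sa: int, s: int, p: int) -> str | None:
    if sa >= 1:
        return "B:BA1"
    if s >= 2:
        return "B:2BS"
    if s >= 1 and p >= 1:
        return "LB:BS+BP"
    if p >= 2:
        return "LB:2BP"
    return None


def combine(codes) -> Classification:
    """Combine evidence codes into one of P/LP/VUS/LB/B.

    Counting is over applied strengths, not base-code categories, so a
    ``PS2_PM`` contributes one Moderate.  Conflicting pathogenic and benign
    rule satisfaction yields VUS.
    """
    codes = tuple(codes)
    path, benign = _strength_counts(codes)
    path_rule = _pathogenic_rule(
        path["very_strong"], path["strong"], path["moderate"], path["supporting"]
    )
    benign_rule = _benign_rule(
        benign["stand_alone"], benign["strong"], benign["supporting"]
    )
    summary = tuple(sorted(
        [(("pathogenic", k), v) for k, v in path.items() if v]
        + [(("benign", k), v) for k, v in benign.items() if v]
    ))
    if path_rule and benign_rule:
        return Classification("VUS", "conflict", summary)
    if path_rule:
        return Classification(path_rule.split(":")[0], path_rule, summary)
    if benign_rule:
        return Classification(benign_rule.split(":")[0], benign_rule, summary)
    return Classification("VUS", "", summary)


# ------------------------------------------------------------------ auto rules

#: PM2 population-frequency ceiling ("extremely rare"); absent counts as met
PM2_AF_MAX = 1e-4


def _pp1_strength(n_carriers: int) -> str:
    # co-segregation weight grows with the number of affected carriers
    if n_carriers >= 4:
        return "strong"
    if n_carriers >= 2:
        return "moderate"
    return "supporting"


def auto_assign(
    variant,
    pattern,
    entry=None,
    history=None,
    in_trans_with_plp: bool = False,
    expert_codes=(),
    pm2_af_max: float = PM2_AF_MAX,
) -> tuple:
    """Rule-based evidence assignment for one variant.

    PVS1 on null changes in loss-of-function-mechanism genes; PS2 on a
    trio-confirmed de novo; PM2 when absent from or extremely rare in
    population data; PM3 for an in-trans partner of a P/LP allele; PS4 when
    the identical variant is reported in previous affected cases; PP3 on an
    in-silico deleterious prediction; PP1 (strength scaled by affected
    carrier count) on significant co-segregation.  Expert- or
    event-supplied codes override auto codes on the same base.
    """
    auto = []
    lof_gene = entry is not None and entry.lof_mechanism
    if variant.is_null and lof_gene:
        auto.append(EvidenceCode("PVS1", "very_strong"))
    is_de_novo = False
    if pattern is not None:
        if pattern.pattern == "de_novo":
            is_de_novo = True
        elif pattern.pattern == "compound_heterozygous":
            is_de_novo = dict(pattern.origin_detail).get(variant.key) == "de_novo"
    if is_de_novo:
        auto.append(EvidenceCode("PS2", "strong"))
    if variant.pop_af is None or variant.pop_af < pm2_af_max:
        auto.append(EvidenceCode("PM2", "moderate"))
    if in_trans_with_plp:
        auto.append(EvidenceCode("PM3", "moderate"))
    if variant.literature_reported:
        auto.append(EvidenceCode("PS4", "strong"))
    if variant.deleterious_predicted and not variant.is_null:
        auto.append(EvidenceCode("PP3", "supporting"))
    if history is not None and history.significant and history.affected_carriers:
        auto.append(EvidenceCode("PP1", _pp1_strength(len(history.affected_carriers))))
    expert_codes = tuple(expert_codes)
    overridden = {c.base for c in expert_codes}
    return tuple(c for c in auto if c.base not in overridden) + expert_codes
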