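"""Gene–disease–phenotype knowledge consulted by the triage steps.

The knowledge base is a versioned table of gene→disease links (inheritance
modes, HPO annotations, onset class, secondary-findings-list membership)
plus a small HPO ontology supporting is_a ancestor queries.  The packaged
fixtures are synthetic stand-ins for the OMIM/Orphanet gene universe and the
full Human Phenotype Ontology, which are not redistributable here; real HP
identifiers are used only for well-known terms.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import networkx as nx
import obonet

log = logging.getLogger(__name__)

INHERITANCE_MODES = frozenset({"AD", "AR", "XLD", "XLR"})
ONSET_CLASSES = frozenset({"prenatal", "childhood", "adult"})
HPO_ID_RE = re.compile(r"^HP:\d{7}$")

#: malformation category -> head ontology term (organ-system superclass).
#: ``multisystem`` is derived (>=2 distinct systems), not a term.
CATEGORY_HEAD_TERMS = {
    "central_nervous": "HP:0002011",
    "facial": "HP:0000271",
    "chest": "HP:0000765",
    "cardiovascular": "HP:0001626",
    "abdominal": "HP:0001438",
    "urogenital": "HP:0000119",
    "skeletal": "HP:0000924",
    "isolated_hydrops": "HP:0001789",
    "FGR": "HP:0001511",
    "increased_NT": "HP:0010880",
}

MALFORMATION_CATEGORIES = tuple(CATEGORY_HEAD_TERMS) + ("multisystem",)


class KnowledgeBaseError(ValueError):
    """Fatal knowledge-base load/validation failure."""


@dataclass(frozen=True)
class HPOOntology:
    """Minimal is_a ontology: term id -> name and parent set."""

    terms: dict
    root: str

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def name(self, term: str) -> str:
        return self.terms[term]["name"]

    def parents(self, term: str) -> frozenset:
        return self.terms[term]["parents"]


@dataclass(frozen=True)
class GeneDiseaseEntry:
    gene_symbol: str
    disease_name: str
    omim_id: str  # 6-digit or ""
    inheritance_modes: frozenset
    hpo_terms: frozenset
    onset_class: str = "childhood"
    sf_list: bool = False
    gene_status: str = "established"
    lof_mechanism: bool = False
    paralog_or_model_support: bool = False
    literature_hpo: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.gene_symbol:
            raise KnowledgeBaseError("gene_symbol must be non-empty")
        if self.onset_class not in ONSET_CLASSES:
            raise KnowledgeBaseError(f"bad onset_class {self.onset_class!r}")
        if self.gene_status not in ("established", "undefined"):
            raise KnowledgeBaseError(f"bad gene_status {self.gene_status!r}")
        bad = set(self.inheritance_modes) - INHERITANCE_MODES
        if bad:
            raise KnowledgeBaseError(f"unknown inheritance modes {sorted(bad)}")
        # modes are required exactly for established gene-disease links
        if (self.gene_status == "established") != bool(self.inheritance_modes):
            raise KnowledgeBaseError(
                f"{self.gene_symbol}: inheritance_modes must be non-empty "
                f"iff gene_status=established"
            )
        if self.omim_id and not re.fullmatch(r"\d{6}", self.omim_id):
            raise KnowledgeBaseError(f"{self.gene_symbol}: bad omim_id {self.omim_id!r}")

    @property
    def x_linked(self) -> bool:
        return bool(self.inheritance_modes & {"XLD", "XLR"})


@dataclass(frozen=True)
class KnowledgeBaseVersion:
    version_tag: str
    entries: tuple
    ontology: HPOOntology

    def __post_init__(self):
        seen = set()
        for e in self.entries:
            key = (e.gene_symbol, e.omim_id)
            if key in seen:
                raise KnowledgeBaseError(f"duplicate (gene, omim_id) pair {key}")
            seen.add(key)

    def entries_for_gene(self, gene_symbol: str):
        return [e for e in self.entries if e.gene_symbol == gene_symbol]

    def genes(self) -> frozenset:
        return frozenset(e.gene_symbol for e in self.entries)


def load_ontology(path) -> HPOOntology:
    """Read an OBO-format ontology (id / name / is_a stanzas)."""
    graph = obonet.read_obo(str(path))
    terms = {}
    for node, data in graph.nodes(data=True):
        if not HPO_ID_RE.match(node):
            raise KnowledgeBaseError(f"ontology id {node!r} is not HP:NNNNNNN")
        parents = frozenset(
            v for _, v, key in graph.out_edges(node, keys=True) if key == "is_a"
        )
        terms[node] = {"name": data.get("name", node), "parents": parents}
    if not nx.is_directed_acyclic_graph(graph):
        raise KnowledgeBaseError("ontology parent graph contains a cycle")
    roots = [t for t, d in terms.items() if not d["parents"]]
    if len(roots) != 1:
        raise KnowledgeBaseError(f"expected one root term, found {sorted(roots)}")
    root = roots[0]
    onto = HPOOntology(terms=terms, root=root)
    for term in terms:
        if term != root and root not in hpo_ancestors(term, onto):
            raise KnowledgeBaseError(f"term {term} does not reach root {root}")
    return onto


def hpo_ancestors(term: str, ontology: HPOOntology) -> frozenset:
    """All proper is_a ancestors of *term* up to the root (term excluded)."""
    if term not in ontology:
        raise KeyError(f"unknown HPO term {term!r}: phenotype/KB-ontology mismatch")
    out, stack = set(), list(ontology.parents(term))
    while stack:
        t = stack.pop()
        if t not in out:
            out.add(t)
            stack.extend(ontology.parents(t))
    return frozenset(out)


_KB_COLUMNS = [
    "gene", "omim_id", "disease", "inheritance", "hpo_terms", "onset",
    "sf_list", "gene_status", "lof_mechanism", "paralog_support",
    "literature_hpo",
]


def _parse_terms(cell: str) -> frozenset:
    return frozenset(t for t in cell.split("|") if t) if cell else frozenset()


def load_knowledge_base(path, ontology_path, version_tag: str | None = None) -> KnowledgeBaseVersion:
    """Load a KB TSV plus its ontology; entries with unresolvable HPO ids are
    rejected with a warning, structural errors are fatal."""
    ontology = ontology_path if isinstance(ontology_path, HPOOntology) else load_ontology(ontology_path)
    path = Path(path)
    entries = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(_KB_COLUMNS)] != _KB_COLUMNS:
            raise KnowledgeBaseError(f"{path}:1: bad KB header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) != len(_KB_COLUMNS):
                raise KnowledgeBaseError(
                    f"{path}:{lineno}: expected {len(_KB_COLUMNS)} columns, got {len(cells)}"
                )
            row = dict(zip(_KB_COLUMNS, cells))
            try:
                entry = GeneDiseaseEntry(
                    gene_symbol=row["gene"],
                    disease_name=row["disease"],
                    omim_id=row["omim_id"],
                    inheritance_modes=_parse_terms(row["inheritance"]),
                    hpo_terms=_parse_terms(row["hpo_terms"]),
                    onset_class=row["onset"],
                    sf_list=row["sf_list"] == "1",
                    gene_status=row["gene_status"],
                    lof_mechanism=row["lof_mechanism"] == "1",
                    paralog_or_model_support=row["paralog_support"] == "1",
                    literature_hpo=_parse_terms(row["literature_hpo"]),
                )
            except KnowledgeBaseError as exc:
                raise KnowledgeBaseError(f"{path}:{lineno}: {exc}") from exc
            unresolved = [
                t for t in entry.hpo_terms | entry.literature_hpo if t not in ontology
            ]
            if unresolved:
                log.warning(
                    "%s:%d: entry %s rejected, unresolved HPO ids %s",
                    path, lineno, entry.gene_symbol, sorted(unresolved),
                )
                continue
            entries.append(entry)
    return KnowledgeBaseVersion(
        version_tag=version_tag or path.stem,
        entries=tuple(entries),
        ontology=ontology,
    )


def save_knowledge_base(kb: KnowledgeBaseVersion, path) -> None:
    """Serialize a KB back to its TSV form (ontology is not rewritten)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_KB_COLUMNS) + "\n")
        for e in kb.entries:
            fh.write(
                "\t".join([
                    e.gene_symbol,
                    e.omim_id,
                    e.disease_name,
                    "|".join(sorted(e.inheritance_modes)),
                    "|".join(sorted(e.hpo_terms)),
                    e.onset_class,
                    "1" if e.sf_list else "0",
                    e.gene_status,
                    "1" if e.lof_mechanism else "0",
                    "1" if e.paralog_or_model_support else "0",
                    "|".join(sorted(e.literature_hpo)),
                ])
                + "\n"
            )


def genes_for_mode(kb: KnowledgeBaseVersion, mode: str) -> list:
    """Gene symbols of entries carrying *mode*, in stable sorted order."""
    if mode not in INHERITANCE_MODES:
        raise ValueError(f"unknown inheritance mode {mode!r}")
    return sorted({e.gene_symbol for e in kb.entries if mode in e.inheritance_modes})


def _data_path(name: str):
    return resources.files("pestriage.data").joinpath(name)


def packaged_ontology() -> HPOOntology:
    return load_ontology(_data_path("mini_hpo.synthetic.obo"))


def packaged_kb(version: str = "v1", ontology: HPOOntology | None = None) -> KnowledgeBaseVersion:
    """The bundled synthetic knowledge base (versions ``v1`` and ``v2``)."""
    onto = ontology or packaged_ontology()
    return load_knowledge_base(
        _data_path(f"gene_disease_kb_{version}.synthetic.tsv"), onto, version_tag=version
    )


def packaged_sf_genes() -> frozenset:
    """Gene symbols on the packaged secondary-findings list (SF v2.0 stand-in)."""
    text = _data_path("sf_genes.synthetic.txt").read_text()
    return frozenset(
        line.strip() for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )
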