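"""Trio genotype and pedigree input.

Reads family structure from 6-column PED files and per-variant trio
genotypes from multi-sample VCF 4.2 (via cyvcf2), decomposing multi-allelic
sites into one record per alternate allele.  Functional annotations (gene,
consequence, population allele frequency, in-silico flags) are expected
pre-computed, either as INFO fields or in a sidecar TSV keyed by
chrom:pos:ref:alt — this package does not predict consequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from cyvcf2 import VCF

log = logging.getLogger(__name__)

CONSEQUENCES = frozenset({
    "missense", "nonsense", "frameshift", "splice_donor_acceptor",
    "splice_region", "inframe", "synonymous", "other",
})
NULL_CONSEQUENCES = frozenset({"nonsense", "frameshift", "splice_donor_acceptor"})
GENOTYPES = frozenset({"0/0", "0/1", "1/1", "0", "1", "missing"})


class TrioInputError(ValueError):
    """Fatal trio input problem (incomplete trio, missing sample column)."""


@dataclass(frozen=True)
class Pedigree:
    proband_id: str
    father_id: str
    mother_id: str
    proband_sex: str  # male | female
    proband_affected: bool = True
    extra_relatives: tuple = ()  # (sample_id, relation, affected)
    affected_parents: frozenset = frozenset()  # subset of {"father", "mother"}

    def __post_init__(self):
        if self.proband_id in (self.father_id, self.mother_id):
            raise TrioInputError("proband id collides with a parent id")
        if self.proband_sex not in ("male", "female"):
            raise TrioInputError(f"bad proband sex {self.proband_sex!r}")
        for _, relation, _ in self.extra_relatives:
            if relation not in ("sibling", "uncle", "aunt", "grandparent"):
                raise TrioInputError(f"bad relative relation {relation!r}")

    @property
    def trio_ids(self):
        return (self.proband_id, self.father_id, self.mother_id)


@dataclass(frozen=True)
class VariantObservation:
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    gene_symbol: str
    consequence: str
    transcript: str = ""
    hgvs_c: str = ""
    hgvs_p: str = ""
    pop_af: float | None = None  # None = absent from population data
    genotypes: dict = field(default_factory=dict)  # sample id -> GT string
    quality_pass: bool = True
    deleterious_predicted: bool = False
    known_plp: bool = False  # reported indisputable P/LP in variant databases
    literature_reported: bool = False  # same variant reported in prior cases

    def __post_init__(self):
        if self.alt == self.ref:
            raise ValueError(f"{self.key}: alt equals ref")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"{self.key}: bad consequence {self.consequence!r}")
        if self.pop_af is not None and not (0.0 <= self.pop_af <= 1.0):
            raise ValueError(f"{self.key}: pop_af {self.pop_af} outside [0,1]")
        for sid, gt in self.genotypes.items():
            if gt not in GENOTYPES:
                raise ValueError(f"{self.key}: bad genotype {gt!r} for {sid}")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def is_null(self) -> bool:
        return self.consequence in NULL_CONSEQUENCES

    @property
    def on_chrx(self) -> bool:
        return self.chrom.removeprefix("chr") == "X"

    def genotype(self, sample_id: str) -> str:
        return self.genotypes.get(sample_id, "missing")


@dataclass(frozen=True)
class EvidenceEvent:
    """Orthogonal evidence entering at reanalysis: an intragenic CNV call or a
    second allele confirmed by focused Sanger sequencing."""

    case_id: str
    kind: str  # intragenic_cnv | second_allele_sanger
    gene_symbol: str
    description: str = ""
    classification_payload: tuple = ()  # EvidenceCode tokens or objects

    def __post_init__(self):
        if self.kind not in ("intragenic_cnv", "second_allele_sanger"):
            raise ValueError(f"bad evidence-event kind {self.kind!r}")


def read_ped(path) -> Pedigree:
    """Parse a whitespace-delimited 6-column PED file into a trio pedigree.

    The proband is the affected row with both parent ids set.  Additional
    rows become extra relatives, with the relation inferred structurally
    (shared parents -> sibling, parent-of-parent -> grandparent, sibling of
    a parent -> uncle/aunt).
    """
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cells = line.split()
        if len(cells) < 6:
            raise TrioInputError(f"{path}:{lineno}: expected 6 PED columns")
        fam, iid, fid, mid, sex, pheno = cells[:6]
        rows.append({
            "iid": iid,
            "fid": fid if fid != "0" else None,
            "mid": mid if mid != "0" else None,
            "sex": {"1": "male", "2": "female"}.get(sex, "unknown"),
            "affected": pheno == "2",
        })
    by_id = {r["iid"]: r for r in rows}
    probands = [
        r for r in rows
        if r["fid"] in by_id and r["mid"] in by_id and r["affected"]
    ] or [r for r in rows if r["fid"] in by_id and r["mid"] in by_id]
    if not probands:
        raise TrioInputError(f"{path}: incomplete trio (no row with both parents present)")
    pro = probands[0]
    father, mother = by_id[pro["fid"]], by_id[pro["mid"]]
    trio = {pro["iid"], father["iid"], mother["iid"]}
    relatives = []
    for r in rows:
        if r["iid"] in trio:
            continue
        if (r["fid"], r["mid"]) == (pro["fid"], pro["mid"]):
            relation = "sibling"
        elif r["iid"] in (father["fid"], father["mid"], mother["fid"], mother["mid"]):
            relation = "grandparent"
        elif (r["fid"], r["mid"]) in (
            (father["fid"], father["mid"]),
            (mother["fid"], mother["mid"]),
        ) and r["fid"] is not None:
            relation = "uncle" if r["sex"] == "male" else "aunt"
        else:
            relation = "grandparent"  # conservative default for untyped links
        relatives.append((r["iid"], relation, r["affected"]))
    affected_parents = frozenset(
        name for name, row in (("father", father), ("mother", mother)) if row["affected"]
    )
    return Pedigree(
        proband_id=pro["iid"],
        father_id=father["iid"],
        mother_id=mother["iid"],
        proband_sex=pro["sex"] if pro["sex"] != "unknown" else "female",
        proband_affected=pro["affected"],
        extra_relatives=tuple(relatives),
        affected_parents=affected_parents,
    )


_SIDEBAR_COLUMNS = [
    "key", "gene", "consequence", "transcript", "hgvs_c", "hgvs_p",
    "pop_af", "deleterious", "known_plp", "literature",
]


def read_annotation_sidecar(path) -> dict:
    """Sidecar annotation TSV keyed by chrom:pos:ref:alt."""
    out = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _SIDEBAR_COLUMNS:
            raise TrioInputError(f"{path}: bad annotation header {header}")
        for line in fh:
            cells = dict(zip(_SIDEBAR_COLUMNS, line.rstrip("\n").split("\t")))
            out[cells["key"]] = cells
    return out


def _alt_genotype(gt_indices, alt_index: int, haploid: bool) -> str:
    """Re-express a (possibly multi-allelic) genotype w.r.t. one alt allele."""
    if any(i < 0 for i in gt_indices):
        return "missing"
    copies = sum(1 for i in gt_indices if i == alt_index)
    if haploid:
        return "1" if copies else "0"
    return {0: "0/0", 1: "0/1", 2: "1/1"}[copies]


def read_trio_vcf(path, ped: Pedigree, annotations: dict | None = None) -> list:
    """Read a multi-sample VCF into per-alt-allele VariantObservation records.

    Records failing FILTER are retained with ``quality_pass=False``.  Raises
    if any pedigree sample is missing from the VCF columns.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    needed = set(ped.trio_ids) | {sid for sid, _, _ in ped.extra_relatives}
    missing = needed - set(samples)
    if missing:
        raise TrioInputError(f"{path}: sample columns missing from VCF: {sorted(missing)}")
    observations = []
    for record in vcf:
        info = dict(record.INFO)
        filter_pass = record.FILTER is None  # cyvcf2: None == PASS
        gt_rows = record.genotypes  # [a, b, phased] or [a, phased]
        for alt_index, alt in enumerate(record.ALT, start=1):
            key = f"{record.CHROM}:{record.POS}:{record.REF}:{alt}"
            ann = dict(annotations.get(key, {})) if annotations else {}
            gene = ann.get("gene") or info.get("GENE", "")
            consequence = ann.get("consequence") or info.get("CONSEQ", "other")
            af_raw = ann.get("pop_af", info.get("POP_AF", ""))
            pop_af = None if af_raw in ("", ".", None) else float(af_raw)
            genotypes = {}
            for sample, gt in zip(samples, gt_rows):
                indices = [int(i) for i in gt[:-1]]
                try:
                    genotypes[sample] = _alt_genotype(indices, alt_index, len(indices) == 1)
                except KeyError:
                    log.warning("%s: unparseable genotype for %s, set to missing", key, sample)
                    genotypes[sample] = "missing"
            observations.append(VariantObservation(
                chrom=record.CHROM,
                pos=record.POS,
                ref=record.REF,
                alt=alt,
                gene_symbol=gene,
                consequence=consequence if consequence in CONSEQUENCES else "other",
                transcript=ann.get("transcript", info.get("TRANSCRIPT", "")),
                hgvs_c=ann.get("hgvs_c", info.get("HGVSC", "")),
                hgvs_p=ann.get("hgvs_p", info.get("HGVSP", "")),
                pop_af=pop_af,
                genotypes=genotypes,
                quality_pass=filter_pass,
                deleterious_predicted=str(ann.get("deleterious", info.get("DELETERIOUS", 0))) == "1",
                known_plp=str(ann.get("known_plp", info.get("KNOWN_PLP", 0))) == "1",
                literature_reported=str(ann.get("literature", info.get("LITERATURE", 0))) == "1",
            ))
    return observations


def write_trio_vcf(path, observations, sample_ids) -> None:
    """Write observations back out as a minimal VCF 4.2 text file.

    One line per observation (already decomposed); annotations are carried
    in INFO so a read/write/read cycle preserves the full record.
    """
    contigs = []
    for obs in observations:
        if obs.chrom not in contigs:
            contigs.append(obs.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c},length=100000>\n")
        for key, desc, typ in [
            ("GENE", "Gene symbol", "String"),
            ("CONSEQ", "Functional consequence", "String"),
            ("TRANSCRIPT", "Transcript", "String"),
            ("HGVSC", "HGVS cDNA", "String"),
            ("HGVSP", "HGVS protein", "String"),
            ("POP_AF", "Population allele frequency", "Float"),
            ("DELETERIOUS", "In-silico deleterious flag", "Integer"),
            ("KNOWN_PLP", "Reported P/LP flag", "Integer"),
            ("LITERATURE", "Reported in prior cases flag", "Integer"),
        ]:
            fh.write(f'##INFO=<ID={key},Number=1,Type={typ},Description="{desc}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\t"
                 + "FORMAT\t" + "\t".join(sample_ids) + "\n")
        for obs in sorted(observations, key=lambda o: (contigs.index(o.chrom), o.pos, o.alt)):
            info_parts = [f"GENE={obs.gene_symbol}", f"CONSEQ={obs.consequence}"]
            if obs.transcript:
                info_parts.append(f"TRANSCRIPT={obs.transcript}")
            if obs.hgvs_c:
                info_parts.append(f"HGVSC={obs.hgvs_c}")
            if obs.hgvs_p:
                info_parts.append(f"HGVSP={obs.hgvs_p}")
            if obs.pop_af is not None:
                info_parts.append(f"POP_AF={obs.pop_af:.6g}")
            info_parts.append(f"DELETERIOUS={int(obs.deleterious_predicted)}")
            info_parts.append(f"KNOWN_PLP={int(obs.known_plp)}")
            info_parts.append(f"LITERATURE={int(obs.literature_reported)}")
            gts = [
                {"missing": "./."}.get(obs.genotype(s), obs.genotype(s))
                for s in sample_ids
            ]
            fh.write("\t".join([
                obs.chrom, str(obs.pos), ".", obs.ref, obs.alt, ".",
                "PASS" if obs.quality_pass else "FAIL",
                ";".join(info_parts), "GT", "\t".join(gts),
            ]) + "\n")


def write_ped(path, ped: Pedigree, family_id: str = "FAM") -> None:
    sex_code = {"male": "1", "female": "2"}
    lines = [
        f"{family_id}\t{ped.father_id}\t0\t0\t1\t{'2' if 'father' in ped.affected_parents else '1'}",
        f"{family_id}\t{ped.mother_id}\t0\t0\t2\t{'2' if 'mother' in ped.affected_parents else '1'}",
        f"{family_id}\t{ped.proband_id}\t{ped.father_id}\t{ped.mother_id}\t"
        f"{sex_code[ped.proband_sex]}\t{'2' if ped.proband_affected else '1'}",
    ]
    for sid, relation, affected in ped.extra_relatives:
        lines.append(f"{family_id}\t{sid}\t0\t0\t0\t{'2' if affected else '1'}")
    Path(path).write_text("\n".join(lines) + "\n")
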