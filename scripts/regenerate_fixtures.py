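"""One-off generator for the packaged text fixtures under src/pestriage/data/.

Run from repo root: python scripts/regenerate_fixtures.py
"""
import json
from pathlib import Path

OUT = Path(__file__).resolve().parents[1] / "src" / "pestriage" / "data"
OUT.mkdir(parents=True, exist_ok=True)

# ---------------------------------------------------------------- ontology
ROOT = ("HP:0000001", "All", None)
PHEN = ("HP:0000118", "Phenotypic abnormality", "HP:0000001")

HEADS = {
    "central_nervous": ("HP:0002011", "Abnormality of the central nervous system"),
    "facial": ("HP:0000271", "Abnormality of the face"),
    "chest": ("HP:0000765", "Abnormality of the thorax"),
    "cardiovascular": ("HP:0001626", "Abnormality of the cardiovascular system"),
    "abdominal": ("HP:0001438", "Abnormality of the abdomen"),
    "urogenital": ("HP:0000119", "Abnormality of the genitourinary system"),
    "skeletal": ("HP:0000924", "Abnormality of the skeletal system"),
    "isolated_hydrops": ("HP:0001789", "Hydrops fetalis"),
    "FGR": ("HP:0001511", "Intrauterine growth retardation"),
    "increased_NT": ("HP:0010880", "Increased nuchal translucency"),
}
EXTRA_HEADS = [
    ("HP:0012759", "Neurodevelopmental abnormality"),
    ("HP:0001939", "Abnormality of metabolism/homeostasis"),
    ("HP:0002664", "Neoplasm"),
]

# (id, name, parent)
LEAVES = [
    ("HP:9000100", "Abnormality of the cerebral ventricles", "HP:0002011"),
    ("HP:0002119", "Ventriculomegaly", "HP:9000100"),
    ("HP:9000103", "Dilation of lateral ventricles", "HP:0002119"),
    ("HP:0001274", "Agenesis of corpus callosum", "HP:0002011"),
    ("HP:0002079", "Hypoplasia of the corpus callosum", "HP:0002011"),
    ("HP:0000238", "Hydrocephalus", "HP:9000100"),
    ("HP:0001305", "Dandy-Walker malformation", "HP:0002011"),
    ("HP:0002280", "Enlarged cisterna magna", "HP:0002011"),
    ("HP:9000101", "Widened posterior fossa", "HP:0002011"),
    ("HP:9000102", "Bilateral choroid plexus cysts", "HP:0002011"),
    ("HP:9000104", "Porencephalic cyst", "HP:0002011"),
    ("HP:9000105", "Intracranial hemorrhage", "HP:0002011"),
    ("HP:0000347", "Micrognathia", "HP:0000271"),
    ("HP:0000175", "Cleft palate", "HP:0000271"),
    ("HP:9000110", "Cleft lip", "HP:0000271"),
    ("HP:0000369", "Low-set ears", "HP:0000271"),
    ("HP:0000316", "Hypertelorism", "HP:0000271"),
    ("HP:9000111", "Aplasia of the nasal bone", "HP:0000271"),
    ("HP:9000112", "Congenital cataract", "HP:0000271"),
    ("HP:0000776", "Congenital diaphragmatic hernia", "HP:0000765"),
    ("HP:0002202", "Pleural effusion", "HP:0000765"),
    ("HP:9000120", "Congenital cystic adenomatoid malformation of the lung", "HP:0000765"),
    ("HP:0001636", "Tetralogy of Fallot", "HP:0001626"),
    ("HP:0001629", "Ventricular septal defect", "HP:0001626"),
    ("HP:0001640", "Cardiomegaly", "HP:0001626"),
    ("HP:9000130", "Transposition of the great arteries", "HP:0001626"),
    ("HP:9000131", "Supraventricular tachycardia", "HP:0001626"),
    ("HP:9000132", "Right aortic arch", "HP:0001626"),
    ("HP:9000133", "Abnormality of ductus venosus blood flow", "HP:0001626"),
    ("HP:0001539", "Omphalocele", "HP:0001438"),
    ("HP:0001541", "Ascites", "HP:0001438"),
    ("HP:0001561", "Polyhydramnios", "HP:0001438"),
    ("HP:9000140", "Echogenic bowel", "HP:0001438"),
    ("HP:9000141", "Single umbilical artery", "HP:0001438"),
    ("HP:0000107", "Renal cyst", "HP:0000119"),
    ("HP:0000126", "Hydronephrosis", "HP:0000119"),
    ("HP:9000150", "Renal agenesis", "HP:0000119"),
    ("HP:9000151", "Hyperechogenic kidneys", "HP:0000119"),
    ("HP:9000152", "Ambiguous genitalia", "HP:0000119"),
    ("HP:0001762", "Talipes equinovarus", "HP:0000924"),
    ("HP:0001155", "Abnormality of the hand", "HP:0000924"),
    ("HP:9000160", "Short long bone", "HP:0000924"),
    ("HP:9000161", "Radial dysplasia", "HP:0000924"),
    ("HP:9000162", "Hypoplasia of the ulna", "HP:0000924"),
    ("HP:9000163", "Arthrogryposis multiplex congenita", "HP:0000924"),
    ("HP:9000164", "Hand clenching", "HP:0001155"),
    ("HP:9000165", "Split foot", "HP:0000924"),
    ("HP:9000166", "Abnormality of digit", "HP:0001155"),
    ("HP:9000170", "Generalized fetal edema", "HP:0001789"),
    ("HP:9000180", "Severe intrauterine growth retardation", "HP:0001511"),
    ("HP:9000190", "Cystic hygroma", "HP:0010880"),
    ("HP:9000200", "Large for gestational age", "HP:0000118"),
    ("HP:0001249", "Intellectual disability", "HP:0012759"),
    ("HP:0001250", "Seizure", "HP:0012759"),
    ("HP:0000407", "Sensorineural hearing impairment", "HP:0012759"),
    ("HP:9000210", "Metabolic decompensation", "HP:0001939"),
    ("HP:9000211", "Hypercholesterolemia", "HP:0001939"),
    ("HP:9000220", "Retinoblastoma", "HP:0002664"),
    ("HP:9000221", "Breast carcinoma", "HP:0002664"),
]

terms = [ROOT, PHEN]
for cat, (tid, name) in HEADS.items():
    terms.append((tid, name, "HP:0000118"))
for tid, name in EXTRA_HEADS:
    terms.append((tid, name, "HP:0000118"))
terms.extend(LEAVES)

# pad each malformation-category head with synthetic noise leaves
pad_id = 9500000
for cat, (head, _) in HEADS.items():
    for i in range(8):
        terms.append((f"HP:{pad_id}", f"Synthetic {cat} finding {i + 1}", head))
        pad_id += 1

lines = [
    "format-version: 1.2",
    "ontology: mini-hpo-synthetic",
    "remark: synthetic miniature phenotype ontology fixture; real HP ids are"
    " used only for well-known terms, HP:9xxxxxx ids are invented",
    "",
]
for tid, name, parent in terms:
    lines.append("[Term]")
    lines.append(f"id: {tid}")
    lines.append(f"name: {name}")
    if parent:
        lines.append(f"is_a: {parent}")
    lines.append("")
(OUT / "mini_hpo.synthetic.obo").write_text("\n".join(lines))
print(f"ontology: {len(terms)} terms")

# ---------------------------------------------------------------- KB
# gene omim disease modes terms onset sf status lof paralog lit
KB_V1 = [
    # established per-category disease genes (onset prenatal)
    ("NFIA", "600727", "Brain malformations with or without urinary tract defects", "AD", "HP:0001274|HP:0002119|HP:0002079", "prenatal", 0, "established", 1, 0, ""),
    ("ARV1", "611647", "Epileptic encephalopathy, early infantile, 38", "AR", "HP:9000103|HP:0000238", "prenatal", 0, "established", 1, 0, ""),
    ("ATRX", "300032", "Alpha-thalassemia/mental retardation syndrome", "XLR", "HP:0002079|HP:0000238", "prenatal", 0, "established", 1, 0, ""),
    ("KCNK9", "605874", "Birk-Barel syndrome", "AD", "HP:0000347|HP:0000175", "prenatal", 0, "established", 1, 0, ""),
    ("FREM2", "617524", "Fraser syndrome 2", "AR", "HP:9000110|HP:0000316", "prenatal", 0, "established", 1, 0, ""),
    ("CRYAA", "123580", "Cataract 9, multiple types", "AD", "HP:9000112", "prenatal", 0, "established", 0, 0, ""),
    ("ZFPM2", "603693", "Diaphragmatic hernia 3", "AD", "HP:0000776", "prenatal", 0, "established", 1, 0, ""),
    ("LRP2", "600073", "Donnai-Barrow syndrome", "AR", "HP:0000776|HP:0002202", "prenatal", 0, "established", 1, 0, ""),
    ("MAPK1", "176948", "Noonan syndrome 13", "AD", "HP:0001636|HP:0001629|HP:9000130", "prenatal", 0, "established", 1, 0, ""),
    ("LZTR1", "600574", "Noonan syndrome 2", "AR", "HP:0001629|HP:0001640", "prenatal", 0, "established", 1, 0, ""),
    ("FLNA", "300017", "Periventricular nodular heterotopia / cardiac valvular dysplasia", "XLD", "HP:0001629|HP:0001640", "prenatal", 0, "established", 0, 0, ""),
    ("CDKN1C", "600856", "Beckwith-Wiedemann syndrome", "AD", "HP:0001539", "prenatal", 0, "established", 1, 0, ""),
    ("TMEM67", "609884", "Meckel syndrome 3", "AR", "HP:9000140|HP:0001541", "prenatal", 0, "established", 1, 0, ""),
    ("HNF1B", "189907", "Renal cysts and diabetes syndrome", "AD", "HP:0000107|HP:9000151", "prenatal", 0, "established", 1, 0, ""),
    ("PKHD1", "606702", "Polycystic kidney disease 4", "AR", "HP:0000126|HP:9000151", "prenatal", 0, "established", 1, 0, ""),
    ("CLCN5", "300008", "Dent disease 1", "XLR", "HP:0000107", "prenatal", 0, "established", 1, 0, "HP:9000200|HP:0001561"),
    ("GDF5", "601146", "Multiple synostoses syndrome 2", "AD", "HP:9000160|HP:0001155", "prenatal", 0, "established", 1, 0, ""),
    ("TPM2", "190990", "Arthrogryposis, distal, type 1A", "AD", "HP:0001762|HP:9000164", "prenatal", 0, "established", 0, 0, ""),
    ("PLOD3", "603066", "Bone fragility with contractures, arterial rupture, and deafness", "AR", "HP:0001155|HP:9000105", "prenatal", 0, "established", 1, 0, ""),
    ("ZC4H2", "300897", "Wieacker-Wolff syndrome", "XLD", "HP:0001762|HP:0001155", "prenatal", 0, "established", 1, 0, ""),
    ("UBA1", "314370", "Spinal muscular atrophy, X-linked 2", "XLR", "HP:0000347|HP:9000163", "prenatal", 0, "established", 0, 0, ""),
    ("RASA1", "139150", "Capillary malformation with hydrops", "AD", "HP:9000170", "prenatal", 0, "established", 1, 0, ""),
    ("PIEZO1", "611184", "Lymphatic dysplasia with hydrops fetalis", "AR", "HP:9000170|HP:0001541", "prenatal", 0, "established", 1, 0, ""),
    ("KAT6A", "601408", "Arboleda-Tham syndrome", "AD", "HP:0001511", "prenatal", 0, "established", 1, 0, ""),
    ("PLK4", "605031", "Microcephaly and chorioretinopathy with growth retardation", "AR", "HP:9000180", "prenatal", 0, "established", 1, 0, ""),
    ("PTPN11", "176876", "Noonan syndrome 1", "AD", "HP:0010880|HP:9000190", "prenatal", 0, "established", 1, 0, ""),
    ("NEB", "161650", "Nemaline myopathy with fetal akinesia", "AR", "HP:9000190|HP:0010880", "prenatal", 0, "established", 1, 0, ""),
    # incidental-finding genes: childhood onset, postnatal-only phenotype branches
    ("SCN1A", "182389", "Dravet syndrome", "AD", "HP:0001250", "childhood", 0, "established", 1, 0, ""),
    ("KCNQ2", "602235", "Developmental and epileptic encephalopathy 7", "AD", "HP:0001250|HP:0001249", "childhood", 0, "established", 1, 0, ""),
    ("GJB2", "121011", "Deafness, autosomal recessive 1A", "AR", "HP:0000407", "childhood", 0, "established", 1, 0, ""),
    ("PAH", "612349", "Phenylketonuria", "AR", "HP:9000210|HP:0001249", "childhood", 0, "established", 1, 0, ""),
    # secondary-findings genes (SF-list stand-in membership)
    ("RB1", "614041", "Retinoblastoma", "AD", "HP:9000220", "childhood", 1, "established", 1, 0, ""),
    ("BRCA2", "600185", "Breast-ovarian cancer, familial, 2", "AD", "HP:9000221", "adult", 1, "established", 1, 0, ""),
    ("LDLR", "606945", "Familial hypercholesterolemia", "AD", "HP:9000211", "adult", 1, "established", 1, 0, ""),
    # undefined candidate genes (paralog / model support, no established disease)
    ("SMARCC2", "", "candidate: chromatin remodelling paralog", "", "", "childhood", 0, "undefined", 0, 1, ""),
    ("CAMK2D", "", "candidate: cardiac kinase, animal-model support", "", "", "childhood", 0, "undefined", 0, 1, ""),
]
# v2 adds two newly established disease genes (reanalysis discoveries)
KB_V2_EXTRA = [
    ("ZMYM2", "602221", "Neurodevelopmental-craniofacial syndrome with variable renal and cardiac abnormalities", "AD", "HP:9000102|HP:9000141", "prenatal", 0, "established", 1, 0, ""),
    ("CSNK2A1", "115440", "Okur-Chung neurodevelopmental syndrome", "AD", "HP:9000131|HP:0002202|HP:0001561", "prenatal", 0, "established", 1, 0, ""),
]

HDR = "gene\tomim_id\tdisease\tinheritance\thpo_terms\tonset\tsf_list\tgene_status\tlof_mechanism\tparalog_support\tliterature_hpo"


def kb_lines(rows):
    out = [HDR]
    for g, om, dis, modes, t, onset, sf, status, lof, par, lit in rows:
        out.append("\t".join([g, om, dis, modes, t, onset, str(sf), status, str(lof), str(par), lit]))
    return "\n".join(out) + "\n"


(OUT / "gene_disease_kb_v1.synthetic.tsv").write_text(kb_lines(KB_V1))
(OUT / "gene_disease_kb_v2.synthetic.tsv").write_text(kb_lines(KB_V1 + KB_V2_EXTRA))
(OUT / "sf_genes.synthetic.txt").write_text(
    "# synthetic stand-in for the ACMG recommended secondary-findings gene list (v2.0)\n"
    + "\n".join(["RB1", "BRCA2", "LDLR", "MYH7", "KCNQ1", "APC"]) + "\n"
)
print(f"KB v1: {len(KB_V1)} entries, v2: {len(KB_V1) + len(KB_V2_EXTRA)}")

# ------------------------------------------------- replay of printed ACMG sets
# (case_id, gene, variant_index, codes, printed class, origin, inheritance)
REPLAY = [
    (4, "NFIA", 1, "PVS1, PS2, PM2", "P", "De novo", "AD"),
    (19, "NFIA", 1, "PS2, PM1, PM2, PP3", "LP", "De novo", "AD"),
    (7, "EZH2", 1, "PS2, PS3_PM, PS4_PP, PM2, PM5, PP3", "P", "De novo", "AD"),
    (108, "EZH2", 1, "PS2_PM, PM1_PP, PM2, PP3", "LP", "De novo", "AD"),
    (12, "PPP2R1A", 1, "PS2, PM2, PP3", "LP", "De novo", "AD"),
    (30, "PPP2R1A", 1, "PM1, PM2, PS3_PP, PS2_PVS", "P", "De novo", "AD"),
    (21, "ADNP", 1, "PVS1_PS, PS2_PM, PM2", "LP", "De novo", "AD"),
    (46, "ADNP", 1, "PVS1_PS, PS2, PM2", "P", "De novo", "AD"),
    (18, "ARV1", 1, "PVS1, PM2, PM3", "P", "Pat", "AR"),
    (18, "ARV1", 2, "PVS1, PM2_PP, PM3", "P", "Mat", "AR"),
    (31, "ZMYM2", 1, "PVS1, PS2_PP, PM2", "P", "De novo", "AD"),
    (38, "KCNK9", 1, "PS2_PVS, PS3_PP, PM2", "P", "De novo", "AD"),
    (40, "CRYAA", 1, "PS4, PM2, PP1_PS, PP3", "P", "Pat(affected)", "AD"),
    (65, "MAPK1", 1, "PS2, PM2, PP3, PP2", "LP", "De novo", "AD"),
    (102, "GDF5", 1, "PS2_PM, PM1_PP, PM2, PP3", "P", "De novo", "AD"),
    (107, "SCN4A", 1, "PVS1, PM2", "LP", "Mat", "AR"),
    (107, "SCN4A", 2, "PM2, PM3_PP, PM5, PP3", "LP", "De novo", "AR"),
    (110, "PUF60", 1, "PVS1_PM, PS2_PM, PM2", "LP", "De novo", "AD"),
    (114, "ZC4H2", 1, "PVS1_PS, PS2", "P", "De novo", "XL"),
    (116, "SMAD4", 1, "PS2, PS4, PM2_PP, PM5, PP3", "P", "De novo", "AD"),
    (118, "TPM2", 1, "PS3_PP, PS4_PM, PM2, PP3", "LP", "Mat (affected)", "AD"),
    (159, "BRPF1", 1, "PS2, PM2, PVS1_PS", "P", "De novo", "AD"),
    (163, "KAT6A", 1, "PVS1, PS2, PM2", "P", "De novo", "AD"),
    (169, "KMT2C", 1, "PVS1, PS2, PM2", "P", "De novo", "AD"),
    (170, "KCNT1", 1, "PM2, PP3, PS2_PVS", "P", "De novo", "AD"),
    (172, "NFIB", 1, "PM1, PP3, PS3_PP, PS2_PP, PM2", "LP", "De novo", "AD"),
    (189, "UBA1", 1, "PM1, PM2, PP3, PP4", "LP", "Mat", "XR"),
    (206, "PLOD3", 1, "PVS1, PM2", "LP", "Mat", "AR"),
    (206, "PLOD3", 2, "PVS1, PM2", "LP", "Pat", "AR"),
    (218, "MTOR", 1, "PS2, PM2, PP3, PP2", "P", "De novo", "AD"),
    (219, "KMT2A", 1, "PM2, PVS1, PS2_PM", "P", "De novo", "AD"),
    (221, "ARID1A", 1, "PS2, PM2, PVS1_PS", "P", "De novo", "AD"),
    (225, "CSNK2A1", 1, "PVS1_PS, PM1, PM2", "LP", "De novo", "AD"),
    (229, "CLCN5", 1, "PVS1_PS, PM1, PM2", "LP", "Mat", "XR"),
]
rep = ["case_id\tgene\tvariant_index\tcodes\texpected_class\torigin\tinheritance"]
for row in REPLAY:
    rep.append("\t".join(str(x) for x in row))
(OUT / "acmg_code_replay.tsv").write_text("\n".join(rep) + "\n")
assert len(REPLAY) == 34
assert len({(c, g) for c, g, *_ in REPLAY}) == 31
print("replay: 34 variant rows, 31 case entries")

# ------------------------------------------------- printed cohort count fixture
counts = {
    "n_cases": 1618,
    "arms": {"retrospective": 565, "prospective": 1053},
    "per_step": {
        "1": {"positive": 187, "inconclusive": 55},
        "2": {"positive": 28, "inconclusive": 68},
        "3": {"positive": 14, "inconclusive": 8},
    },
    "total_positive": 229,
    "total_inconclusive": 131,
    "inheritance_mix": {
        "AD_de_novo": 145,
        "AD_inherited": 27,
        "AR": 40,
        "XL_de_novo": 7,
        "XL_maternal": 10,
    },
    "family_history": {
        "significant": [48, 100],
        "_comment_sporadic": "positives among family-history cases = 12 retro + 42 pro = 54; sporadic = (229-54)/(1618-134)",
        "sporadic": [175, 1484],
    },
    "arm_positive": {"retrospective": [98, 565], "prospective": [131, 1053]},
    "nt_strata": {
        "isolated_total": [6, 121],
        "isolated_3p5_4p9": [3, 78],
        "isolated_ge5p0": [3, 43],
        "associated_ge3p5": [12, 47],
        "associated_3p0_3p4": [None, 522],
    },
    "incidental_findings": 8,
    "secondary_findings": 13,
    "candidate_variants": 33,
    "candidate_cases": 31,
    "reanalysis_breakdown": {
        "vus_to_lp_new_phenotype": 1,
        "if_to_positive_new_phenotype": 7,
        "new_disease_gene": 3,
        "intragenic_cnv": 2,
        "second_allele_sanger": 1,
    },
}
(OUT / "cohort_counts.json").write_text(json.dumps(counts, indent=2) + "\n")
print("cohort_counts.json written")
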