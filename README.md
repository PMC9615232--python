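# pestriage

Genotype-driven three-step triage of prenatal trio exome data.

## The problem

When a fetal structural anomaly is found on ultrasound and karyotype/CMA are
uninformative, trio exome sequencing (fetus + both parents) is the next
diagnostic step. Interpreting those exomes is hard precisely because the
phenotype is thin: many disease presentations are invisible in utero
(developmental delay, metabolic disease, dysmorphic detail), and new findings
keep appearing as the pregnancy progresses. `pestriage` implements the
analysis framework used by large prenatal-exome programs to cope with this:

1. **Step 1 — genotype-driven screen** (no phenotype input): shortlist
   known pathogenic/likely-pathogenic (P/LP) alleles, extremely rare null
   changes (nonsense, frameshift, canonical splice), and rare variants whose
   trio inheritance pattern is causal-prone — de novo, homozygous, compound
   heterozygous (phased by parental origin), or hemizygous on chrX.
2. **Step 2 — phenotype-driven review**: rare protein-altering variants in
   disease genes whose Human Phenotype Ontology (HPO) annotations match the
   clinical indications — exactly, at the organ-system superclass level, or
   through literature links — are reviewed with phenotype-informed evidence
   (co-segregation PP1, recurrent-report PS4, phenotype specificity PP4).
3. **Step 3 — reanalysis**: triggered by late-appearing phenotypes, a new
   knowledge-base version (newly established disease genes), or orthogonal
   evidence events (intragenic CNVs, a second allele found by focused Sanger
   sequencing). Tier transitions are recorded in an append-only history.

Variant-level evidence uses the ACMG/ClinGen grammar with strength
modifiers (`PS2_PM` = PS2 applied at Moderate): evidence is combined over
*applied* strengths with the standard pathogenic/benign combining rules plus
the ClinGen SVI provision (1 Very Strong + 1 Moderate → LP). Case-level
results fall into five tiers: **positive** (P/LP explaining the phenotype),
**inconclusive** (matching VUS, with a high-risk flag), **incidental
finding** (P/LP in a childhood-onset gene unrelated to the fetal phenotype),
**secondary finding** (P/LP in an ACMG SF-list gene), and **candidate gene**
(deleterious, population-absent variants in undefined genes with paralog or
model support); everything else is negative.

The package bundles a synthetic miniature HPO ontology and gene–disease
knowledge base (both clearly labelled synthetic), a replay table of 34
published strength-modified code sets with their expert labels, the printed
count structure of a 1618-trio cohort, and a synthetic trio-cohort
generator that plants diagnostic variants with a realistic inheritance-mode
and step-discoverability mix so the full pipeline is testable offline.

## Worked example

Simulate a 100-trio cohort and triage it end to end (step 1–2 against KB
v1, reanalysis against KB v2 where triggered):

```bash
pestriage simulate --out cohort --seed 42 --n-cases 100
DATA=src/pestriage/data
pestriage summarize --cohort-dir cohort \
    --kb $DATA/gene_disease_kb_v1.synthetic.tsv \
    --kb-new $DATA/gene_disease_kb_v2.synthetic.tsv \
    --ontology $DATA/mini_hpo.synthetic.obo \
    --out reports
cat reports/summary.json
```

```json
{
 "n_cases": 100,
 "per_tier": {
  "positive": 17, "inconclusive": 11, "incidental_finding": 0,
  "secondary_finding": 0, "candidate_gene": 1, "negative": 71
 },
 "per_step_positive": {"1": 15, "2": 2},
 "per_step_inconclusive": {"2": 11},
 "positive_rate_pct": 17.0,
 "inconclusive_rate_pct": 11.0,
 "inheritance_mix": {"AD_de_novo": 12, "XL_de_novo": 1, "AR": 2, "AD_inherited": 2},
 "high_risk_vus": 9
}
```

Reading this: 17 of 100 fetuses received a molecular diagnosis (15 found by
the phenotype-blind genotype screen, 2 more by phenotype-driven review);
11 carry a phenotype-consistent VUS, 9 of them high-risk (deleterious
prediction, literature, or a prior affected fetus in the family); one case
has a candidate-gene finding in an undefined disease gene. Per-case JSON
reports in `reports/` show each variant's evidence codes, combined label,
inheritance pattern, match level, and tier.

Replaying the published code→classification table:

```bash
pestriage classify --replay src/pestriage/data/acmg_code_replay.tsv --out replay.tsv
# INFO pestriage: replay concordance: 32/34 (94.1%)
```

The two discordant rows are a documented internal inconsistency of the
source table: two entries printed P carry code sets identical to entries
printed LP; the engine follows the combining rules and reports LP for all
four.

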