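# Methods

## Evidence model

Variant-level evidence is a set of ACMG/ClinGen codes, each carrying an
*applied* strength that may differ from the base code's native level
(`PS2_PM` is PS2 used at Moderate, `PP1_PS` is PP1 upgraded to Strong; a
`_SA` suffix is reserved for stand-alone). Combining counts applied
strengths, not base categories, and evaluates the rule thresholds as
at-least conditions:

- Pathogenic: ≥2 Very Strong; 1 VS with (≥1 Strong, ≥2 Moderate,
  1 Moderate + 1 Supporting, or ≥2 Supporting); ≥2 Strong; or 1 Strong with
  (≥3 M, 2 M + ≥2 Sup, or 1 M + ≥4 Sup).
- Likely pathogenic: 1 VS + 1 M (the SVI provision); 1 S + 1–2 M;
  1 S + ≥2 Sup; ≥3 M; 2 M + ≥2 Sup; or 1 M + ≥4 Sup.
- Benign: BA1 or ≥2 BS. Likely benign: 1 BS + 1 BP or ≥2 BP.
- A code set satisfying both a pathogenic and a benign rule is conflicting
  evidence → VUS; an empty or insufficient set is VUS.

Reading thresholds as "at least" makes the outcome monotone: adding
pathogenic evidence never lowers the label, adding benign evidence never
raises it (outside the explicit conflict state). The engine is verified
exhaustively against an independently written enumerator over all
effective-strength multisets of size ≤5 per side.

One deliberate refinement: P/LP is only assertable against an *established*
gene–disease link. Variants in genes absent from the knowledge base or
with `gene_status=undefined` are capped at VUS regardless of the evidence
arithmetic — a de novo null change in a gene with no known disease is a
candidate finding, not a diagnosis. This is what routes candidate-gene
cases and "new disease gene at reanalysis" cases correctly.

### Automatic code assignment

`auto_assign` implements the rule-based layer: PVS1 for null consequences
(nonsense, frameshift, canonical splice) in genes where loss of function is
the disease mechanism; PS2 for trio-confirmed de novo (including the de
novo member of a compound-het pair); PM2 when the population allele
frequency is absent or < 1×10⁻⁴ (configurable; the criterion is
"extremely rare", and absence from population data counts); PM3 for the
in-trans partner of a P/LP allele; PS4 when the identical variant is
reported in previous affected individuals (a per-variant annotation flag);
PP3 for an in-silico deleterious prediction (taken as a supplied flag, not
computed — no Bayesian point scaling, no predictor-score modelling); PP1
for significant co-segregation, with strength scaled by the number of
affected carriers (1 → Supporting, 2–3 → Moderate, ≥4 → Strong, an
approximation of segregation-LOD practice); PP4 during phenotype-driven
review (steps 2–3 only — step 1 is phenotype-blind) when the gene matches
the presentation at the specific-term level. Expert- or event-supplied
codes override automatic codes on the same base and keep their provenance.

## Triage steps and tier assignment

Step 1 captures: known-P/LP alleles (annotation flag), rare null changes,
and rare protein-altering variants with pattern in {de novo, homozygous,
compound heterozygous, hemizygous}. Rarity is population AF absent or
< 1×10⁻³ (configurable). Apparent de novo calls with AF > 1×10⁻³ are
demoted to unresolved as probable genotyping artifacts; male chrX
heterozygous calls are treated as genotype errors; a missing parental
genotype yields "unresolved" rather than a guess, surfacing the variant for
step-2 review instead of dropping it.

Step 2 reviews rare protein-altering variants in knowledge-base genes whose
entries match the case at any level. Matching is three-tiered: *exact* on a
shared HPO term; *superclass* when the transitive is_a closures of the
entry terms and case terms intersect outside the two generic roots (this
covers both "entry annotated at organ-system level" and two sibling leaves
of one system); *literature* when the knowledge base links the gene to a
case term only through prior reported cases (a dedicated annotation
column). "Explains the phenotype partially or fully" is operationalized as
match ≠ none; partial vs full is not modelled.

Tier assignment per variant: P/LP + match → positive; VUS + match in an
established gene → inconclusive; P/LP without match → secondary finding if
the gene is on the bundled secondary-findings list, else incidental finding
if childhood-onset; deleterious, population-absent variants in undefined
genes with paralog/model support → candidate gene; otherwise negative. The
case tier is the highest-precedence variant tier (positive > inconclusive >
IF > SF > candidate > negative). Adult-onset secondary findings keep their
tier but are suppressed from default reports (`--report-adult-sf`
re-enables them). An inconclusive case is flagged *high-risk* when a
matching VUS carries a deleterious prediction, literature support, or the
family has a prior similarly affected fetus.

Step 3 re-runs matching and combining with the enlarged phenotype set, the
new knowledge-base version, and any evidence events: a
`second_allele_sanger` event injects PM3 (completing a compound
heterozygote), an `intragenic_cnv` event enters as a P/LP finding in its
gene. With no trigger the result object is returned unchanged (idempotent
by identity). Every tier change appends to the result history; findings
that become positive only at reanalysis are attributed to step 3, while
unchanged results keep their original detection step. Increased-NT cases
whose late phenotypes localize to organ systems are re-binned (one system →
that category, two or more → multisystem) via the ontology category map.

## Knowledge base and fixtures

The KB is a TSV of gene–disease links (inheritance modes, HPO terms, onset
class, SF-list membership, LoF-mechanism flag, paralog support, plus a
literature-HPO column) over an OBO-format is_a ontology, chosen for
diff-ability and hand-editing. The packaged ontology (~154 terms) and KB
(36 entries in v1, 38 in v2) are synthetic stand-ins — the real analysis
universe (all OMIM/Orphanet genes, full HPO) is neither enumerable nor
redistributable here — and carry `.synthetic.` in their filenames; real HP
identifiers appear only for well-known terms. KB v2 adds two genes
established after v1, driving the negative→positive reanalysis path. Onset
is a single label per entry (prenatal/childhood/adult, default childhood)
because only childhood vs late onset matters for IF/SF reporting.

Two non-synthetic fixtures carry published numbers: a 34-row replay table
of strength-modified code sets with their expert-assigned labels (31 cases;
three carry two variants each), and the printed count structure of a
1618-trio cohort (per-step yields, inheritance mix, family-history, arm,
and NT strata). Rates are always recomputed from (k, n) pairs and rounded
half-up to one decimal percent. The sporadic-rate denominator, not printed
directly, is derived from the inheritance table's family-history sub-rows
(54 of 134 family-history cases were positive, so sporadic =
175/1484 = 11.8%). Two replay rows are internally inconsistent in the
source (identical code sets printed both P and LP); the engine follows the
rules and reports them as mismatches rather than special-casing them.

## Synthetic cohort generator

Defaults are the reference study conditions: diagnostic fraction 0.142
split over steps 0.817/0.122/0.061; AD/AR/XL 0.751/0.175/0.074 among
positives; VUS 0.081, incidental 0.005, secondary 0.008, candidate 0.019;
malformation-category weights cardiovascular 0.179, CNS 0.162, skeletal
0.128, urogenital 0.114 with the remainder spread uniformly (the source
prints only the top four); retrospective arm fraction 0.349; ~34 background
variants per case (the "quickly ruled out" load); late-phenotype
probability 0.18; family-history probability 0.083 with 75% significant;
10/17 of X-linked positives maternally inherited; 60% of AR positives
compound heterozygous.

Plantings are constructed to be discoverable at their intended step:
step-1 positives are de novo (AD), biallelic null (AR), or hemizygous (XL)
variants in matching genes; step-2 positives are *parentally inherited*
missense variants that the genotype screen cannot capture and that reach
LP only with phenotype-driven evidence — a co-segregation flavor (affected
carrier parent and grandparent → PP1 Moderate) with typical phenotype, and
a literature flavor (PS4) with deliberately atypical, superclass-only
phenotype terms; step-3 positives come in three flavors — an incidental
finding upgraded by a matching late phenotype, a gene established only in
KB v2 (with a physician-request flag), and a single AR het completed by a
Sanger second-allele event. VUS plantings are single AR hets or
AD-inherited missense from unaffected parents (de novo VUS are not
generated: under the automatic rules a rare de novo missense in a disease
gene reaches LP, so uncertain de novos would require modelling expert
down-weighting, which is out of scope). Background variants are common
protein-altering or rare synonymous changes, so they can never satisfy the
capture or review rules — the generator provides review burden, not
false-positive pressure.

Genome coordinates are synthetic (one contig per autosomal gene, a shared
chrX), with no reference sequence, coverage, error, or mosaicism modelling.
Each case draws from `default_rng([seed, case_index])`, making cohorts
reproducible under case-order shuffling and byte-identical across runs.
Causal multisystem cases are not generated (genes are annotated within one
system); multisystem appears only among non-causal case categories.

What passing tests show, and what they do not: recovery statistics on this
generator demonstrate the *pipeline logic* — capture rules, phasing,
combining, matching, tier routing, reanalysis bookkeeping — under
error-free genotypes and annotation flags that agree with the planted
truth. They say nothing about performance on real data, where genotype
error, incomplete annotation, phenotype-conversion noise, and expert
judgement dominate.

## Statistics

Two-proportion comparisons use Fisher's exact two-sided test when any
expected cell is below 5, else the chi-square test without continuity
correction; the method used is always reported. The chi-square p converges
to the exact p as counts grow (within 0.005 at cells of a few hundred) but
can differ by several percent on moderate tables — the switch rule, not
agreement, is the contract. NT strata are isolated ≥3.5 mm (sub-binned
3.5–4.9 / ≥5.0) versus associated 3.0–3.4 / ≥3.5, with a Spearman trend
across isolated measurements. Clinical-impact tabulation buckets per-case
outcome records by tier; the overall impact numerator counts decisions
whose recorded reason cites the sequencing result (configurable rule — the
printed overall figure is not unambiguously reconstructible from the
published per-tier rows, so no attempt is made to force it).

## Problem sizes

The acceptance run uses a 500-case synthetic cohort (~70 positives), enough
to bound the step-share estimates within three binomial standard errors;
property tests use 120–2000 cases depending on the statistic. The combining
oracle is exhaustive (~10⁴ multiset pairs per side).

## Known limitations

- No read-backed phasing, mosaicism, uniparental disomy, or CNV calling;
  intragenic CNVs enter only as externally supplied evidence events.
- Consequence annotation is taken as given (VEP/ANNOVAR-style fields or a
  sidecar TSV); the package predicts nothing from sequence.
- PP3/BP4 and candidate-gene deleteriousness are supplied flags.
- Quality control is delegated to the VCF FILTER column.
- The five-tier logic models one proband finding per tier slot; cases
  combining positive and VUS findings resolve to the positive tier with
  both findings retained in the report.
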