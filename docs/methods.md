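# Methods

## Scope and data model

`rccland` interprets already-called, already-annotated variants. Alignment,
variant calling, allele-specific copy-number segmentation (FACETS-style) and
functional annotation (SIFT, PolyPhen-2, CADD, ClinVar, HGMD, population
frequencies) happen upstream; their outputs arrive in the input files. This
keeps every run offline and reproducible: annotations travel in VCF INFO
keys under a named dialect (built-in mapping is named `default`; see
`rccland.io.GERMLINE_DIALECTS` / `SOMATIC_DIALECTS`), clinical attributes in
a TSV, and copy-number segments in a SEG-style TSV with tumor/normal
`copy_ratio` and `minor_allele_copies`.

Coordinates are 1-based inclusive everywhere (VCF convention); a
`zero_based_half_open` flag converts UCSC-style segment input on read.
Missing annotations are represented as missing and can never satisfy a
filter or classification rule; absence from a population database in
particular is treated as "not observed", not as evidence of rarity or
commonness.

## Germline filtering

Five rules, evaluated in order with every failure recorded per call
(`FilterTrace`):

| rule | condition to pass | default |
|------|-------------------|---------|
| R1_reads | reads ≥ `germline_min_reads_total` and alt reads ≥ `germline_min_reads_alt` | 5, 3 |
| R2_af | allele fraction ∈ [`germline_af_low`, `germline_af_high`], closed interval | 0.3–0.7 |
| R3_popfreq | every *observed* population frequency < `popfreq_max` (strict) | 1% |
| R4_cohortfreq | carriers/cohort < `cohort_freq_max` (strict), counted over patients per distinct (chrom, pos, ref, alt) | 5% |
| R5_relevance | not synonymous and not non-exonic; splice variants are exempt | — |

R2 is a closed interval so exactly-boundary heterozygotes are kept. R4 is
computed on the set surviving R1–R3, matching the stated order of the
standard; a consequence is that relaxing R3 can, in contrived cases, add
carriers that newly trip R4 — the filter is therefore only guaranteed
monotone in `popfreq_max` when variants are private to single patients.
Splice means canonical ±2 sites; deeper intronic variants are `non_exonic`.

## P/LP classification

A filtered variant is promoted to PGV when any route fires: truncating
(nonsense/frameshift/splice, the standard loss-of-function reading),
in-frame indel affecting ≥ `inframe_min_aa` (4, i.e. "more than three")
amino acids, concordant predictors (missense with SIFT deleterious AND
PolyPhen-2 damaging AND CADD Phred ≥ `cadd_deleterious_min`), ClinVar
pathogenic/likely-pathogenic, or HGMD class DM/DP/DFP/FP. Routes accumulate
and are reported.

Two judgment calls are exposed as configuration:

* **CADD cut-off** — no Phred threshold is universally standard; 20
  (top ~1% of scored substitutions) is the conventional choice and is the
  default.
* **All-three vs majority predictors** — the default demands all three
  (`predictor_rule_requires_all=True`); a 2-of-3 majority mode exists.

A ClinVar benign/likely-benign assertion vetoes a promotion resting on the
predictor rule alone, modelling the downstream manual ACMG review; it never
overrides a truncating consequence or a positive database route. Full
28-criterion ACMG scoring is deliberately out of scope: the implemented
surface is the operational rule set plus the database routes.

## Stratification and association tests

Patients partition into SRP (any PGV in a syndromic-RCC gene — precedence),
OCP (any other PGV; DDR vs non-DDR subclass), NCP (no PGV). *PBRM1* sits in
the syndromic panel (an RCC predisposition gene); its fixture carrier is
also a *VHL* carrier, so group counts are insensitive to that placement.
Panels are YAML-editable; the packaged panel lists every gene the pipeline
references (~60 symbols) rather than a full commercial assay manifest, and
panel membership is validated at classification time.

Categorical associations use Fisher's exact test (two-sided) when a 2×2
table has any expected cell < 5 **or any empty observed cell** (the
chi-squared approximation is unsafe in both regimes); otherwise Pearson
chi-squared with Yates continuity correction for 2×2, uncorrected for r×c.
No exact r×c test is attempted; small-expected-count r×c tables run
chi-squared with a logged warning. Significance is p < `alpha` (0.05),
two-tailed. Reported percentages use decimal half-up rounding to one
decimal with explicit denominators (322 germline; 37 variants; 274 tumor;
28 carriers-with-tumor).

## Second hits

For each (carrier, PGV gene) with tumor data: somatic truncating variants
and SIFT+PolyPhen-damaging missense variants in the same gene (CADD is not
required here — second-hit calling predates it in the filter chain), LOH
(any overlapping segment with `minor_allele_copies == 0`, which includes
copy-neutral LOH), and copy loss (`copy_ratio < cnv_loss_ratio`, default
0.9, strict). Arm-level losses are detected by ordinary locus overlap — no
separate arm-fraction threshold exists because none is defined for the
procedure. The germline variant's own site is excluded from somatic
matching so the first hit is never double-counted. Segments lacking an
allele-specific estimate cannot support LOH and log a warning (panel
backbones genuinely under-detect LOH). Gene loci come from a packaged table
with real chromosome/arm labels and synthetic positions; any BED-like
five-column table can replace it.

## Mutational signatures

Passing somatic SNVs (synonymous included — catalogs are built
pre-consequence-filter) are tallied into the canonical 96 classes
(6 pyrimidine-centered substitutions × 16 flanking contexts); purine-strand
calls are reverse-complemented, and a context whose middle base contradicts
the reference allele is an error. Catalogs pool per patient group by
default (per-sample is a flag). Factorization is scikit-learn NMF
(Frobenius objective, random init), best of `n_restarts` (default 10) by
reconstruction error, deterministic given a seed; signatures are
column-normalized with exposures absorbing scale. If `k` is not given, the
smallest k in 1..5 whose incremental error improvement drops below 5% is
kept. Extracted signatures are assigned to a reference set by cosine
similarity, accepting matches strictly above `cosine_threshold` (0.7). The
package ships no reference signatures; COSMIC SBS tables can be supplied as
a TSV via `SignatureSet.from_frame`.

## Actionability

A packaged, versioned evidence TSV (gene, alteration class, basis,
OncoKB-style level 1/2/3A/3B/4/R1/R2, candidate therapy, oncogenic flag)
replaces live OncoKB/NCCN queries. Somatic rows match by consequence class
(synonymous and non-exonic calls never match), germline rows match any PGV
in the gene, and a dMMR row fires on `mmr_deficient = true`. Only patients
with tumor tissue are evaluated (they are the denominator). Patients are
counted once in the actionable fraction with precedence
somatic > germline > dMMR; rows with an oncogenic flag but no level feed an
oncogenic-but-not-actionable tally.

## Synthetic cohorts

**Deterministic reference cohort** (`generate_reference_cohort`): 322 patients
(217 male; 71 aged ≤46; stages 33/74/72/61/82; 274 with tumor tissue)
carrying exactly 37 PGVs in 32 patients across 25 genes — *VHL* ×7 (three
double-carriers with *PBRM1*, *BAP1*, *TP53*), *FH* ×2, one *TSC2* patient
with two variants, *FLCN*, *TSC1*, and 20 other-cancer-gene carriers — with
the 13/13/8/3 frameshift/nonsense/missense/splice mix, planted second hits
(six 3p losses over *VHL*, 17p loss over *FLCN*, 13q loss over *BRCA2*,
copy-neutral LOH at *FANCA*, 22q loss over *NF2*, a somatic *TSC1*
frameshift), a 30/9/8 somatic/germline/dMMR actionability decomposition,
and decoy variants that exercise every filter rule. Attributes the
composition does not pin (which patients smoke, carrier stages, exact ages
within an age band) are assigned by patient index, documented in the
emitted manifest, and carry no analytical weight. Generation is
byte-identical across runs.

**Stochastic generator** (`generate_random_cohort`): seeded cohorts with
configurable size, carrier prevalence (default 0.099), per-gene PGV weights
(default: the reference spectrum), heterozygous VAF ~ Normal(0.5, 0.05)
clipped into the filter band, Poisson sequencing depths (120× germline,
500× tumor), common-variant contamination (sites with database frequency
1–10% or ~8% cohort share, to exercise R3/R4), Poisson(10) somatic
mutations per tumor with contexts drawn from an optional planted signature
mixture (uniform otherwise), and a 39% per-carrier second-hit probability
split copy-loss/LOH/somatic-truncating. Every planted fact is returned and
written as a ground-truth table.

What the synthetic data does **not** emulate: real linkage between
genotype and phenotype (ages, stages and smoking are independent of carrier
status by construction except where planted), FFPE artifacts, sequencing
error, multi-allelic sites at scale, subclonal copy number, germline CNVs,
or realistic per-gene somatic driver spectra. Passing recovery tests
therefore demonstrates the correctness of the decision rules and plumbing
on inputs that satisfy the callers' contracts — not calling performance on
raw reads.

## Numerical choices and degenerate inputs

* Percentages: decimal half-up to 1 decimal (`round_half_up`), never
  binary-float `round()`.
* VCF INFO floats are written with 6 significant digits and snapped back to
  that text on read (htslib returns float32), so write→read round-trips are
  exact.
* Zero-length cohorts, zero denominators, duplicate patient IDs,
  overlapping segments per patient/chromosome, PGV genes without a locus,
  zero vectors in cosine similarity, and k exceeding the non-zero catalog
  columns are all hard errors, not warnings.
* NMF ties across restarts resolve to the first-seen minimum (restart
  order is seed-deterministic).

## Problem sizes used in the test suite

Unit and property tests run on the 322-patient reference cohort, randomized
call tables up to 1,000 calls × 100 trials, exhaustive 2×2 Fisher
enumeration up to n = 40, 10,000-mutation signature recoveries over 5
seeds, and a 1,000-patient stochastic cohort for exact planted-PGV
recovery — sizes chosen so the full suite completes in a few minutes on one
CPU while still covering every rule boundary.

## Known limitations

* The evidence table is a static snapshot by design; clinical use would
  re-export current OncoKB/NCCN content into the same TSV schema.
* LOH calling consumes FACETS-style output; it does not re-estimate allele-
  specific copy number, and segments without minor-allele estimates reduce
  sensitivity.
* No VUS tiering: only P/LP carriers define carrier status, so carrier
  prevalence is a lower bound by construction.
* Signature extraction has no stability (cophenetic) analysis and no
  indel/doublet catalogs; per-group pooled catalogs are small, so extracted
  signatures on real panel data should be treated as descriptive.
* The chi-squared fallback for sparse r×c tables is approximate; collapse
  categories or use a dedicated exact test if that matters.
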