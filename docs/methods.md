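# Methods

This note documents the statistical procedures implemented in `ccprs`, the
choices made where the design was genuinely open, and what the synthetic
data generator does and does not emulate.

## Data model

A cohort is an individuals × loci matrix of risk-allele dosages
g ∈ {0, 1, 2, missing}, a binary disease status, and lifestyle covariates
(age in years; sex; diet in three classes; weekly alcohol in the ordinal
bands 0, 1–6, 7–13, 14+; smoking never/ever). Dosage coding is fixed at
read time by each locus' declared risk allele; swapping the risk allele maps
g → 2−g. Readers accept a tidy delimited table (dosages or "X/Y" allele
pairs) and PLINK text PED/MAP; binary PLINK and VCF are out of scope.

Missing data policy: individuals are excluded locus-wise from per-locus
analyses, excluded entirely from polygenic scores (and listed), and handled
complete-case for covariates in adjusted models. A covariate that is wholly
missing (smoking often is in this kind of legacy data set) is dropped from
the adjustment with a warning rather than failing the run. The source study
does not state its missing-data handling; this is the package's own,
documented choice.

## Association models

For each locus the five standard codings are available: codominant (two
genotype indicators), dominant, recessive, log-additive (dosage), and the
allele-count 2×2. Crude odds ratios for the 2×2-representable models are
computed from the contingency table: OR = ad/bc, Woolf 95% interval, Pearson
chi-square p (no continuity correction), Haldane–Anscombe +0.5 on all cells
when any cell is empty (flagged in the output). The "log-additive/allelic"
pair is reported as two distinct quantities: the per-allele logistic slope
on dosage (the log-additive OR) and the allele-level 2×2 OR, which are close
but not identical.

Logistic models are fitted by Newton–Raphson/IRLS from a zero start;
convergence when max|score| < 1e-8 or the relative log-likelihood change
< 1e-10, capped at 100 iterations. Complete or quasi-complete separation is
detected as |β| > 15 on the log-odds scale, reported with a warning and a
non-converged flag; estimates are returned unpenalised (no Firth
correction — separation is flagged, not repaired). The fit is cross-checked
against an independent maximum-likelihood implementation in the test suite.

P-values for logistic models are likelihood-ratio tests of the genotype
term(s) against the covariate-only (or intercept-only) null — the convention
of the SNPstats-style workflow this package mirrors; confidence intervals
are Wald on the log-odds scale. Covariate codings: male indicator, age
linear in years, diet as two indicators with "mixed" as reference, alcohol
as integer scores 0–3 over the ordinal bands, smoking as an "ever"
indicator. The family-wise Bonferroni threshold is α/m with m defaulting to
the number of loci (0.05/11 displays as 0.0045 for the built-in panel).

## Hardy–Weinberg tests

Both a 1-df chi-square goodness-of-fit test (expected counts from the
estimated allele frequency) and the exact conditional test are implemented.
The exact test fixes the observed allele counts and sums the probabilities
of all heterozygote counts whose conditional probability does not exceed the
observed one. The exact test is the default for summary tables because rare
homozygote classes with expected counts below 5 occur at several panel loci.
Being discrete, the exact test is conservative: under null simulations at
n = 150 its rejection rate at α = 0.05 sits near 0.037–0.04 versus ~0.05
for the chi-square test; both behaviours are asserted in the test suite.
Monomorphic loci return the degenerate result (statistic 0, p = 1).

## Reconstructing counts from published rounded tables

To check printed odds ratios against printed frequencies, the package
inverts rounding: `reconstruct_counts` enumerates every integer genotype
triple summing to the group size whose frequencies round (half away from
zero, 2 decimals — the tables' display precision) to the printed values,
ordered by L2 distance to n×freqs. Ambiguity is surfaced as a candidate
list, never silently resolved, and inconsistent rows (three of the 22 rows
of the built-in panel do not admit any integer solution at the printed
precision) return an empty list. The printed HWE p-values of the source
tables are not reproducible from the rows' own rounded frequencies under
either test; the package therefore reports its own HWE results and makes no
attempt to reverse-engineer the source's procedure.

## Haplotypes and LD

EM over 2–3 biallelic loci with deterministic uniform initialisation
(optionally seeded Dirichlet restarts): the E-step distributes each
individual's dosage pattern over its compatible phase pairs with weights
proportional to products of current haplotype frequencies; the M-step
re-estimates frequencies from expected haplotype counts. Iteration stops
when the largest frequency change is below 1e-8 (cap 1000 iterations); the
log-likelihood is verified non-decreasing at every step, and on small
instances the fixed point is checked in the tests against a grid search of
the 1-parameter profile likelihood. Individuals missing any block genotype
are excluded. All-heterozygote data sets are unidentifiable (the likelihood
is bimodal and uniform initialisation is a stationary point); at least one
homozygous anchor is required for meaningful estimates.

LD is reported pairwise: D = h₁₁ − p₁p₂, D′ = |D|/D_max, r² =
D²/(p₁q₁p₂q₂), and p from χ² = 2n·r² on 1 df. Haplotype association fits
one joint logistic model of status on the expected dosages of all
non-reference haplotypes (reference = most frequent, ties broken
lexicographically with a warning; haplotypes under a 1% frequency floor are
pooled as "rare"), using the cases+controls pooled EM fit for dosage
construction. Per-haplotype p-values are 1-df likelihood-ratio tests of that
haplotype's term. Expected-dosage regression ignores phase uncertainty in
the variance, as standard; at the panel's low LD this is a second-order
effect.

## Polygenic risk scores

S_i = Σ_l w_l·g_il. Weights are **raw odds ratios**, not log-odds: the
weighted score is defined as the dosage multiplied by the relevant allelic
odds ratio, and only the raw-OR convention reproduces the study's printed
weighted mean difference (≈2.72 vs 2.75 printed; log-OR weights would give
≈0.8). The default weighted scheme uses adjusted allelic ORs; crude and
external weights are selectable. Group comparison is the pooled-variance
two-sample t-test with df = n₁+n₂−2.

Because E[g] = 2p under binomial dosage, the group mean difference obeys
E[ΔS] = 2·Σ_l w_l·(p_case,l − p_control,l). On the built-in panel's printed
allele frequencies this gives exactly 1.48 for unit weights and 2.7226 for
adjusted-OR weights; the 0.03 gap to the printed 2.75 is attributable to the
2-decimal rounding of the published frequency and OR tables. Risk alleles
default to the study's six named susceptibility alleles plus, for the five
loci it leaves unnamed, the allele in the direction implied by the printed
odds ratios (ACE D, VDR Bsm1 T, VDR Fok1 C, VDR Taq1 G, STAT4 T); all are
overridable. STAT4 is internally inconsistent in the source (T rarer in
patients yet OR > 1) and is carried as printed.

## Synthetic cohorts

`simulate_from_published_tables` draws genotypes per group straight from the
published group-specific genotype frequencies (renormalising rows whose
printed values sum within ±0.035 of 1 — the widest deviation in the built-in
panel is 0.97 — and refusing anything worse), with covariates drawn from
per-group distributions matching the published participant characteristics
(mean ages 49.0/58.9; an age SD of 12 years is assumed since none is
printed; sex, diet and alcohol probabilities renormalise the printed
counts). No disease model is imposed; group differences come entirely from
the frequency tables. This is the fixture for identity and table-shape
checks.

`simulate_cohort` imposes a disease model. Controls are drawn from
Hardy–Weinberg proportions at configured control frequencies (or from a
configured haplotype block, which induces LD); cases are drawn by
**exponential tilting**: candidates from the control model are accepted with
probability exp(lp − bound), lp = Σ_l ln(OR_l)·g_l + covariate effects. This
makes the case density proportional to P(x)·exp(lp), so the retrospective
case-vs-control logistic fit recovers the configured log odds ratios
*exactly* at any acceptance rate. A logistic-link acceptance rule (solving
an intercept for a target prevalence) was considered and rejected: it
attenuates retrospective odds ratios by roughly (1 − prevalence) unless the
disease is made artificially rare, which would waste most candidate draws.
The tilt bound is the maximum of lp over the covariate support, with age
bounded at ±6 SD; generation fails with a clear error if the acceptance rate
is too low. All randomness flows from the single config seed.

What the generator does **not** emulate: genome-scale LD beyond one
configured block, population stratification, genotyping error and
missingness patterns, and the correlation structure among lifestyle
covariates. Tests passing on these cohorts demonstrate correctness of the
estimators under the stated models, not robustness to real-data artefacts.

## Calibration and problem sizes

The simulation-based checks use the study's own sample sizes and a
mid-panel risk-allele frequency of 0.3: type-I error of the log-additive LRT
at n = 137/150 and of both HWE tests at n = 150 over 10,000 null replicates
(expected within ±0.015 of the nominal 0.05, the exact test near its
conservative lower edge); 95% Wald-interval coverage over 1,000 replicates
of n = 2,000; and recovery of ln 2 from a single n = 50,000 cohort at a
per-allele OR of 2. These sizes keep the whole suite and the acceptance
script to a few minutes on one CPU while leaving Monte-Carlo error well
inside the asserted bands.

## Known limitations

- No exact (conditional) logistic regression or Firth penalisation;
  separated models are flagged, not repaired (the study's own adjusted
  PTPN22 TT odds ratio of 14.2 with CI 1.6–130 illustrates the regime where
  those methods would be preferable).
- Haplotype blocks are limited to 2–3 loci; no partition–ligation EM, no
  per-individual phase export.
- The published tables embed rounding inconsistencies (rows not summing to
  1, one garbled codominant row in the source's association table); the
  package surfaces rather than repairs them, and comparisons against printed
  values carry tolerances reflecting 2-decimal rounding, not method slack.
- Adjusted odds ratios, haplotype odds ratios and t statistics printed by
  the source study depend on its individual-level data, which are not
  deposited; they are context for design choices here, never test oracles.
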