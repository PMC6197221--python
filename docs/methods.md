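# Statistical methods

This note records the exact statistics the package computes, the default
parameter choices and why they were made, and the known limitations.

## Allelic 2×2 association (`assoc_core`)

The allelic table counts chromosomes: `a` case chromosomes carrying the
allele, `b` case chromosomes not carrying it, `c`/`d` likewise for
controls. The odds ratio is `ad/bc` with a Woolf (log-normal) 95%
confidence interval, `exp(log OR ± 1.96·√(1/a+1/b+1/c+1/d))`. The P value
is the Pearson χ² test with 1 df and **no** Yates continuity correction
by default; the continuity correction is conservative at these sample
sizes and would not match published-scale reproductions.

When any cell is zero the OR is undefined; `haldane=True` adds 0.5 to
every cell (Haldane–Anscombe) **only when a zero cell exists**, so
non-degenerate tables are always scored exactly. Without the flag a zero
cell raises `ZeroDivisionError` naming the cell.

Genotypic tests code the per-sample dosage additively, dominantly, or
recessively and fit a logistic regression by IRLS (Newton–Raphson on the
log-likelihood) with Wald z statistics. For a saturated binary predictor
the fitted `exp(β)` equals the 2×2 OR (verified to six significant
digits in the acceptance suite); `statsmodels` is used in the test suite
only, as an independent oracle. Quasi-complete separation and rank
deficiency are detected and flagged rather than silently returning huge
coefficients. `conditional_test` refits with conditioning dosages as
covariates and reports the Wald test of the focal term.
`genomic_lambda` is the median association χ² divided by 0.4549
(the χ²₁ median), the usual confounding gauge.

## Haplotype EM and LD (`haplotype_ld`)

`em_haplotypes` maximises the multinomial likelihood of unphased
genotypes over haplotype frequencies under random mating (HWE at the
haplotype level). The E step distributes each ambiguous multi-locus
genotype over its consistent phase pairs in proportion to current
frequency products; the M step re-normalises expected chromosome counts.
Convergence is declared when the largest frequency change is below 1e-8.

The likelihood can have saddle points and symmetric multiple optima: a
uniform start is itself stationary whenever the phase posteriors tie
exactly (`f00·f11 = f01·f10`), which happens on a few percent of very
small samples. The fitter therefore runs a deterministic multistart —
the uniform start plus one start per complementary haplotype pair (mass
0.35 on each member of the pair) — and reports the converged optimum
with the best log-likelihood. On randomly generated ≤25-sample two-SNP
instances this attained the exhaustive grid-search maximum in 508/508
instances. When two symmetric optima tie exactly the reported point is
one of them; the log-likelihood is always reported alongside.

LD statistics for an allele pair: `D = f_AB − p_A·p_B`, `D′ = D/D_max`,
`r² = D²/(p_A(1−p_A)p_B(1−p_B))`. `stratified_ld` fits the EM
separately inside each sample stratum (e.g. cases vs controls), which is
the correct comparison when a disease model itself distorts LD in cases.
`haplotype_association` compares expected haplotype counts (EM fitted
per group) in a 2×2 chromosome table, optionally with a permutation P
value; `haplotype_association_from_frequencies` does the same from
externally supplied group frequencies and chromosome totals.
`haplotype_dosage` gives each sample's posterior expected copy number of
a target haplotype, and `recessive_state` thresholds the posterior
probability of carrying two copies.

## Multiallelic locus and RPE (`hla_rpe`)

Per-allele tests are allele-vs-all-other-alleles 2×2 chromosome tables.
Because the locus denominators are shared, a strong allele deflates
every other allele's case frequency; the sequential RPE procedure
removes that distortion. Round 1 selects the smallest-P allele
(uncorrected; the first test is the locus-wide hypothesis). Each later
round removes all previously selected alleles' chromosomes from both
groups and re-tests the remainder, selecting the best allele while
`Pc = P × n_correction < alpha` (default 0.05). `n_correction` counts
alleles still under test with control frequency above a floor
(default 0.5%), recomputed each round; a fixed initial count is
available via `correction="initial"`.

Two statistics are offered for rounds ≥ 2:

- `remaining_2x2` — the ordinary Pearson 2×2 test on the reduced table.
- `expected_deviation` (default) — a goodness-of-fit test of the
  allele's case count against its control-frequency expectation
  `exp = f̂_ctrl · n_case`. The naive `(obs−exp)²/exp` χ² is badly
  anticonservative because `f̂_ctrl` is itself estimated; the correct
  score-test null variance is
  `Var(obs−exp) = n_case·f·(1−f)·(1+n_case/n_control)` with `f` the
  pooled case+control frequency. With this variance the null tail
  probabilities are exactly nominal (verified by simulation at the
  Bonferroni-corrected level), and the sequential procedure's per-run
  familywise null-selection rate measures ≈4.3% at `alpha = 0.05`
  (1000 simulated null rounds), as Bonferroni control predicts.

`collapse_risk` converts a detected risk-allele set into a 0/1/2
per-sample dosage (fully untyped samples are NaN; a half-typed sample is
scored on its typed chromosome), and `reciprocal_conditional` fits
`phenotype ~ dosage_A + dosage_B` and reports each locus's Wald test
conditioned on the other — the standard check of which locus carries the
primary signal.

## Combined risk groups (`risk_interaction`)

Samples are cross-classified by haplotype carrier state and HLA risk
carrier state into four groups; each exposed group's OR is computed
against the double-negative reference group, and the multiplicativity
ratio `OR_joint / (OR_hap · OR_hla)` measures departure from a
multiplicative joint model (ratio > 1: super-multiplicative).

## Synthetic cohorts (`synthetic_data`)

Haplotype frequency constructors solve the 2- and 3-SNP frequency
vectors exactly from allele margins and a target r². The disease model
assigns each haplotype a per-chromosome odds ratio and tilts the
unordered haplotype-pair distribution by the logistic penetrance
`logit(P(case)) = intercept + Σ log(OR_h)` over the pair; case and
control pools are then sampled exactly at the configured sizes. Because
the tilt is closed-form, `expected_summaries` returns the exact group
haplotype frequencies, stratified r², and allele-vs-rest ORs implied by
any configuration — every simulation test compares estimates against
analytically known targets rather than against another simulation.

Defaults and their rationale:

- `intercept = -9` (rare disease, prevalence ~1e-4): the configured
  per-chromosome OR then passes through the case-control tilt
  essentially unchanged (relative-to-null-allele OR exact to ~1e-3).
  A common-disease intercept attenuates planted effects through
  penetrance saturation — supported, but not the default.
- Allele-vs-rest ORs at a multiallelic locus are **attenuated** below
  the planted per-chromosome values whenever another risk allele sits in
  the "rest" pool (e.g. planted 3.0/2.0 imply allele-vs-rest 2.76/1.64
  in the 20-allele fixture); `expected_summaries` reports the attenuated
  closed-form values, which the empirical counts match.
- Blocks (SNP block, HLA block) are sampled independently given
  phenotype; cross-block joint penetrance is not modelled. The provided
  `paperlike_config` links DRB1/DQB1 alleles within one HLA block, so
  within-block LD is exact.
- Missingness is missing-completely-at-random at `missing_rate`.

## QC cascade (`io_qc`)

Order: sample call rate (default ≥ 97%) → variant call rate (≥ 99%) →
MAF (≥ 5%) → HWE exact P (≥ 1e-3, required to fail in **both** phenotype
strata by default; `hwe_rule="either"` is stricter). The HWE test is the
exact conditional test (sum of heterozygote-count probabilities no
larger than the observed one), validated against brute-force
enumeration. The removal report records every removed sample/variant
with its reason, and the cascade is idempotent.

## Limitations

- The EM assumes random mating within each group it is fitted on;
  population structure or strong inbreeding biases haplotype
  frequencies. No genotype-uncertainty or imputation-dosage input.
- Woolf CIs and Pearson P values are asymptotic; for very sparse tables
  use the Haldane flag (OR) and treat P values with caution (the test
  suite's Fisher cross-checks quantify the divergence).
- The RPE procedure tests alleles marginally within each round; it does
  not model phase between alleles at different loci (use
  `reciprocal_conditional` on collapsed dosages for between-locus
  questions).
- The generator's closed-form guarantees hold for the implemented
  logistic tilt; it does not model covariates, relatedness, genotyping
  error, or cross-block epistasis.
- Permutation P values in `haplotype_association` permute phenotype
  labels, which assumes exchangeability (no covariate structure).
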