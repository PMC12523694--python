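# Methods

This note records the statistical model, the construction of the
relationship matrices, the synthetic-data generator's assumptions, and the
numerical and design choices behind the package.

## Repeatability animal model

Records are 305-day lactation yields (milk, fat, protein, kg). The model is
`y = Xb + Za + W pe + e` with contemporary group (herd × calving year ×
season), parity (1–3), and a linear age-at-calving covariate nested within
parity as fixed effects; additive genetic effects over the full pedigree;
and a permanent-environment effect per cow linking her repeated records.
Seasons follow the Southern-hemisphere dairy convention: October–March is
summer, April–September winter.

Variance components are inputs, not estimated: the package ships
illustrative defaults derived from heritabilities of 0.28 (milk), 0.21
(protein) and 0.25 (fat) with an assumed repeatability of 0.45, so
σ²ₐ = h²·Vp, σ²ₚₑ = (0.45 − h²)·Vp, σ²ₑ = 0.55·Vp. The repeatability value
is an assumption of this package (typical of 305-day yield evaluations),
made because only heritabilities are commonly published.

Henderson's mixed-model equations are assembled sparse. One contemporary-
group level is dropped (reference coding); the parity dummies jointly span
the intercept, which gives the usual estimable-function caveat for
reported fixed-effect values and makes EBVs invariant to phenotype shifts.
The age covariate is centred for conditioning. Fitting age as a linear
nested covariate (rather than age-class dummies) is a design choice; age
classes can be emulated upstream by recoding the column.

## Pedigree matrices

Pedigrees are renumbered parents-before-offspring (Kahn's algorithm);
animals appearing only as parents become founders, unknown parents are
base-population animals (no unknown-parent groups — deliberately out of
scope). A is built by the tabular method; A⁻¹ by the Meuwissen–Luo
ancestor-trace construction, always including inbreeding in the
Mendelian-sampling variances (d = 0.5 − 0.25(F_s + F_d) with both parents
known). The two routes are cross-checked against dense inversion in the
tests.

A₂₂ (pedigree relationships among genotyped animals) is the principal
submatrix of A; `extract_A22` forms it from dense A, and
`A22_from_A_inverse` obtains the same matrix by exact indirect products
(sparse solves of A⁻¹ against indicator columns), which is what the
evaluation bundle uses so that pedigrees of tens of thousands of animals
never require a dense n × n matrix. A₂₂⁻¹ is always a dense inverse of the
(small) genotyped block.

## Genomic relationships and QC

Dosages count the minor (or declared) allele; missing calls are imputed to
the locus mean *after* QC, before centering, which keeps the VanRaden
estimator unbiased at low missingness. G = ZZ′ / (2Σpⱼ(1−pⱼ)) with
observed allele frequencies (method 1); base-population frequencies are
unavailable in practice. G is invariant to which allele is counted.

QC applies, in order: individual call rate ≥ 0.90, SNP call rate ≥ 0.90,
MAF ≥ 0.05, Hardy–Weinberg equilibrium p ≥ 10⁻⁴ (one-df chi-square;
the asymptotic test was chosen over the exact test because it is
deterministic and oracle-checkable). Statistics are recomputed after each
rule, and the ordered pass repeats until no further removals occur —
dropping a locus can push an individual below the call-rate threshold —
making the filter idempotent; per-rule counts accumulate across passes.
The SNP call-rate cutoff of 0.90 is a configurable default (only "low
genotyping rate" is typically reported for this step).

## The hybrid matrix: blending, tuning, scaling

`tune_G` aligns G with A₂₂: TG0 none; TG1 affine a + bG with mean
diagonal 1 and mean off-diagonal 0; TG2 (standard) affine with both means
matched to A₂₂; TG3 additive shift matching overall means (additive rather
than multiplicative, to avoid sign trouble when mean(G) ≈ 0); TG4 an
Fst-style rescale G* = (1 − s/2)G + sJ with s = mean(A₂₂) − mean(G),
interpreting s as the drift correction between the two bases. TG1/TG2 are
degenerate when mean(diag G) = mean(offdiag G) and raise rather than
divide by ~0.

`blend_G` defaults to blending the matrices, G_b = (1−β)G + βA₂₂ — the
behaviour of the standard evaluation software — because β represents
residual polygenic variance on the covariance scale. A `literal_inverse`
mode blends the inverses, (1−β)G⁻¹ + βA₂₂⁻¹, for comparison; the two agree
exactly when G = A₂₂ and differ measurably otherwise.

`assemble_H_inverse` scatters τG_b⁻¹ − ωA₂₂⁻¹ into the genotyped block of
the sparse A⁻¹. With τ = ω = 1 and G_b = A₂₂ the scatter is exactly zero,
so the single-step model collapses to pedigree BLUP — a tested identity.

## Forward validation and realized accuracy

Validation masks *all* records of the n most recently born genotyped cows
with at least one lactation (whole-cow masking; birth-date ties break
lexicographically by id). n defaults to a fraction 0.32 of the eligible
cows and is configurable.

Realized accuracy is the Pearson correlation, over the validation cows,
of the solutions from the paired analyses of the same model with and
without their phenotypes. This paired-analysis definition is the default;
a config switch (`full_reference="ablup"`) scores every variant against
the full-data pedigree fit instead. The distinction matters: two nested
fits of the *same* estimator share parent-average estimation errors, so an
ABLUP-full yardstick structurally favours ABLUP-reduced and penalises any
model that adds information orthogonal to the pedigree; the paired
definition compares each model's internal consistency and is the one under
which genomic information shows its expected benefit.

Sweeps vary one factor at a time, holding the others at the standard
configuration (β = 0.05, TG2, τ = ω = 1): five blending runs
(β 0.40→0.05, labelled ssGBLUP_G0.60…G0.95), five tuning runs
(ssGBLUP_TG0…TG4), and ten scaling runs (five τ values with ω = 1, five ω
values with τ = 1). Each sweep emits a pedigree-model baseline row per
trait.

## Synthetic population generator

The generator emulates the structure of a national dairy evaluation with a
small genotyped subset:

- **Pedigree** — 300 founders and four discrete generations of 2,400
  offspring (~9,900 animals); parents come from the preceding cohort.
  Older cohorts are sired by small proven batteries (40 sires/generation),
  the two recent cohorts by wide young-bull batteries (200/generation), so
  recent cows' sires are weakly proven — the population state in which
  genomic evaluation is actually deployed.
- **Recording** — 65% of females ever enter milk recording (national
  pedigrees carry far more females than recorded cows); the youngest
  cohort is only 30% recorded at the evaluation date, and lactation counts
  are capped by cohort age (youngest: first lactations only). Records per
  cow are drawn 1/2/3 with probabilities 0.5/0.3/0.2 before the cap.
  Non-genotyped animals' sire and dam are present in the recorded pedigree
  with probabilities 0.6 and 0.8; genotyped animals keep complete
  parentage. True parents always drive inheritance.
- **Genotypes** — 4,000 unlinked biallelic SNPs, founder frequencies
  Uniform(0.05, 0.5), gene-dropped with independent Mendelian sampling per
  locus. No linkage map: sufficient for exercising the G/H algebra and
  accuracy trends; LD structure is out of scope.
- **Genetics** — 400 QTL among the SNPs carry effects; the additive
  variance is split 0.7 marker / 0.3 residual polygenic (so blending has a
  true optimum to detect), with trait effects correlated 0.8 across milk,
  protein and fat. Founder-cohort components are standardised exactly, so
  founder var(BV) equals σ²ₐ by construction and realised heritabilities
  track their targets up to pedigree sampling.
- **Phenotypes** — y = HYS effect (SD 0.5 Vp½, shared across traits) +
  parity effect + age covariate + BV + pe + e, with environmental
  correlation 0.8 across traits. Yields and component percentages are
  truncated to the legal recording windows (milk 1,000–30,000 kg,
  percentages 2–9%; ≲0.5% of records affected), so generated data pass the
  record edits unchanged.
- **Genotyping** — a 300-animal panel: 20% of the budget goes to sires
  sampled proportional to progeny count (proven AI bulls first), 80% to
  cows with a per-generation recency bias of 2; bull calves that never
  sired are not genotyped. Genotyped cows are always recorded.

All randomness flows from a single seed; equal configurations reproduce
bit-identical outputs.

What passing tests on these data show — and what they do not: the
generator reproduces the *information structure* (few genotyped animals,
weak recent pedigrees, repeated records, HYS grouping) but not LD between
markers and QTL, selection, genotyping errors, or non-MCAR missingness.
Accuracy levels on real data will differ; the tested claims are
definitional identities, oracle agreements, and directional comparisons.

## Problem sizes and numerics

Default test/simulation sizes (9,900-animal pedigree, ~3,000 recorded
cows, 4,000 SNPs) were chosen so a full replicate — simulation, matrices,
three model fits — runs in a few seconds; the replicate comparison uses
ten seeds. The MME direct solver is SuperLU in symmetric mode with an
AT+A minimum-degree ordering; prediction-error variances (and the
individual accuracies √(1 − PEV/((1+F)σ²ₐ))) require the dense inverse of
the coefficient matrix and are intended for modest problems. The optional
PCG solver uses Jacobi preconditioning with relative tolerance 10⁻¹⁰ and
raises on non-convergence. Dosage arrays are kept int8 until the final
float conversion, and the full-population dosage matrix is never
materialised (only QTL columns and genotyped rows), which keeps memory
flat in the population size.

## Known limitations

Single-trait analyses only; no unknown-parent groups or metafounders; no
APY or other approximate inverses; no SNP weighting; no REML (variances
are inputs); the exact-test variant of the HWE filter and multiplicative
TG3 are noted as possible extensions.
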