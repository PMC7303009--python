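# Methods

This note documents the statistical models the package implements, the
generative model behind the synthetic data, the defaults and why they were
chosen, and the numerical conventions.  Nothing here states an empirical
result; the numbers the package produces come from the test suite and
`scripts/acceptance.py`.

## Two-sample MR model

The estimand is the causal effect θ of an exposure X on a binary outcome Y
(log odds of Y per unit of X), identified through J genetic variants used
as instrumental variables.  Inputs are per-variant summary associations:
β̂_Xj with standard error σ_Xj from an exposure GWAS, and β̂_Yj with σ_Yj
from an outcome GWAS in a non-overlapping sample.  Standard two-sample
assumptions apply: instruments are associated with the exposure,
independent of confounders, and (for IVW) affect the outcome only through
the exposure.  σ_Yj is treated as known (the NO Measurement Error
approximation), and IVW weights use σ_Y only; weak-instrument dilution is
therefore not corrected, which is why the synthetic defaults use strong
instruments (see below).

Estimators and their exact formulas are in the README and docstrings.
Conventions worth recording:

- **Effects model.** The default is multiplicative random effects: the
  fixed-effects SE is scaled by max(1, √(Q/d.f.)), never deflated below
  the fixed-effects value.  The point estimate is identical under both
  models; a `fixed` flag is exposed.  A consequence of the truncation at 1
  is that when there is no true heterogeneity the Egger slope CI (and the
  bootstrap-SE weighted median) run mildly conservative — null coverage a
  little above 97% rather than 95% — while under real heterogeneity the
  scaling engages and calibration is nominal; the property tests encode
  exactly this.
- **MR-Egger orientation.** Each variant is flipped so β̂_Xj ≥ 0 before
  the intercept regression (the Egger estimate is not invariant to allele
  coding; this is the standard convention).  The intercept is reported
  both raw and exponentiated, since published tables print intercepts as
  OR-scale values near 1.00.
- **Weighted median.** Ratio estimates are ordered; with normalized
  weights w′ the cumulative midpoints are p_j = Σ_{k≤j} w′_k − w′_j/2 and
  the estimate is the linear interpolation of θ̂_(j) at p = 0.5.  The SE is
  a parametric bootstrap (β̂_X, β̂_Y resampled from their reported normal
  sampling distributions), default 10,000 replicates, with a mandatory
  seed so results are reproducible.  Other weight normalizations and
  bootstrap flavours exist in the literature; this choice is documented
  rather than asserted as canonical.
- **Correlated instruments.** For cis-region analyses the GLS form uses
  the signed LD correlation ρ from a reference panel (σ-scaled weights,
  not p-value-derived).  ρ is eigenvalue-clipped at 1e-8 if indefinite
  (pairwise-complete estimation can produce this); a condition number of
  Ω above 1e8 after clipping raises an error advising pruning rather than
  returning an unstable estimate.
- **Minimum instrument counts.** Egger and the weighted median require
  J ≥ 3; IVW and ratio accept J = 1 (a single-variant exposure is routed
  to a per-allele report in the pipeline, not to IVW).
- **Odds-ratio reporting.** CI half-width uses z = 1.959964 hard-coded,
  so printed CI digits are bit-reproducible; p-values are two-sided normal
  tails of β/SE.

## Synthetic summary statistics

The generator draws, per variant: true instrument effects
β_Xj ~ N(0, s²) with s = `instrument_strength`; observed
β̂_Xj = β_Xj + ε_Xj, ε_Xj ~ N(0, σ_Xj²); and observed
β̂_Yj = θ·β_Xj + α_j + ε_Yj with ε_Y drawn jointly with covariance
σ_Yi σ_Yj ρ_ij under an exchangeable-or-matrix LD model.

**Pleiotropy is defined relative to the exposure-increasing allele**:
α_j = sign(β_Xj)·a_j with a_j ~ N(μ_α, σ_α²).  Under balanced pleiotropy
(μ_α = 0) this is distributionally identical to coding-independent
pleiotropy; under directional pleiotropy it makes μ_α a coding-invariant
quantity — every Wald ratio is biased upward by a_j/|β_Xj| regardless of
which allele a variant happens to be coded by, and the MR-Egger intercept
(which re-orients variants internally) targets exactly μ_α.  Defining α on
the raw coding instead would let the estimators' re-orientation cancel the
directional component, making "directional pleiotropy" unobservable by
construction.  Violation of the InSIDE assumption is controlled
explicitly: a_j = μ_α + ρ_I·σ_α·standardize(|β_Xj|) + √(1−ρ_I²)·σ_α·z_j,
correlating pleiotropy with instrument *strength* |β_X|.

**Defaults are chosen to emulate the triglycerides analysis scale**: 51
variants; instrument effects with SD 0.05 per exposure SD; σ_X = 0.004
(the order implied by a quantitative-trait GWAS of ~190,000 samples);
σ_Y = 0.013 (the order implied by a binary-outcome GWAS with ~15,000 cases
in ~368,000 individuals).  These put the IVW standard error near 0.037 and
the mean instrument F-statistic in the hundreds, so weak-instrument
dilution is negligible relative to Monte-Carlo error.  They were fixed
from these design facts, once.

All randomness flows from a single seed through named SeedSequence
substreams (instrument effects, pleiotropy, exposure noise, outcome
noise), so output is bit-reproducible and adding a stream cannot perturb
existing ones.

## Synthetic cohort

Genotypes are Binomial(2, f_v) draws (allele frequencies Uniform(0.1, 0.9)
unless supplied); the risk score is the weighted dosage sum standardized
to sample mean 0, SD 1.  Depression is drawn from
logit P = logit(base rate) + θ_GRS·score + θ_FH·famhist, with base rate
4%, so the base rate is the prevalence at score 0 without family history
(and the marginal prevalence when both effects are zero).  Cases are split
severe vs moderate with probability 6228/14701 ≈ 0.424, the proportion in
the emulated cohort.  Sex is drawn at 45.9% male.

Questionnaire answers are generated *after* the phenotype, consistently
with it: cases receive answers satisfying every criterion of their level
(severe cases answer yes to the psychiatrist item; moderate cases yes to
the GP item and no to the psychiatrist item), controls fail at least one
criterion chosen uniformly among the four.  The phenotype classifier
therefore re-derives the drawn status exactly — by design, so that
classifier → counting → prevalence arithmetic can be exercised at scale.

**What the generator does not emulate**: realistic LD from haplotypes
(LD is exchangeable or user-supplied), ascertainment or participation
bias, genotyping error, population structure (PCs computed on random
genotypes are pure noise, so PC adjustment is exercised mechanically, not
substantively), item non-response patterns, and exposure–outcome sample
overlap.  Passing tests show the estimators have the advertised
frequentist behaviour *under the generative model*, not that any
real-data finding is correct.

## Phenotype and QC conventions

- Probable moderate lifetime major depression requires: a week of low
  mood or anhedonia; longest episode ≥ 2 weeks; ≥ 2 episodes; and having
  seen a GP for nerves/anxiety/tension/depression.  Severe replaces the
  GP criterion with the psychiatrist item.  Severe takes precedence when
  both professional-contact items are yes, so the two levels are disjoint
  and sum to the total case count.
- Missing answers resolve to "criterion not met" (control), a
  conservative toward-the-null convention for a "probable" phenotype.
- HWE uses the 1-d.f. chi-square goodness-of-fit test; the thresholds
  applied (1e-6 common / 1e-12 rare at MAF 0.01) are extreme enough that
  the asymptotic test suffices at simulated sizes — an exact test would
  matter only at very small counts (documented limitation).  Monomorphic
  variants return p = 1 (no departure testable).
- Variant/individual call-rate filters are one-sided (low tail) at
  mean − 3 SD; heterozygosity is two-sided.  QC order is fixed: variant
  filters, then individual filters (statistics recomputed on retained
  variants), then relatedness pruning, which keeps the lexicographically
  smallest ID of each kinship-connected component — a deterministic
  tie-break so QC is reproducible and order-invariant.

## Association analyses

Logistic fits use IRLS with tolerance 1e-8 on the relative log-likelihood
change, at most 25 iterations; Wald SEs from the inverse observed
information.  Complete separation (all fitted probabilities numerically
0/1) is flagged and the fit marked non-converged rather than reporting
diverging coefficients; rank-deficient designs raise an error naming the
collinear column.  The risk score is standardized on the full analysis
sample; sex-stratified fits reuse that standardization so per-SD units are
comparable across strata.  PC adjustment is the default for both the
per-variant scan and the GRS model (the GRS model can be run unadjusted
via a flag).  Missing dosages are mean-imputed (2×EAF) before scoring —
deterministic and standard for risk scores.

## Instrument selection

Candidates are filtered to p ≤ 5e-8 (and an optional region), then pruned
greedily by ascending p-value with variant-ID tie-break, dropping any
variant with r² strictly above the ceiling (default 0.6, the convention
for cis sets) against an already retained one.  Published variant lists
do not record a pruning order; this rule is a reproducible stand-in, and
the strict inequality at the boundary is tested.

## Pipeline

Method routing: polygenic exposures get IVW + MR-Egger + weighted median;
cis exposures with ≥ 2 variants get the correlation-adjusted IVW from
their panel; single-variant exposures are reported per allele;
multivariable groups (the lipid-panel design) run the joint model over
shared variants.  Multiplicity uses Bonferroni with m = 15 exposures by
default (α/m = 0.003, reported both exactly and at the one-significant-
figure rounding used in prose).  Rendered tables print ORs to two
decimals, CIs in parentheses with an en-dash, and p-values at two
significant figures down to 0.001, one below that, scientific notation
below 1e-4; the TSV keeps full precision, and a test asserts the rendered
and full-precision values agree under these rules.  Per-exposure failures
abort that exposure with a logged reason, never the run.  The
weighted-median bootstrap seed for each exposure is derived
deterministically from the plan seed and the exposure label (CRC32), so
identical plan + seed reproduce byte-identical reports.

## Problem sizes used in verification

Monte-Carlo suites use 1000 replicates for IVW recovery/coverage and for
the Egger intercept's type-I error and power, 300 replicates of n = 20,000
cohorts for risk-score coverage in the unit suite, and 200 replicates of
n = 50,000 cohorts in the acceptance script — sizes at which Monte-Carlo
standard errors are small relative to the tolerances being checked while
the full verification run stays in the minutes range on one CPU.

## Known limitations

- No weak-instrument (NOME-violation) correction in IVW/Egger; no I²_GX
  diagnostic.
- No MR-PRESSO outlier removal, mode-based estimators, Steiger filtering
  or bidirectional analyses.
- Harmonization matches variants by ID only (no positional matching,
  liftover or proxy lookup).
- Palindromic variants are resolved by allele frequency only below the
  ambiguity ceiling (minor-allele frequency 0.42); above it, or with
  missing frequencies, they are dropped.
- The cohort generator's logistic model is the same family the analysis
  fits, so cohort recovery tests check calibration of the machinery, not
  robustness to model misspecification.
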