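# Methods

## Variant selection

Candidates are GWAS summary-statistic rows for BDR to albuterol. Two filters
are applied in sequence: association strength (p < 0.001, strict inequality,
matching the discovery convention) and functional prioritization
(PHRED-scaled CADD ≥ 10, inclusive — CADD 10 marks the top 10% most
deleterious possible substitutions, and a variant exactly at 10 is kept).
Variants without a CADD annotation fail the filter: the design assumes all
candidates were annotated, so an unannotated row is treated conservatively
rather than given the benefit of the doubt. The selection output is ordered
by descending CADD score (ties broken by chromosome and position) because
prioritization by annotation, not by p-value rank, is the point of the
design; the ordering carries no weight in scoring. Both thresholds are
configurable so sensitivity to the cut-points is a one-flag change.

## Dosage harmonization

Scoring needs effect-allele counts, which are not the same as VCF ALT
counts. The rule set, in order: ALT equals the effect allele → dosage is the
ALT count; REF equals it → dosage is 2 − ALT count; otherwise, for
non-palindromic variants only, the reverse complement of the effect allele
is tried the same way. Palindromic (A/T, C/G) variants must match literally:
strand cannot be resolved from the alleles, and frequency-based
disambiguation was rejected as unauditable on a 16-variant score. Variants
are matched by rsID first with a (chromosome, position) fallback, because
discovery-build coordinates need not match the target cohort's build while
rsIDs are stable. Missing genotypes are mean-imputed (2 × the effect-allele
frequency among observed calls), which preserves the per-variant mean
dosage exactly and keeps every individual; the missingness mask is retained
for reporting. Multiallelic records at scoring variants are an error, not a
silent split.

## Score and standardization

The raw score is the weighted dosage sum over the 16 variants in weight-
table order (no compensated summation — at 16 terms the rounding error is
orders of magnitude below any tolerance used). Models use the in-sample
z-score with the n−1 standard deviation; "per SD" therefore means per SD of
the score in the analyzed cohort, the only standardization consistent with
a single-cohort analysis. Degenerate inputs error loudly: fewer than two
individuals, or raw scores constant up to float rounding (detected with a
relative 1e-12 floor).

## Association models

All models share one fixed design: intercept, PRS z-score, age (years,
continuous), male indicator, three BMI indicators (underweight, overweight,
obese; normal — the largest class at 65% — is the reference), doctor visits
(untransformed count), and six genotype PCs. Linear models are OLS; binary
responder models (BDR ≥ 12%, and ≥ 8%; both cuts inclusive) are
maximum-likelihood logistic fits via Newton iterations (tolerance 1e-8, cap
100 iterations). Inference is Wald throughout: estimate ± 1.959964 × SE,
exponentiated onto the odds-ratio scale for logistic models, so the CI is
symmetric on the log-odds scale by construction. Separation is never
reported as a huge OR: a perfect-separation signal from the optimizer, or
any coefficient beyond |50|, raises an error. Interaction tests add
modifier × PRS product terms and report the Wald p-value — joint, via the
chi-square Wald statistic, for the three BMI product terms. A p ≤ 0.10
descriptor is used only for flagging in the text report; the raw p-value is
always returned. No multiple-testing correction is applied across the three
primary models, mirroring standard practice for a small set of
pre-specified analyses. Rank-deficient designs error with the names of the
collinear columns (found by pivoted QR).

## Synthetic cohort generator

The generator is the test bed: it produces cohorts whose *population*
parameters equal the published study statistics, so pipeline estimates can
be validated against known injected truths.

**Genotypes.** Dosages are Binomial(2, p_j), independent across the 16
variants and individuals (HWE and linkage equilibrium; the variants sit on
13 different chromosomes, so LD is negligible by design). The frequencies
p_j are not published, so they are solved from the two raw-PRS moment
equations — Σ 2p_jβ_j = 3.84 and Σ 2p_j(1−p_j)β_j² = 7.41² — by bounded
least squares (all p_j started at 0.3, constrained to [0.01, 0.99],
tolerance 1e-6 on both moments). The system is underdetermined (16 unknowns,
2 equations); the fixed start makes the solution deterministic, and only the
moments, not the individual frequencies, are treated as meaningful.
Feasibility is checked in closed form first (target mean within
[2Σ_{β<0}β, 2Σ_{β>0}β] = [−35.02, 78.14]; target variance at most
Σβ²/2 = 104.52).

**Outcome, continuous mode.** BDR_i = effect_per_sd · z_i + ε_i with
effect_per_sd = −0.63 by default and z the in-sample z-scored PRS. A single
normal ε cannot reproduce the published marginals: a normal with mean 5.6
and SD 10.2 puts ≈26.5% of mass above 12 and ≈40.7% above 8, against the
observed 17.2% (166/967) and 28.4% (275/967) — the observed BDR
distribution is right-skewed. The noise is therefore a two-component
Gaussian mixture, the minimal 5-parameter family that can match all four
functionals (mean, SD, and the two exceedances, computed on the marginal
including the PRS term). The five parameters are solved by bounded least
squares on relative errors from a fixed start (sum of squared relative
errors < 1e-6; a zero target falls back to absolute error). Exceedance
targets use the exact fractions 166/967 and 275/967 rather than the rounded
percentages.

**Outcome, threshold-logistic mode.** Responder_i ~
Bernoulli(expit(α + log(OR)·z_i)) with OR = 0.80 per SD by default and α
solved by quadrature + root-finding so the marginal prevalence over a
standard-normal PRS equals the target (166/967 at 12%, 275/967 at 8%). This
mode makes the logistic model exactly correctly specified, so OR recovery
is a clean estimator check.

**Covariates.** Age ~ N(9.3, 1.9²) truncated to the 6–14 y recruitment
window (truncation shifts the realized mean to ≈9.44; the stated location
parameter is kept, since age carries no effect on the outcome); sex male
with probability 0.59; BMI categorical (0.65, 0.03, 0.15, 0.17 for
normal/under/over/obese); doctor visits negative binomial with dispersion
and mean grid-searched (step 0.05, fixed scan order) to hit median 3 and
quartiles (1, 5) exactly; PCs six iid standard normals. Covariates have
zero true effect on BDR by default — no covariate coefficients were
published, and zero effects keep injected-PRS recovery unbiased.

**Determinism.** One master seed is expanded into per-stage child seeds
(stream order: genotypes, covariates, outcome), so identical configs
produce byte-identical VCF/CSV/JSON outputs. Generated VCFs store the
effect allele as ALT over a non-palindromic transition REF, so re-reading
them through the harmonizer reproduces the simulated dosages exactly.

## What the simulations do and do not show

Passing recovery tests shows the pipeline is an unbiased, correctly
calibrated estimator *under this generative model*: HWE, linkage
equilibrium, no population structure or relatedness (the founder-population
structure of the real cohort is deliberately not modelled), covariates
independent of genotype, and outcomes generated from the fitted model
family. They do not validate the scientific association in real data, nor
robustness to confounding, genotyping error or LD between scoring variants.

## Problem sizes and tolerances

Recovery experiments use 200 cohorts (linear) and 500 per threshold
(logistic) at the study's n = 967, judged within 3 Monte-Carlo standard
errors; marginal calibration checks use single draws of n = 100 000, with
the SD's MC-SE computed by the delta method from the empirical fourth
moment (the mixture is non-normal). Exact worked examples (single-allele
score 5.36; all-effect homozygote 2Σβ = 43.12) are asserted to float
precision. Null calibration of interaction tests uses 300 replicates at
n = 400 with a Kolmogorov–Smirnov check at α = 0.01. These sizes were
chosen so each statistical check has 3-MC-SE resolution well below the
effect being verified.

## Known limitations

* Allele frequencies matching the PRS moments are non-unique; only the
  moments are calibrated.
* The mixture noise is a convenience family: it matches four functionals of
  the unpublished BDR distribution, not its full shape.
* `compute_pcs` is a small SVD utility for simulated panels; real ancestry
  adjustment needs genome-wide PCs supplied as covariates.
* Continuous-mode logistic fits (dichotomizing a continuous simulated BDR)
  are slightly misspecified relative to the logistic data-generating
  process; the threshold-logistic mode exists precisely to check OR
  recovery under correct specification.
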