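# Methods

`pleioscan` implements a cross-trait pleiotropy analysis between nicotine
dependence (ND) and respiratory outcomes (lung function and COPD), built
around four statistics — a polygenic-score mediation contrast, threshold-
stratified SNP-overlap enrichment with effect-direction concordance,
conditional QQ data, and five-hypothesis colocalization — plus a synthetic
data generator that supplies cohorts and GWAS summary statistics with the
structure these statistics assume. This note records the models, the
parameters that matter, and the design decisions taken where the design
was genuinely open.

## The two pleiotropy models

A variant associated with both smoking behaviour and lung function (LF)
can act through two mechanisms:

* **causal pleiotropy** — variant → smoking behaviour → LF decline.
  Conditioning on smoking phenotypes removes the variant–LF association.
* **independent pleiotropy** — the variant affects smoking and LF through
  separate paths. The association survives smoking adjustment.

The discriminating quantity is the attenuation ratio
`beta_adjusted / beta_crude` of a PGS–outcome regression: near 0 under the
causal model (with the mediator observed), near 1 under the independent
model.

## Synthetic data generator

### Reference panel

Haplotypes are drawn from a one-factor Gaussian copula per LD block:
latent `L = sqrt(rho)*common + sqrt(1-rho)*noise`, allele = 1 when
`L < Phi^-1(MAF)`. Thresholding attenuates correlation, so the latent
`rho` is calibrated by root finding (bivariate normal rectangle
probability at the panel's mean MAF) to hit the requested correlation on
the 0/1 haplotype scale; a two-variant block at target 0.9 lands within
±0.05 empirically at 50,000 haplotypes. Blocks are mutually independent
and separated by 10 Mb so clumping windows (default 250 kb) never straddle
blocks. Variant MAFs are uniform on the spec range (default 0.05–0.5);
allele pairs are drawn from the non-palindromic ordered ACGT pairs so the
generator's own summary statistics survive the strand-ambiguity drop rule.
Cohort dosages are formed by pairing panel haplotypes with replacement
(hard 0/1/2 genotypes; imputation uncertainty is not modelled).

### Cohort model

ND liability = sum of per-allele effects over `n_nd_causal` variants
(default 20) plus standard normal noise. Effects are `±nd_effect_sd`
(default 0.3) with Rademacher signs rather than Gaussian draws, so every
causal variant genuinely carries signal — this keeps per-variant recovery
tests meaningful. The causal set and effect signs are drawn from a
dedicated `architecture_seed` so that cohorts differing only in `seed`
(e.g. a PGS training cohort and a target cohort) share the same genetic
architecture, as two samples from one population would.

Smoking phenotypes derive from the liability `L`:

* ever smoked ~ Bernoulli(logit⁻¹(0.5 + 0.8·L)) (≈60% smokers at L = 0,
  matching the smoking-enriched cohorts this emulates);
* cigarettes/day = max(0, round(10 + 5·L)) among ever-smokers, else 0;
* former vs current (among ever-smokers) ~ Bernoulli(logit⁻¹(0.2 − 0.4·L)):
  higher ND liability lowers the cessation probability;
* log onset age = ln 18 − 0.05·L + noise; smoking duration = age − onset −
  (years since quitting, uniform 1–15 y for former smokers), floored at 0.

Lung function receives the signal `lf = gamma·packs + D` where
`packs = cpd/10` and `gamma` (`smoking_effect_on_lf`, default −0.5 LF
units per pack/day) is the *only* genotype→LF path under the causal model.
Under the independent model, `D` adds direct per-allele effects on the
ND-causal set with effect `-(direct_lf_effect_sd/nd_effect_sd)·beta_ND`:
the allele raising smoking quantity lowers lung function directly, the
divergent-direction pattern reported at loci like 15q25.1. The default
`direct_lf_effect_sd = 0.6` (twice the ND scale) makes the direct path
dominate the mediated one — the regime in which crude and smoking-adjusted
associations are "little changed", which is precisely the phenomenon the
independent scenario exists to exhibit. FVC and FEV1 are built on litre-ish
scales (FVC ≈ 3.8 L + sex/age terms + 0.6·lf; FEV1 ≈ 0.75·FVC + 0.4·lf),
with the ratio clipped into (0, 1.45]. COPD liability is
`-gamma·packs − D + noise`, thresholded at the `copd_liability_threshold`
quantile (default 0.70, i.e. 30% cases, a case-enriched design); COPD
status is therefore a label derived from a liability threshold, not from
spirometric cutoffs.

### Per-SNP GWAS

Quantitative traits use exact OLS via Frisch–Waugh–Lovell residualization
(vectorized across variants; identical to per-variant full-model OLS,
with t p-values). Binary traits use per-variant logistic regression
(statsmodels GLM, Wald tests). Smoking-quantity, onset and cessation
traits are analysed within ever-smokers, as in smoking-behaviour GWAS.
Monomorphic or covariate-collinear variants are emitted with NaN results
and a `monomorphic` status flag, never silently dropped.

## Harmonization

Records are aligned to the panel's counted allele: exact match kept;
effect/other swap flips `beta` and complements `eaf`; reverse-complement
matches are strand-flipped first; palindromic (A/T, C/G) records are
dropped outright — with no reference frequencies there is no reliable way
to orient them, and no frequency-based disambiguation rule is attempted.
Every action is tallied, and `kept + dropped = input` exactly. Tables are
joined on variant id (rsID); positional fallback is out of scope. The
genome build is carried as a label (`hg19`) with no liftover.

## Polygenic scores and the mediation contrast

Clumping is greedy and p-value-ordered: visit variants by ascending p
(ties broken by position then id for determinism); retain a variant iff
its panel r² with every retained variant within the window is below the
threshold. Defaults r² < 0.2 within 250 kb are conventional clumping
settings; both are exposed. Scores are raw weighted dosage sums (training
betas per effect-allele copy); model variants missing from a cohort
contribute zero and are counted — no mean imputation, no standardization
(coefficients are per raw score unit; a binary outcome gives a log odds
ratio). The mediation contrast fits crude and adjusted models on the
identical subject set (listwise deletion over the covariate union first)
and reports `beta_adjusted/beta_crude` per adjusted covariate set.

A note on attainable ratios: even with the mediator fully observed, the
independent-model ratio sits slightly below its population value (~0.9
rather than ~0.95 in the default scenario) because the estimated PGS
measures the true genetic component with error, and conditioning on the
mediator removes proportionally more signal variance than noise variance.
This is a property of PGS mediation analysis generally, not of this
implementation.

## Overlap enrichment and direction concordance

For a p threshold t, `n_a` and `n_b` count variants at p ≤ t (boundary
inclusive) in each trait over the shared-variant universe of size
`n_total` (the paired table — the only universe for which the chance
expectation `n_a·n_b/n_total` is internally consistent); the enrichment
fold is `n_overlap / expected`, reported as missing when the expectation
is 0. Direction is the sign product of the aligned betas: positive =
consistent (the LF-raising allele also raises the ND trait), negative =
divergent. Zero betas stay in the overlap count but are excluded (and
tallied) from direction counts. The divergent proportion is tested with
an exact two-sided binomial test against 0.5 (minimum-likelihood
two-sided definition, as in R's `binom.test`). Stratified runs restrict
selections *and* universe to one sign class, so within-stratum folds
compare to within-stratum chance.

## Conditional QQ

For each conditioning threshold t, the subset is the shared variants with
conditioning p ≤ t; observed values are sorted −log10 primary p-values
against uniform midpoint quantiles `-log10((i-0.5)/m)`. Null calibration
is checked with a Kolmogorov–Smirnov band: the acceptance check uses a
99% band and requires ≥95% of null runs inside it (a 95% band would by
construction exclude ~5% of null runs, making the pass criterion a coin
flip at 100 runs).

## Colocalization

Per shared variant and trait, the Wakefield approximate Bayes factor is
`log ABF = 0.5·(ln(1-r) + r·z²)` with `r = W/(se² + W)`; prior effect SD
0.15 for quantitative traits and 0.2 (log-odds) for binary traits, priors
p1 = p2 = 1e-4, p12 = 1e-5 (the conventional defaults; all exposed).
Hypothesis weights accumulate in log space with max-shift stabilization;
the H3 (two distinct causal variants) term is
`log(exp(S1+S2) − exp(S12))`, exactly −inf for a single-variant region
and clamped with a warning if rounding drives it negative. One causal
variant per trait per region is assumed; no conditioning/masking
extensions, no se reconstruction from allele frequency and N (betas and
ses are required inputs).

## What the generator does and does not emulate

It reproduces: block LD with tunable r², sparse causal architecture,
liability-threshold case/control outcomes, smoking-mediated vs direct
pleiotropy, smoker-only trait definitions, and GWAS summary statistics
with correct sampling noise. It does not reproduce: realistic human LD
maps, imputation quality variation, population stratification, sex
chromosomes, or confounding between covariates and genotype. Passing
tests therefore demonstrate correctness of the statistics and the
qualitative discriminability of the two pleiotropy mechanisms, not
performance on real GWAS data.

## Problem sizes and numerical choices

Simulation-backed checks run at 20,000 subjects per cohort with 60-variant
panels (mediation; 50 replicate cohort pairs) and 150-variant regions
(colocalization; 50 replicates per scenario), 50,000-variant null
summary-stat pairs (enrichment calibration; 100–200 replicates), and
5,000-variant null pairs (QQ calibration; 100 runs) — sizes at which the
target quantities' sampling error is well inside the asserted bands. At
the 1e-3 threshold the null-enrichment fold has an irreducible Poisson
sampling SD of ~0.3 even pooled over 200 replicates of 50,000 variants
(pooled expected overlap ≈ 10), so the calibration assertion uses a
3-sigma band there and the ±0.1 band at 1e-2/1e-1 where the estimator SD
is below 0.035. Ties in clumping are broken deterministically; all
randomness flows from explicit integer seeds; posterior vectors are
renormalized after exponentiation and sum to 1 within 1e-6.

## Known limitations

* Logistic per-variant GWAS is a Python loop; scans of binary traits over
  very many variants are slow compared to the vectorized linear path.
* Palindromic variants are always dropped; studies whose signal sits on
  ambiguous SNPs lose it at harmonization.
* The join is rsID-based; datasets with positional ids must be mapped
  before harmonization.
* Published divergent-direction binomial p-values in the source tables do
  not match a standard exact test against 0.5 (their construction is not
  stated); this package's binomial p-values are therefore validated
  against an exact enumeration oracle, not against those published values.
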