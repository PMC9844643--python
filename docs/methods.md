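# Methods

## Scope and model

`gipm` estimates the separate and joint association of metabolic syndrome
(MetS) and a composite polygenic score with incident gastrointestinal
cancer in a prospective cohort, under Cox proportional hazards on the
follow-up time scale (years since baseline). Age-as-timescale is not
used. Adjustment is tiered:

* Model 1: age group, sex, qualification, Townsend deprivation index,
  family history of cancer;
* Model 2: Model 1 + smoking, alcohol, physical activity, fruit,
  vegetables, red/processed meat, aspirin/ibuprofen use;
* genetic models additionally adjust for 10 genetic principal components.

Categorical covariates are dummy-coded against fixed reference levels
(non-MetS; 0 components; low genetic category; the (low, no-MetS) joint
cell). Hazard ratios are `exp(β)` with Wald 95% CIs `exp(β ± 1.96·SE)`.

## Synthetic cohort generator

The generator is the package's substitute for access-controlled biobank
data. It reproduces the *statistical structure* the analysis assumes, not
any real cohort's joint distribution.

**Genotypes.** Each of the 106 panel variants (13 esophageal, 3 gastric,
90 colorectal; no variant shared between sites, no LD by default) draws
dosages Binomial(2, MAF) — Hardy–Weinberg, independent across variants
and of everything metabolic. Effect sizes have random sign and magnitude
uniform on [0.05, 0.3]; MAFs uniform on [0.05, 0.5].

**Metabolic components.** Five latent standard Gaussians with an
equicorrelated correlation matrix (ρ = 0.3 by default; any valid 5×5
matrix accepted) are thresholded at `c_j = Φ⁻¹(1 − p_j)` so each
component flag has its target marginal prevalence. The continuous
measurements are linear transforms of the latents anchored at the
classifier cutoffs (triglycerides log-linear, so they stay positive;
floors far below the cutoffs guard the remaining measurements), which
makes classification of the generated table reproduce the latent flags
*exactly*. Diastolic pressure is a deterministic linear map of systolic
pressure crossing 85 mmHg exactly at SBP = 130, so the either-pressure
hypertension criterion reduces to one latent threshold; generated DBP
means therefore do not match real-cohort descriptives — a deliberate
trade of marginal realism for exact calibration.

Default marginal prevalences (obesity 0.32, hypertension 0.5485,
hypertriglyceridemia 0.42, low HDL 0.22, hyperglycemia 0.15) were fixed
once by numerical quadrature of the one-factor copula so that
P(≥3 flags) = 0.2558, the cohort-level MetS prevalence the scenario
emulates. The real-data correlation structure among components is not
published; ρ = 0.3 is a stated assumption (metabolic traits cluster),
not an estimate, and is configurable.

**Covariates.** Categorical covariates draw from fixed marginals chosen
to be plausible for a 40–69-year-old European cohort; Townsend is
Gaussian; PCs are standard normal. All are independent of genotypes and
of the metabolic latents, so covariate adjustment is exercised without
confounding. Confounding scenarios are opt-in through planted covariate
effects (`planted_loghr` accepts any numeric column or
`column:level` indicator).

**Outcomes.** Event times are exponential with individual hazard
`λ₀ · exp(η)` and administrative censoring (single date at 10.9 years by
default; a multi-date scheme mimicking per-country registry end dates is
configurable). The exponential choice gives closed-form oracles: the
crude rate ratio between groups equals the planted hazard ratio, which
the tests exploit. Events receive a site label by the configured mix
(0.142/0.094/0.765). λ₀ = 9.9503×10⁻⁴ per person-year was calibrated
once so the default scenario's crude event fraction is 1.278%
(≈ 5,494/430,036).

**Planted effects.** The default linear predictor is

```
η = log(1.12)·[1–2 comps] + log(1.41)·[≥3 comps]
  + log(1.35)·z + g(category)
```

with `z` the standardized composite score. The published estimates are
mutually constrained (the binary MetS contrast and the component-band
contrasts use different references; a single log-linear score effect
cannot reproduce both the per-SD and the quintile-category contrasts
exactly), so the generator plants the band contrasts directly and adds
small category-level offsets `g` — computed from the empirical
within-category means of `exp(βz)` — so the *category-model estimands*
equal their targets (1.46 intermediate, 2.28 high vs low) exactly while
the per-SD estimand stays ≈ 1.35. The implied binary-MetS estimand is
1.41 / mix(1, 1.12) ≈ 1.299, and the implied (high, MetS) joint-cell
estimand under the default multiplicative model is ≈ 2.96; no interaction
is planted by default (sub- or super-multiplicative scenarios are opt-in
via `interaction_mets_x_*` terms).

**Eligibility and missingness.** By default every exclusion rate and the
missingness rate are zero: the scenario emulates the post-eligibility
analysis cohort, and nonzero missingness would flip component flags after
median imputation, breaking the exact prevalence calibration. Both are
opt-in stressors; the eligibility cascade itself always runs (its only
default effect is removing first-year events, which leaves partial-
likelihood estimands untouched because those subjects would have exited
every later risk set anyway).

**Seeding.** One global seed expands into per-stage child streams via
`SeedSequence((seed, stage_code))` with fixed stage codes, so panels,
genotypes, phenotypes, outcomes, missingness and bootstraps are
independently reproducible.

## MetS classification

NCEP-ATP III with ≥3 of 5 components. Boundary conventions: `≥` for
triglycerides (1.7 mmol/L), blood pressure (130/85 mmHg) and HbA1c
(42 mmol/mol, the fasting-glucose surrogate); strict `>` for waist
(102/88 cm by sex) and BMI (30 kg/m², the alternative obesity mode).
Whether the original analysis counted medication use toward the
hypertension/dyslipidemia/hyperglycemia flags is not stated in its main
text; medication qualification is therefore implemented but off by
default, and every cutoff is configurable so exact criteria tables can be
dropped in. Imputation is sex-specific-median for continuous fields with
raw copies retained, and an explicit `missing` level for refused or
unknown categorical answers; it is idempotent.

## Polygenic score pipeline

Filters follow the published thresholds exactly: keep p < 5×10⁻⁸ and
MAF ≥ 0.01; substitute an absent variant by its best available proxy iff
r² > 0.8 (strict), ties by smallest position; fail on |MAF difference|
> 0.10, irreconcilable alleles, or palindromic (A/T, G/C) alleles with
MAF ≥ 0.45; clump greedily within site at r² ≥ 0.2, index = smallest p,
ties by position. Missing LD entries mean r² = 0 with a lenient default
and a strict mode that raises. An effect/other allele swap negates β and
flips the frequency so scores are always on the harmonized
effect-allele scale. Every variant ends in exactly one terminal status
(`pass`, `proxy:<id>`, `fail:<reason>`), so harmonization reports always
sum to the input count.

Quintiles are computed on the post-eligibility analysis cohort (the
ordering of exclusion vs quantile computation is not specified in the
source analysis); values equal to a cut point go to the lower quintile.
The incidence weights are required configuration; the shipped defaults
(ESC 14, GC 11, CRC 70 per 100,000 person-years) are order-of-magnitude
stand-ins for UK age-standardized rates, and nothing in the test suite
depends on their absolute values — only on the weighting mechanics and
the invariance of the standardized score to weight rescaling.

## Estimation and diagnostics

The Cox engine is `statsmodels` PHReg (Efron ties default, Breslow
available); `lifelines` serves as an independent cross-check in the test
suite, together with a brute-force partial-likelihood oracle on ≤8-subject
data (agreement to 1e-4), the Efron/Breslow no-ties identity (1e-10) and
time-rescaling invariance (1e-8). Designs are checked for rank and for
zero-event exposure strata before fitting; non-convergence is flagged.

The proportional-hazards test is the Grambsch–Therneau statistic on
Schoenfeld residuals with identity time transform by default (rank, KM
and log transforms available); per-term p-values match
`lifelines.proportional_hazard_test` to 1e-6 and the global statistic
uses the joint quadratic form.

The interaction test enters MetS × genetic-category product terms
(2-df joint Wald) in the fully adjusted model; a 1-df continuous
MetS × z variant is offered because the original parameterization is not
stated. Trend tests enter the ordinal band as a single score. The
restricted cubic spline uses the Harrell basis with 4 knots at the
5/35/65/95th percentiles (count and placement configurable; unstated in
the source), reference at the median score. Subgroup heterogeneity is
summarized by an exposure × stratifier joint Wald test.

## Risk translation

Five-year absolute risk is crude cumulative incidence — events within 5
years over baseline stratum size, per mille — matching the source's
"percentage of incident cases" phrasing; a Kaplan–Meier mode is provided
for settings with material early censoring (negligible here). The
absolute risk increase is the exact difference of the two per-mille
risks, and the number of exposed subjects per additional case is
`round(1000/ARI)` computed from the *unrounded* ARI. (Computing it from
the rounded printed risks of the low stratum gives 671 where the source
prints 669 — the reciprocal-of-rounded-inputs discrepancy is documented,
not hidden; the intermediate stratum's 364 is exact either way.)
Bootstrap CIs are percentile-method over participant resamples (B = 1000
by default, BCa behind a flag; the method is unstated in the source).
Direct standardization uses the whole-cohort age-group × sex person-year
distribution (the standardization variables of the source figures are
unstated; configurable).

## Problem sizes used in the tests

Simulation-backed checks are scaled to hold the full suite to a few
minutes: headline parameter recovery pools five cohorts of 200,000
(the size named by the scenario's recovery criteria); null calibration
uses 220 replicates of n = 2,500 with the baseline hazard raised to
2×10⁻² py⁻¹ (≈ 490 events each); planted-effect recovery uses 10 seeds
of n = 15,000; prevalence calibration uses one cohort of 150,000
(Monte-Carlo SE 0.11 pp against a ±0.5 pp band); the score-independence
check uses 12 cohorts of 30,000. Smoke tests of the full pipeline run at
n = 6,000 with a tenfold baseline hazard.

## What passing tests do and do not show

The generator matches the analysis assumptions by construction —
proportional hazards, hazard multiplicativity, component-flag exactness,
genotype–metabolic independence and no confounding. Green tests
therefore demonstrate that the *estimators and pipeline plumbing* are
correct and calibrated, not that real cohort data satisfy those
assumptions: real data carry measurement error, medication effects on
measured components, genotype–covariate correlation through population
structure, relatedness, informative censoring and non-proportional
hazards, none of which the default scenario emulates. The unrelated-
subset sensitivity analysis uses a simple "has a relative" flag rather
than a kinship network, and no competing-risks or time-varying-covariate
machinery is provided.
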