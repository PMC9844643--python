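# gipm

Joint metabolic-syndrome and polygenic-risk analysis of gastrointestinal
(GI) cancer in prospective survival cohorts.

## The problem

Esophageal (ICD-10 C15), gastric (C16) and colorectal (C18–C20) cancers
share both lifestyle-linked metabolic risk factors and common germline
susceptibility loci. Two measurable summary exposures capture these:

* **Metabolic syndrome (MetS)** — carrying ≥3 of 5 components (central
  obesity, hypertension, hypertriglyceridemia, low HDL, hyperglycemia)
  under the NCEP-ATP III definition, with HbA1c ≥ 42 mmol/mol standing in
  for fasting glucose;
* **a composite GI polygenic risk score (GI-PRS)** — site-specific PRSs
  (dosage-weighted sums of GWAS effect sizes,
  `PRS_i = Σ_j d_ij β_j`) combined with weights proportional to each
  site's age-standardized incidence rate, then standardized per SD and
  banded into low (bottom quintile) / intermediate (quintiles 2–4) /
  high (top quintile) genetic risk.

`gipm` implements the full analysis chain for epidemiologists who want to
estimate the separate and joint effects of these two exposures:
GWAS summary-statistic harmonization (p < 5×10⁻⁸, MAF ≥ 0.01, proxy
substitution at r² > 0.8, allele/frequency/palindrome QC, LD clumping at
r² < 0.2), eligibility filtering and sex-specific median imputation,
Cox proportional-hazards models under a two-tier covariate adjustment
(`HR = exp(β)` from the partial likelihood, Efron ties), Schoenfeld-residual
proportionality diagnostics, interaction and trend tests, restricted cubic
spline dose–response, and translation into 5-year absolute risks (‰),
absolute risk increases, and numbers of exposed subjects per additional
case, with 1000-resample bootstrap CIs.

Because individual-level biobank data are access-controlled, the package
ships a first-class **synthetic cohort generator** that reproduces the
statistical structure the analysis assumes — Hardy–Weinberg genotypes for
a 106-variant panel (13/3/90 per site), a latent-Gaussian copula for the
five correlated metabolic components calibrated to 25.58% MetS prevalence,
and exponential proportional-hazards outcomes with planted hazard ratios —
so every stage is testable end to end without any data download.

## Worked example

```python
from gipm import pipeline

doc = {"scenario": {"n_participants": 50_000, "seed": 1},
       "analysis": {"bootstrap_B": 200}}
pipeline.run_full_analysis(doc, "out/", seed=1)
print(open("out/summary.txt").read())
```

```
Joint metabolic-genetic GI cancer risk analysis
================================================
analysis cohort: n=49,933, events=596
MetS prevalence: 0.2575
MetS HR (Model 2): 1.27 (1.07, 1.51)
high vs low genetic risk: HR 1.96 (1.52, 2.53)
per-SD GI-PRS: HR 1.29 (1.19, 1.40)
high genetic + MetS vs low + no MetS: HR 2.31 (1.59, 3.37)
         low genetic risk: ARI5 1.80 per mille, subjects per extra case 555
intermediate genetic risk: ARI5 2.65 per mille, subjects per extra case 378
        high genetic risk: ARI5 0.13 per mille, subjects per extra case 7928
GI-PRS -> MetS logistic OR: 1.012
MetS x genetic interaction p: 0.587
spline nonlinearity p: 0.990
```

Reading the output: 49,933 of 50,000 simulated participants survive the
eligibility cascade (events in the first follow-up year are excluded);
25.75% carry ≥3 metabolic components. The fully adjusted (Model 2) Cox
model estimates a 1.27-fold hazard for MetS carriers; the top GI-PRS
quintile carries a 1.96-fold hazard versus the bottom quintile, and the
doubly exposed group a 2.31-fold hazard versus the doubly unexposed
reference. The absolute-risk rows translate the within-category MetS
effect into per-mille 5-year risk differences and the number of MetS
subjects per additional case (at this cohort size the per-stratum
absolute risks are noisy — the high-genetic stratum's 0.13‰ draw is
sampling noise around its planted value; the spec-scale runs below use
five 200,000-participant cohorts). The logistic OR near 1 reflects that
the score is independent of MetS by construction, and the interaction p
shows no departure from hazard multiplicativity — both planted nulls.

The same run is available from the shell:

```bash
gipm analyze --config config.yaml --seed 1 --out out/
gipm sensitivity --config config.yaml --seed 1 --out out-sens/
```

writing tidy CSVs (descriptives, MetS/band models, component models,
quintile and per-SD models, six-cell joint effects, the 5-year risk
table, standardized rates, subgroup forest, spline curve, PH diagnostics)
plus a checksummed run manifest. `gipm sensitivity` reruns the headline
models under five variants: BMI-defined obesity, exclusion of the first
two follow-up years, complete-case data, unrelated participants, and a
mean-standardized score construction.

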