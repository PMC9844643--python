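"""Synthetic survival cohorts with the statistical structure the analysis
assumes.

The generator emulates a biobank-scale prospective cohort: a panel of
independent risk variants per cancer site with Hardy-Weinberg genotypes,
five correlated metabolic components realised through a latent-Gaussian
copula and back-transformed into continuous measurements that the
NCEP-ATP III classifier reproduces exactly, a standard covariate block,
and exponential proportional-hazards event times with planted effects and
administrative censoring.

Planted-effect model
--------------------
The individual hazard is ``baseline_hazard * exp(eta)`` with

``eta = band_offset(component count) + beta_z * z + cat_offset(category)
+ covariate terms``

where ``z`` is the standardized composite genetic score.  The component
count bands (0 / 1-2 / >=3 flags) carry the metabolic contrasts; the
genetic effect is log-linear per SD with small category-level offsets
chosen so that the *category-model estimands* (intermediate- and
high-vs-low quintile contrasts) equal their configured targets exactly,
accounting for the within-category spread of the continuous score.
Because the outcome model is exponential, every planted contrast has a
closed-form oracle: the crude rate ratio between two groups equals the
planted hazard ratio.

Genotypes are independent of the metabolic traits by construction, so the
composite genetic score carries no information about metabolic syndrome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import mets, prs
from .config import COMPONENTS, SITES, ConfigurationError, ScenarioConfig, child_rng

# ---------------------------------------------------------------------------
# Defaults for the covariate block
# ---------------------------------------------------------------------------

DEFAULT_COVARIATE_MARGINALS: dict[str, dict[str, float]] = {
    "sex": {"female": 0.536, "male": 0.464},
    "age_group": {"40-49": 0.26, "50-59": 0.33, "60-69": 0.41},
    "qualification": {"degree": 0.33, "other": 0.45, "none": 0.22},
    "family_history": {"no": 0.67, "yes": 0.33},
    "smoking": {"never": 0.55, "former": 0.34, "current": 0.11},
    "alcohol": {"lt_weekly": 0.32, "weekly": 0.47, "daily": 0.21},
    "physical_activity": {"low": 0.20, "moderate": 0.45, "high": 0.35},
    "fruit": {"lt2_day": 0.45, "ge2_day": 0.55},
    "vegetables": {"lt2_day": 0.40, "ge2_day": 0.60},
    "red_processed_meat": {"lt2_wk": 0.35, "ge2_wk": 0.65},
    "aspirin": {"no": 0.75, "yes": 0.25},
}

#: Back-transform parameters: (classifier cutoff used as anchor, scale).
#: Measurements are ``cutoff + scale * (Z - c)`` in latent units so the
#: classifier threshold falls exactly at the calibrated latent threshold c.
_MEASUREMENT_SCALE = {
    "central_obesity": 13.49,      # waist SD, cm
    "hypertension": 18.07,         # SBP SD, mmHg
    "hypertriglyceridemia": 0.55,  # log-TG SD
    "low_hdl": 0.30,               # HDL SD, mmol/L
    "hyperglycemia": 6.35,         # HbA1c SD, mmol/mol
}

#: Latent threshold used when a target prevalence is exactly zero.
_INF_THRESHOLD = 8.5

#: planted_loghr keys with special meaning (everything else must name a
#: numeric column, or "column:level" for a categorical indicator).
_RESERVED_TERMS = {
    "mets",
    "mets_components_1_2",
    "mets_components_3plus",
    "gi_prs_per_sd",
    "genetic_cat_intermediate",
    "genetic_cat_high",
    "interaction_mets_x_high",
    "interaction_mets_x_intermediate",
}


@dataclass
class VariantPanel:
    """A site-labelled risk-variant panel plus its sparse LD map."""

    variants: pd.DataFrame
    ld_blocks: dict[frozenset, float]

    def passing(self) -> pd.DataFrame:
        return self.variants[
            self.variants["qc_status"].astype(str).str.startswith(("pass", "proxy"))
        ]


@dataclass
class Cohort:
    """One simulated analysis-ready cohort.

    ``phenotypes`` is the participant table the analysis consumes;
    ``truth`` retains the generator-side quantities (true component flags,
    linear predictor) that missingness may later obscure in ``phenotypes``.
    """

    config: ScenarioConfig
    panel: VariantPanel
    genotypes: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: pd.DataFrame


# ---------------------------------------------------------------------------
# Variant panel
# ---------------------------------------------------------------------------

def make_variant_panel(config: ScenarioConfig) -> VariantPanel:
    """Draw a synthetic risk-variant panel.

    Effect sizes have random sign and magnitude uniform in
    ``effect_size_range``; allele frequencies are uniform in ``maf_range``.
    Clean variants use non-palindromic allele pairs and concordant
    reference frequencies.  Optional decoy variants (flagged
    ``is_decoy``) are palindromic at high MAF or frequency-discordant and
    exist only to exercise harmonization QC.  No variant is shared between
    sites and the default LD map is empty (unlinked panel).
    """
    rng = child_rng(config.seed, "panel")
    lo_maf, hi_maf = config.maf_range
    lo_b, hi_b = config.effect_size_range
    nonpalindromic = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"), ("C", "A"), ("G", "A")]

    rows = []
    for site in SITES:
        k = config.n_snps_per_site.get(site, 0)
        n_decoys = config.n_decoys_per_site.get(site, 0)
        for j in range(k + n_decoys):
            decoy = j >= k
            if decoy:
                alleles = ("A", "T") if rng.random() < 0.5 else ("C", "G")
                maf = rng.uniform(0.45, 0.5)
            else:
                alleles = nonpalindromic[rng.integers(len(nonpalindromic))]
                maf = rng.uniform(lo_maf, hi_maf)
            beta = rng.uniform(lo_b, hi_b) * (1 if rng.random() < 0.5 else -1)
            maf_ref = maf
            if decoy and alleles not in (("A", "T"), ("C", "G")):
                maf_ref = min(0.95, maf + 0.2)  # frequency-discordant decoy
            rows.append(
                {
                    "variant_id": f"snp_{site.lower()}_{j:03d}",
                    "chr": str(int(rng.integers(1, 23))),
                    "pos": int(rng.integers(1_000_000, 200_000_000)),
                    "effect_allele": alleles[0],
                    "other_allele": alleles[1],
                    "beta": float(beta),
                    "p": float(10.0 ** -rng.uniform(8.5, 30.0)),
                    "maf_gwas": float(maf),
                    "maf_ref": float(maf_ref),
                    "site": site,
                    "qc_status": "pass",
                    "is_decoy": decoy,
                }
            )
    variants = pd.DataFrame(rows)
    return VariantPanel(variants=variants, ld_blocks={})


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(panel: VariantPanel, n: int, seed: int) -> pd.DataFrame:
    """Hardy-Weinberg dosages: per variant, Binomial(2, MAF), independent.

    Returns an ``n x m`` int8 DataFrame with variant ids as columns.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = child_rng(seed, "genotypes")
    variants = panel.passing()
    mafs = variants["maf_gwas"].to_numpy(dtype=float)
    dosages = rng.binomial(2, mafs, size=(n, len(mafs))).astype(np.int8)
    return pd.DataFrame(dosages, columns=list(variants["variant_id"]))


# ---------------------------------------------------------------------------
# Metabolic phenotypes and covariates
# ---------------------------------------------------------------------------

def _latent_thresholds(prevalences: Mapping[str, float]) -> np.ndarray:
    c = np.empty(len(COMPONENTS))
    for i, comp in enumerate(COMPONENTS):
        p = prevalences.get(comp, 0.0)
        c[i] = _INF_THRESHOLD if p <= 0.0 else stats.norm.ppf(1.0 - p)
    return c


def simulate_metabolic_phenotypes(config: ScenarioConfig, n: int, seed: int) -> pd.DataFrame:
    """Correlated metabolic measurements plus the covariate block.

    Five latent Gaussian traits with correlation
    ``config.component_latent_corr`` are thresholded so each component's
    flag prevalence matches its target; continuous measurements are linear
    (triglycerides: log-linear) transforms of the latents anchored at the
    classifier cutoffs, so classifying the output reproduces the latent
    flags exactly.  Genotypes are generated elsewhere and are independent
    of everything here.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = child_rng(seed, "phenotypes")

    corr = config.component_latent_corr
    try:
        chol = np.linalg.cholesky(corr + 1e-12 * np.eye(5))
    except np.linalg.LinAlgError as err:
        raise ConfigurationError(
            "component_latent_corr is not a feasible correlation matrix"
        ) from err
    z = rng.standard_normal((n, 5)) @ chol.T
    c = _latent_thresholds(config.component_target_prevalence)

    marginals = dict(DEFAULT_COVARIATE_MARGINALS)
    if config.covariate_marginals:
        marginals.update(config.covariate_marginals)

    df = pd.DataFrame({"eid": np.arange(1, n + 1)})
    for col, levels in marginals.items():
        names = list(levels)
        probs = np.asarray([levels[k] for k in names], dtype=float)
        if not np.isclose(probs.sum(), 1.0):
            raise ConfigurationError(f"covariate marginals for {col!r} must sum to 1")
        df[col] = rng.choice(names, size=n, p=probs)

    male = (df["sex"] == "male").to_numpy()
    crit = mets.MetSCriteria()

    # central obesity: waist > sex-specific cutoff  <=>  Z0 > c0
    waist_cut = np.where(male, crit.waist_cutoff_male, crit.waist_cutoff_female)
    waist = waist_cut + _MEASUREMENT_SCALE["central_obesity"] * (z[:, 0] - c[0])
    # strict '>' at the cutoff: nudge exact boundary values upward is not
    # needed for continuous draws (ties have measure zero)
    df["waist_cm"] = np.maximum(waist, 40.0)
    df["bmi"] = np.maximum(27.0 + 0.25 * (waist - 90.0) + rng.normal(0.0, 2.0, n), 12.0)

    # hypertension: SBP >= 130 OR DBP >= 85; DBP is a deterministic linear
    # map of SBP crossing 85 exactly at SBP 130, so the OR reduces to the
    # SBP criterion and the latent calibration stays exact.
    sbp = crit.sbp_cutoff + _MEASUREMENT_SCALE["hypertension"] * (z[:, 1] - c[1])
    sbp = np.maximum(sbp, 70.0)
    df["sbp_mmhg"] = sbp
    df["dbp_mmhg"] = np.maximum(crit.dbp_cutoff + 0.545 * (sbp - crit.sbp_cutoff), 40.0)

    # hypertriglyceridemia: TG >= 1.7, log-normal tail
    df["tg_mmol_l"] = crit.tg_cutoff * np.exp(
        _MEASUREMENT_SCALE["hypertriglyceridemia"] * (z[:, 2] - c[2])
    )

    # dyslipidemia: HDL < sex-specific cutoff  <=>  Z3 > c3
    hdl_cut = np.where(male, crit.hdl_cutoff_male, crit.hdl_cutoff_female)
    hdl = hdl_cut - _MEASUREMENT_SCALE["low_hdl"] * (z[:, 3] - c[3])
    df["hdl_mmol_l"] = np.clip(hdl, 0.2, None)

    # hyperglycemia: HbA1c >= 42
    hba1c = crit.hba1c_cutoff + _MEASUREMENT_SCALE["hyperglycemia"] * (z[:, 4] - c[4])
    df["hba1c_mmol_mol"] = np.maximum(hba1c, 15.0)

    # medication flags (ignored by the default classifier configuration)
    for col in ("med_bp", "med_lipid", "med_glucose"):
        df[col] = rng.random(n) < 0.03

    df["townsend"] = rng.normal(-1.3, 3.0, n)
    for i in range(1, 11):
        df[f"pc{i}"] = rng.standard_normal(n)
    df["has_relative"] = rng.random(n) < config.related_fraction

    # eligibility flags
    rates = config.exclusion_rates
    codes = np.full(n, "", dtype=object)
    m = rng.random(n) < rates.get("prevalent_cancer", 0.0)
    codes[m] = "C50"
    m2 = (~m) & (rng.random(n) < rates.get("prevalent_c44", 0.0))
    codes[m2] = "C44"
    df["prevalent_cancer_icd10"] = codes
    df["pregnant"] = (df["sex"] == "female") & (rng.random(n) < rates.get("pregnant", 0.0))
    df["ethnicity"] = np.where(rng.random(n) < rates.get("nonwhite", 0.0), "nonwhite", "white")
    df["sex_mismatch"] = rng.random(n) < rates.get("sex_mismatch", 0.0)
    df["genotype_available"] = rng.random(n) >= rates.get("genotype_missing", 0.0)
    blank = np.full(n, np.nan)
    m = rng.random(n) < rates.get("all_components_missing", 0.0)
    for col in ("waist_cm", "sbp_mmhg", "dbp_mmhg", "tg_mmol_l", "hdl_mmol_l", "hba1c_mmol_mol"):
        df.loc[m, col] = blank[m]
    other = np.full(n, np.nan)
    m = rng.random(n) < rates.get("other_cancer", 0.0)
    other[m] = rng.uniform(0.0, config.followup_years, int(m.sum()))
    df["other_cancer_years"] = other

    return df


# ---------------------------------------------------------------------------
# Outcomes
# ---------------------------------------------------------------------------

def _category_offsets(z: np.ndarray, beta: float, target_int: float, target_high: float) -> np.ndarray:
    """Per-participant category log-offsets making the quintile-category
    model estimands equal the planted targets.

    With a rare outcome, the category-model contrast vs the bottom quintile
    is ``(g_cat * E[e^{beta z} | cat]) / (g_low * E[e^{beta z} | low])``;
    solving for the ``g`` offsets at the empirical conditional means makes
    the contrast equal its target exactly.
    """
    cats = prs.assign_genetic_category(z)["genetic_category"].to_numpy()
    ez = np.exp(beta * z)
    mean_low = ez[cats == "low"].mean()
    mean_int = ez[cats == "intermediate"].mean()
    mean_high = ez[cats == "high"].mean()
    g_int = target_int - np.log(mean_int / mean_low)
    g_high = target_high - np.log(mean_high / mean_low)
    return np.where(cats == "intermediate", g_int, np.where(cats == "high", g_high, 0.0))


def planted_linear_predictor(records: pd.DataFrame,
                             gi_prs_z: np.ndarray,
                             config: ScenarioConfig) -> np.ndarray:
    """The planted log-hazard (relative to baseline) for each participant."""
    n = len(records)
    z = np.asarray(gi_prs_z, dtype=float)
    if z.shape != (n,):
        raise ValueError(f"gi_prs_z has length {z.size}, expected {n}")

    if "n_components" in records.columns:
        ncomp = records["n_components"].to_numpy(dtype=int)
    else:
        ncomp = mets.flag_components(records)["n_components"].to_numpy()
    band12 = (ncomp >= 1) & (ncomp <= 2)
    band3 = ncomp >= 3

    p = config.planted_loghr
    eta = np.zeros(n)
    eta += p.get("mets_components_1_2", 0.0) * band12
    eta += p.get("mets_components_3plus", 0.0) * band3
    eta += p.get("mets", 0.0) * band3  # binary MetS term (MetS <=> >=3 flags)

    beta = p.get("gi_prs_per_sd", 0.0)
    eta += beta * z
    has_targets = "genetic_cat_intermediate" in p or "genetic_cat_high" in p
    if has_targets and np.unique(z).size >= 5:
        eta += _category_offsets(
            z, beta,
            p.get("genetic_cat_intermediate", 0.0),
            p.get("genetic_cat_high", 0.0),
        )
    if "interaction_mets_x_high" in p or "interaction_mets_x_intermediate" in p:
        cats = prs.assign_genetic_category(z)["genetic_category"].to_numpy()
        eta += p.get("interaction_mets_x_high", 0.0) * (band3 & (cats == "high"))
        eta += p.get("interaction_mets_x_intermediate", 0.0) * (band3 & (cats == "intermediate"))

    for term, value in p.items():
        if term in _RESERVED_TERMS:
            continue
        if ":" in term:
            col, level = term.split(":", 1)
            if col not in records.columns:
                raise ConfigurationError(f"planted_loghr term {term!r}: no column {col!r}")
            eta += value * (records[col].astype(str) == level).to_numpy()
        elif term in records.columns:
            eta += value * records[term].to_numpy(dtype=float)
        else:
            raise ConfigurationError(f"planted_loghr term {term!r} matches no column")
    return eta


def simulate_outcomes(records: pd.DataFrame,
                      gi_prs_z: np.ndarray,
                      config: ScenarioConfig,
                      seed: int) -> pd.DataFrame:
    """Exponential event times under the planted proportional-hazards model,
    with administrative censoring and site labels for events.

    Adds ``time_years``, ``event`` (0/1) and ``site`` columns.
    """
    rng = child_rng(seed, "outcomes")
    n = len(records)
    eta = planted_linear_predictor(records, gi_prs_z, config)
    hazard = config.baseline_hazard * np.exp(eta)
    event_time = rng.exponential(1.0 / hazard)

    scheme = config.effective_censoring_scheme()
    fracs = np.asarray([f for f, _ in scheme])
    years = np.asarray([y for _, y in scheme])
    censor = years[rng.choice(len(scheme), size=n, p=fracs / fracs.sum())]

    event = event_time <= censor
    out = records.copy()
    out["time_years"] = np.where(event, event_time, censor)
    out["event"] = event.astype(int)
    sites = np.full(n, "", dtype=object)
    k = int(event.sum())
    if k:
        sites[event] = rng.choice(list(SITES), size=k, p=np.asarray(config.site_mix))
    out["site"] = sites
    return out


# ---------------------------------------------------------------------------
# Missingness
# ---------------------------------------------------------------------------

def inject_missingness(records: pd.DataFrame, config: ScenarioConfig, seed: int) -> pd.DataFrame:
    """Blank fields completely at random at ``config.missing_rate``.

    Continuous metabolic fields become NaN; categorical covariates become
    the refused-answer token.  Rate 0 returns the table unchanged.
    """
    rate = config.missing_rate
    if not (0.0 <= rate < 1.0):
        raise ConfigurationError("missing_rate must be in [0, 1)")
    if rate == 0.0:
        return records.copy()
    rng = child_rng(seed, "missingness")
    df = records.copy()
    for col in mets.CONTINUOUS_FIELDS:
        if col in df.columns:
            mask = rng.random(len(df)) < rate
            df.loc[mask, col] = np.nan
    for col in mets.CATEGORICAL_FIELDS:
        if col in df.columns:
            mask = rng.random(len(df)) < rate
            df.loc[mask, col] = "prefer_not_to_answer"
    return df


# ---------------------------------------------------------------------------
# End-to-end cohort assembly
# ---------------------------------------------------------------------------

def simulate_cohort(config: ScenarioConfig,
                    seed: int | None = None,
                    weights: prs.IncidenceWeights | None = None) -> Cohort:
    """Generate one analysis-ready cohort under a scenario.

    Stages (each on its own child seed): variant panel, genotypes,
    phenotypes, genetic scoring, outcomes, missingness.  The returned
    ``phenotypes`` table carries the composite score, its standardized
    version, quintile category, outcomes and eligibility flags; the
    ``truth`` table retains the generator-side component flags and linear
    predictor before any missingness.
    """
    seed = config.seed if seed is None else int(seed)
    panel = make_variant_panel(config)
    genotypes = simulate_genotypes(panel, config.n_participants, seed)
    phen = simulate_metabolic_phenotypes(config, config.n_participants, seed)

    flags = mets.flag_components(phen)
    phen_flags = pd.concat([phen, flags], axis=1)

    site_scores = {}
    clean = panel.variants[~panel.variants["is_decoy"]]
    for site in SITES:
        vsite = clean[clean["site"] == site]
        site_scores[site] = prs.score_site_prs(genotypes, vsite)
    scores = prs.combine_gi_prs(pd.DataFrame(site_scores), weights)

    phen_flags = pd.concat([phen_flags, scores[["gi_prs", "gi_prs_z", "quintile", "genetic_category"]]], axis=1)
    phen_out = simulate_outcomes(phen_flags, scores["gi_prs_z"].to_numpy(), config, seed)

    truth_cols = list(COMPONENTS) + ["n_components", "mets", "gi_prs_z", "genetic_category"]
    truth = phen_out[["eid"] + truth_cols].copy()
    truth["eta"] = planted_linear_predictor(phen_out, scores["gi_prs_z"].to_numpy(), config)

    observed = phen_out.drop(columns=list(COMPONENTS) + ["n_components", "mets"])
    observed = inject_missingness(observed, config, seed)
    return Cohort(config=config, panel=panel, genotypes=genotypes,
                  phenotypes=observed, truth=truth)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_phenotypes_csv(phenotypes: pd.DataFrame, path: str) -> None:
    phenotypes.to_csv(path, index=False)


def write_dosage_csv(genotypes: pd.DataFrame, path: str) -> None:
    genotypes.to_csv(path, index_label="participant")


def write_minimal_vcf(panel: VariantPanel, genotypes: pd.DataFrame, path: str) -> None:
    """Write hard-call genotypes as a minimal VCFv4.2 text file (GT only)."""
    variants = panel.passing()
    samples = [f"S{i}" for i in range(len(genotypes))]
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for _, v in variants.iterrows():
            dosages = genotypes[v["variant_id"]].to_numpy()
            calls = "\t".join(gt_map[int(d)] for d in dosages)
            fh.write(
                f"{v['chr']}\t{v['pos']}\t{v['variant_id']}\t{v['other_allele']}\t"
                f"{v['effect_allele']}\t.\tPASS\t.\tGT\t{calls}\n"
            )
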