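"""Scenario and analysis configuration.

A single :class:`ScenarioConfig` drives the synthetic cohort generator; the
same YAML file also carries the metabolic-syndrome criteria block
(:class:`gipm.mets.MetSCriteria`), the incidence weights used to combine
site-specific polygenic scores, and pipeline options.  Every tunable named in
the module documentation is reachable from this schema.

Seed policy
-----------
A single global integer seed is expanded into independent per-stage streams
via ``numpy.random.SeedSequence((seed, STAGE_CODES[stage]))``.  Stages are
therefore individually reproducible: regenerating only the outcomes of a
cohort under a new global seed does not disturb its genotypes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

SITES = ("ESC", "GC", "CRC")

#: Metabolic-syndrome components, in the fixed order used throughout.
COMPONENTS = (
    "central_obesity",
    "hypertension",
    "hypertriglyceridemia",
    "low_hdl",
    "hyperglycemia",
)

#: Fixed per-stage codes for the seed-splitting rule (never reordered).
STAGE_CODES = {
    "panel": 11,
    "genotypes": 12,
    "phenotypes": 13,
    "outcomes": 14,
    "missingness": 15,
    "bootstrap": 16,
    "analysis": 17,
}


class ConfigurationError(ValueError):
    """Raised when a scenario or analysis configuration is invalid."""


def child_rng(seed: int, stage: str) -> np.random.Generator:
    """Return the dedicated random generator for one pipeline stage."""
    if stage not in STAGE_CODES:
        raise ConfigurationError(f"unknown stage {stage!r}; known: {sorted(STAGE_CODES)}")
    ss = np.random.SeedSequence((int(seed), STAGE_CODES[stage]))
    return np.random.Generator(np.random.PCG64(ss))


def _default_site_mix() -> tuple[float, float, float]:
    # Site shares of incident GI events: 782 ESC, 516 GC, 4205 CRC of 5494.
    total = 782 + 516 + 4205
    return (782 / total, 516 / total, 4205 / total)


def _default_planted_loghr() -> dict[str, float]:
    return {
        # Hazard contrasts for the component-count bands (reference: 0 flags).
        "mets_components_1_2": math.log(1.12),
        "mets_components_3plus": math.log(1.41),
        # Log-linear genetic effect per SD of the composite score.
        "gi_prs_per_sd": math.log(1.35),
        # Target marginal contrasts of the quintile-category model vs the
        # bottom quintile.  Internally converted to small category-level
        # offsets that account for the within-category spread of the
        # continuous score, so the fitted category model recovers exactly
        # these values while the per-SD model recovers gi_prs_per_sd.
        "genetic_cat_intermediate": math.log(1.46),
        "genetic_cat_high": math.log(2.28),
    }


def _default_component_prevalence() -> dict[str, float]:
    # Calibrated so that, with equicorrelated latent correlation 0.3, the
    # fraction with >=3 flags is 0.25581 (the cohort-level MetS prevalence
    # the generator emulates).
    return {
        "central_obesity": 0.32,
        "hypertension": 0.5485,
        "hypertriglyceridemia": 0.42,
        "low_hdl": 0.22,
        "hyperglycemia": 0.15,
    }


def equicorrelated(rho: float, k: int = 5) -> np.ndarray:
    """Equicorrelated correlation matrix with off-diagonal ``rho``."""
    m = np.full((k, k), float(rho))
    np.fill_diagonal(m, 1.0)
    return m


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic-cohort scenario.

    Defaults emulate a UK-Biobank-scale GI-cancer cohort: ~430k white-British
    participants aged 40-69, 25.58% metabolic-syndrome prevalence, a 106-SNP
    risk panel (13 esophageal, 3 gastric, 90 colorectal), ~10.9 years of
    administrative follow-up and a 1.28% crude GI event fraction.
    """

    n_participants: int = 430_036
    n_snps_per_site: dict[str, int] = field(
        default_factory=lambda: {"ESC": 13, "GC": 3, "CRC": 90}
    )
    #: Extra QC-failing decoy variants appended per site (palindromic or
    #: frequency-discordant); they never enter the scoring panel counts.
    n_decoys_per_site: dict[str, int] = field(
        default_factory=lambda: {"ESC": 0, "GC": 0, "CRC": 0}
    )
    maf_range: tuple[float, float] = (0.05, 0.5)
    effect_size_range: tuple[float, float] = (0.05, 0.3)
    planted_loghr: dict[str, float] = field(default_factory=_default_planted_loghr)
    component_latent_corr: np.ndarray = field(
        default_factory=lambda: equicorrelated(0.3)
    )
    component_target_prevalence: dict[str, float] = field(
        default_factory=_default_component_prevalence
    )
    followup_years: float = 10.9
    #: (fraction, years) administrative censoring dates; mimics per-country
    #: registry end dates.  Fractions must sum to 1.  ``None`` means a
    #: single date at ``followup_years``.
    censoring_scheme: tuple[tuple[float, float], ...] | None = None
    #: Baseline hazard (events per person-year) calibrated so the default
    #: scenario yields a crude GI event fraction of 5494/430036 = 1.278%.
    baseline_hazard: float = 9.950301e-4
    site_mix: tuple[float, float, float] = field(default_factory=_default_site_mix)
    missing_rate: float = 0.0
    #: Per-filter fractions of participants planted to fail eligibility.
    #: All zero by default: the generator emulates the post-eligibility
    #: analysis cohort directly.
    exclusion_rates: dict[str, float] = field(
        default_factory=lambda: {
            "prevalent_cancer": 0.0,
            "prevalent_c44": 0.0,
            "all_components_missing": 0.0,
            "pregnant": 0.0,
            "nonwhite": 0.0,
            "sex_mismatch": 0.0,
            "genotype_missing": 0.0,
            "other_cancer": 0.0,
        }
    )
    #: Fraction flagged as having at least one relative in the cohort
    #: (consumed by the unrelated-subset sensitivity analysis).
    related_fraction: float = 0.30
    #: Optional overrides of categorical covariate level probabilities,
    #: e.g. ``{"smoking": {"never": 0.55, "former": 0.34, "current": 0.11}}``.
    #: ``None`` uses the generator's built-in marginals.
    covariate_marginals: dict[str, dict[str, float]] | None = None
    seed: int = 20260

    def __post_init__(self) -> None:
        self.component_latent_corr = np.asarray(self.component_latent_corr, dtype=float)
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        for site, k in self.n_snps_per_site.items():
            if site not in SITES:
                raise ConfigurationError(f"unknown site {site!r}")
            if k < 0:
                raise ConfigurationError(f"n_snps_per_site[{site}] must be >= 0")
        if sum(self.n_snps_per_site.get(s, 0) for s in SITES) == 0:
            raise ConfigurationError("variant panel would be empty: all site counts are 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ConfigurationError(f"maf_range must satisfy 0 < lo <= hi < 1, got {self.maf_range}")
        m = self.component_latent_corr
        if m.shape != (5, 5):
            raise ConfigurationError("component_latent_corr must be 5x5")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ConfigurationError("component_latent_corr is not symmetric")
        if not np.allclose(np.diag(m), 1.0, atol=1e-10):
            raise ConfigurationError("component_latent_corr must have unit diagonal")
        if np.linalg.eigvalsh(m).min() < -1e-10:
            raise ConfigurationError(
                "component_latent_corr is not positive semi-definite"
            )
        for name, p in self.component_target_prevalence.items():
            if name not in COMPONENTS:
                raise ConfigurationError(f"unknown MetS component {name!r}")
            if not (0.0 <= p < 1.0):
                raise ConfigurationError(f"target prevalence for {name} must be in [0,1)")
        if self.baseline_hazard <= 0:
            raise ConfigurationError("baseline_hazard must be > 0")
        if self.followup_years < 0:
            raise ConfigurationError("followup_years must be >= 0")
        if self.censoring_scheme is not None:
            fracs = [f for f, _ in self.censoring_scheme]
            if any(f < 0 for f in fracs) or not math.isclose(sum(fracs), 1.0):
                raise ConfigurationError("censoring_scheme fractions must be >= 0 and sum to 1")
            if any(y < 0 for _, y in self.censoring_scheme):
                raise ConfigurationError("censoring_scheme years must be >= 0")
        mix = np.asarray(self.site_mix, dtype=float)
        if mix.shape != (3,) or (mix < 0).any() or not np.isclose(mix.sum(), 1.0):
            raise ConfigurationError("site_mix must be 3 non-negative fractions summing to 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must be in [0, 1)")
        for name, r in self.exclusion_rates.items():
            if not (0.0 <= r < 1.0):
                raise ConfigurationError(f"exclusion_rates[{name}] must be in [0, 1)")
        for term, v in self.planted_loghr.items():
            if not np.isfinite(v):
                raise ConfigurationError(f"planted_loghr[{term}] is not finite")

    # -- (de)serialisation --------------------------------------------------
    def effective_censoring_scheme(self) -> tuple[tuple[float, float], ...]:
        if self.censoring_scheme is None:
            return ((1.0, self.followup_years),)
        return self.censoring_scheme

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["component_latent_corr"] = self.component_latent_corr.tolist()
        d["censoring_scheme"] = (
            None if self.censoring_scheme is None
            else [list(x) for x in self.censoring_scheme]
        )
        d["maf_range"] = list(self.maf_range)
        d["effect_size_range"] = list(self.effect_size_range)
        d["site_mix"] = list(self.site_mix)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "ScenarioConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown scenario keys: {sorted(unknown)}")
        kwargs = dict(d)
        if "component_latent_corr" in kwargs:
            kwargs["component_latent_corr"] = np.asarray(kwargs["component_latent_corr"], dtype=float)
        for key in ("maf_range", "effect_size_range", "site_mix"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if kwargs.get("censoring_scheme") is not None:
            kwargs["censoring_scheme"] = tuple(tuple(x) for x in kwargs["censoring_scheme"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "ScenarioConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        scenario = doc.get("scenario", doc)
        return cls.from_dict(scenario)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path: str) -> dict[str, Any]:
    """Load a full pipeline YAML configuration document."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigurationError("config file must contain a mapping at top level")
    return doc


def validate_sequence_of_fractions(values: Sequence[float], name: str) -> None:
    for v in values:
        if not (0.0 <= v <= 1.0):
            raise ConfigurationError(f"{name} entries must be fractions in [0,1]")
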