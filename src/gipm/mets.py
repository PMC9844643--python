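"""Eligibility filtering, covariate imputation, and NCEP-ATP III
metabolic-syndrome classification.

Metabolic syndrome (MetS) is defined as carrying any three or more of five
components — central obesity, hypertension, hypertriglyceridemia, low HDL
cholesterol (dyslipidemia) and hyperglycemia — per the National Cholesterol
Education Programme Adult Treatment Panel III (NCEP-ATP III).  Because
fasting glucose is typically unavailable in biobank settings, glycated
hemoglobin (HbA1c >= 42 mmol/mol, i.e. >= 6%) serves as the hyperglycemia
surrogate.

Boundary conventions (configurable): ``>=`` for triglycerides, blood
pressure and HbA1c; strict ``>`` for waist circumference.  Medication-based
qualification of a component is supported but off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .config import COMPONENTS

#: Continuous metabolic measurements subject to median imputation.
CONTINUOUS_FIELDS = ("waist_cm", "bmi", "sbp_mmhg", "dbp_mmhg", "tg_mmol_l", "hdl_mmol_l", "hba1c_mmol_mol")

#: Categorical covariates that receive an explicit "missing" level.
CATEGORICAL_FIELDS = (
    "qualification",
    "family_history",
    "smoking",
    "alcohol",
    "physical_activity",
    "fruit",
    "vegetables",
    "red_processed_meat",
    "aspirin",
)

#: Tokens treated as refused/unknown answers in categorical covariates.
MISSING_TOKENS = ("prefer_not_to_answer", "do_not_know")


class MissingColumnError(KeyError):
    """A required input column is absent."""


@dataclass(frozen=True)
class MetSCriteria:
    """Cutoffs of the five-component classifier.

    ``obesity_mode='bmi30'`` replaces the waist-circumference criterion with
    BMI > 30 kg/m^2 (the obesity-definition sensitivity analysis).
    """

    waist_cutoff_male: float = 102.0     # cm, strict >
    waist_cutoff_female: float = 88.0    # cm, strict >
    tg_cutoff: float = 1.7               # mmol/L, >=
    hdl_cutoff_male: float = 1.03        # mmol/L, < flags dyslipidemia
    hdl_cutoff_female: float = 1.29      # mmol/L, < flags dyslipidemia
    sbp_cutoff: float = 130.0            # mmHg, >=
    dbp_cutoff: float = 85.0             # mmHg, >=
    hba1c_cutoff: float = 42.0           # mmol/mol, >=
    use_medication_flags: bool = False
    obesity_mode: str = "waist"          # "waist" | "bmi30"
    bmi_cutoff: float = 30.0             # kg/m^2, strict > (bmi30 mode)

    def __post_init__(self) -> None:
        for name in ("waist_cutoff_male", "waist_cutoff_female", "tg_cutoff",
                     "hdl_cutoff_male", "hdl_cutoff_female", "sbp_cutoff",
                     "dbp_cutoff", "hba1c_cutoff", "bmi_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.obesity_mode not in ("waist", "bmi30"):
            raise ValueError("obesity_mode must be 'waist' or 'bmi30'")


@dataclass
class EligibilityLog:
    """Ordered record of the exclusion cascade."""

    steps: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, name: str, n_removed: int, n_remaining: int) -> None:
        if self.steps and n_remaining > self.steps[-1][2]:
            raise ValueError("n remaining may not increase down the cascade")
        self.steps.append((name, int(n_removed), int(n_remaining)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["filter", "n_removed", "n_remaining"])

    def write(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _require(df: pd.DataFrame, columns: Iterable[str]) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise MissingColumnError(f"required column(s) missing: {missing}")


# ---------------------------------------------------------------------------
# Eligibility cascade
# ---------------------------------------------------------------------------

def apply_eligibility(records: pd.DataFrame) -> tuple[pd.DataFrame, EligibilityLog]:
    """Apply the baseline exclusion cascade, in its fixed order.

    Removes, in order: prevalent cancer at baseline (non-melanoma skin
    cancer, ICD-10 C44, is exempt); all five MetS components missing;
    pregnancy at recruitment; non-white ancestry; genetic-reported sex
    mismatch; unavailable genotypes; GI cancer diagnosed within the first
    year of follow-up (reverse-causality guard); and another cancer
    diagnosed before the GI cancer.

    Returns the retained records and a per-step :class:`EligibilityLog`.
    """
    _require(records, ["prevalent_cancer_icd10", "pregnant", "ethnicity",
                       "sex_mismatch", "genotype_available", "time_years",
                       "event", "other_cancer_years"])
    _require(records, CONTINUOUS_FIELDS)

    log = EligibilityLog()
    df = records
    log.add("enrolled", 0, len(df))

    code = df["prevalent_cancer_icd10"].fillna("").astype(str)
    keep = (code == "") | code.str.startswith("C44")
    df = df[keep]
    log.add("prevalent_cancer_except_C44", int((~keep).sum()), len(df))

    comp_cols = ["waist_cm", "sbp_mmhg", "tg_mmol_l", "hdl_mmol_l", "hba1c_mmol_mol"]
    keep = ~df[comp_cols].isna().all(axis=1)
    removed = int((~keep).sum())
    df = df[keep]
    log.add("all_five_components_missing", removed, len(df))

    keep = ~df["pregnant"].astype(bool)
    removed = int((~keep).sum())
    df = df[keep]
    log.add("pregnant_at_recruitment", removed, len(df))

    keep = df["ethnicity"].astype(str) == "white"
    removed = int((~keep).sum())
    df = df[keep]
    log.add("nonwhite", removed, len(df))

    keep = ~df["sex_mismatch"].astype(bool)
    removed = int((~keep).sum())
    df = df[keep]
    log.add("genetic_sex_mismatch", removed, len(df))

    keep = df["genotype_available"].astype(bool)
    removed = int((~keep).sum())
    df = df[keep]
    log.add("genotype_unavailable", removed, len(df))

    keep = ~((df["event"].astype(bool)) & (df["time_years"] < 1.0))
    removed = int((~keep).sum())
    df = df[keep]
    log.add("gi_event_in_first_year", removed, len(df))

    other = df["other_cancer_years"]
    has_other = other.notna()
    # Another cancer before the GI diagnosis (or with no GI event at all).
    before_gi = has_other & (~df["event"].astype(bool) | (other < df["time_years"]))
    keep = ~before_gi
    removed = int((~keep).sum())
    df = df[keep]
    log.add("other_cancer_before_gi", removed, len(df))

    return df.copy(), log


# ---------------------------------------------------------------------------
# Missing-value handling
# ---------------------------------------------------------------------------

def impute_covariates(records: pd.DataFrame) -> pd.DataFrame:
    """Impute sex-specific medians for continuous fields; map refused or
    unknown categorical answers to an explicit ``"missing"`` level.

    The unimputed continuous values are retained in ``<field>_raw`` columns
    for the unimputed-data sensitivity analysis.  Idempotent.
    """
    _require(records, ["sex"])
    df = records.copy()
    if df["sex"].isna().any():
        raise ValueError("sex must be non-missing before imputation")

    for col in CONTINUOUS_FIELDS:
        if col not in df.columns:
            continue
        raw_col = f"{col}_raw"
        if raw_col not in df.columns:
            df[raw_col] = df[col]
        missing = df[col].isna()
        if not missing.any():
            continue
        medians = df.groupby("sex", observed=True)[col].median()
        for sex_level, med in medians.items():
            if np.isnan(med):
                raise ValueError(
                    f"cannot impute {col}: all values missing for sex={sex_level!r}"
                )
            mask = missing & (df["sex"] == sex_level)
            df.loc[mask, col] = med

    for col in CATEGORICAL_FIELDS:
        if col not in df.columns:
            continue
        vals = df[col].astype("object")
        mask = vals.isna() | vals.isin(MISSING_TOKENS)
        if mask.any():
            df[col] = vals.where(~mask, "missing")

    return df


# ---------------------------------------------------------------------------
# Component classification
# ---------------------------------------------------------------------------

def flag_components(records: pd.DataFrame, criteria: MetSCriteria | None = None) -> pd.DataFrame:
    """Evaluate the five component flags for each record.

    Returns a DataFrame (aligned to the input index) with one boolean column
    per component plus ``n_components`` and ``mets``.
    """
    criteria = criteria or MetSCriteria()
    required = ["sex", "sbp_mmhg", "dbp_mmhg", "tg_mmol_l", "hdl_mmol_l", "hba1c_mmol_mol"]
    required.append("bmi" if criteria.obesity_mode == "bmi30" else "waist_cm")
    _require(records, required)

    measure_cols = [c for c in CONTINUOUS_FIELDS if c in records.columns]
    values = records[measure_cols].to_numpy(dtype=float)
    if np.nanmin(values) < 0:
        bad = [c for c in measure_cols if (records[c] < 0).any()]
        raise ValueError(f"negative measurement(s) in {bad}")

    male = records["sex"].astype(str).str.lower().isin(["male", "m", "1"]).to_numpy()

    if criteria.obesity_mode == "bmi30":
        obesity = records["bmi"].to_numpy(dtype=float) > criteria.bmi_cutoff
    else:
        waist_cut = np.where(male, criteria.waist_cutoff_male, criteria.waist_cutoff_female)
        obesity = records["waist_cm"].to_numpy(dtype=float) > waist_cut

    hypertension = (records["sbp_mmhg"].to_numpy(dtype=float) >= criteria.sbp_cutoff) | (
        records["dbp_mmhg"].to_numpy(dtype=float) >= criteria.dbp_cutoff
    )
    hypertg = records["tg_mmol_l"].to_numpy(dtype=float) >= criteria.tg_cutoff
    hdl_cut = np.where(male, criteria.hdl_cutoff_male, criteria.hdl_cutoff_female)
    low_hdl = records["hdl_mmol_l"].to_numpy(dtype=float) < hdl_cut
    hyperglycemia = records["hba1c_mmol_mol"].to_numpy(dtype=float) >= criteria.hba1c_cutoff

    if criteria.use_medication_flags:
        if "med_bp" in records.columns:
            hypertension |= records["med_bp"].astype(bool).to_numpy()
        if "med_lipid" in records.columns:
            low_hdl |= records["med_lipid"].astype(bool).to_numpy()
            hypertg |= records["med_lipid"].astype(bool).to_numpy()
        if "med_glucose" in records.columns:
            hyperglycemia |= records["med_glucose"].astype(bool).to_numpy()

    flags = pd.DataFrame(
        {
            "central_obesity": obesity,
            "hypertension": hypertension,
            "hypertriglyceridemia": hypertg,
            "low_hdl": low_hdl,
            "hyperglycemia": hyperglycemia,
        },
        index=records.index,
    )
    flags["n_components"] = flags[list(COMPONENTS)].sum(axis=1).astype(int)
    flags["mets"] = flags["n_components"] >= 3
    return flags


BAND_LABELS = ("0", "1-2", ">=3")


def component_band(n_components: pd.Series | np.ndarray) -> pd.Categorical:
    """Band the component count into 0 / 1-2 / >=3."""
    n = np.asarray(n_components, dtype=int)
    labels = np.where(n == 0, "0", np.where(n <= 2, "1-2", ">=3"))
    return pd.Categorical(labels, categories=list(BAND_LABELS), ordered=True)


def classify_cohort(records: pd.DataFrame, criteria: MetSCriteria | None = None) -> pd.DataFrame:
    """Attach component flags, ``n_components``, the 0/1-2/>=3 band, and the
    binary ``mets`` label to a cohort table."""
    flags = flag_components(records, criteria)
    out = records.copy()
    for col in flags.columns:
        out[col] = flags[col]
    out["mets_band"] = component_band(flags["n_components"])
    return out


def summary_counts(classified: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions by MetS status and by band (descriptives)."""
    n = len(classified)
    rows = []
    for label, mask in [
        ("mets_no", ~classified["mets"]),
        ("mets_yes", classified["mets"]),
        *[(f"band_{b}", classified["mets_band"] == b) for b in BAND_LABELS],
    ]:
        k = int(mask.sum())
        rows.append((label, k, k / n if n else np.nan))
    return pd.DataFrame(rows, columns=["group", "n", "fraction"])
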