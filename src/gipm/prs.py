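"""GWAS summary-statistic harmonization, LD clumping, and polygenic scoring.

The composite gastrointestinal polygenic risk score (GI-PRS) is built in
three steps:

1. *Harmonization.*  Genome-wide-significant variants (p < 5e-8,
   MAF >= 0.01) are reconciled against a reference panel: unavailable
   variants may be replaced by a strongly correlated proxy (r^2 > 0.8);
   variants with allele mismatches, allele-frequency discordance
   (|MAF difference| > 0.10), or strand-ambiguous palindromic alleles
   (A/T, G/C) at MAF >= 0.45 are removed.  Correlated variants at the same
   locus are pruned by greedy LD clumping (r^2 < 0.2), keeping the variant
   with the smallest p-value as the locus index.
2. *Site scoring.*  Each site-specific PRS is the dosage-weighted sum of
   per-allele effect sizes: ``score_i = sum_j dosage_ij * beta_j``.
3. *Combination.*  Site scores are summed with weights proportional to each
   cancer site's age-standardized incidence rate (or, alternatively, after
   rescaling each site PRS to unit cohort mean), then standardized to zero
   mean and unit SD over the analysis cohort.

Every input variant ends with exactly one terminal status — ``pass``,
``proxy:<original id>``, or ``fail:<reason>`` — so harmonization reports
are conservative: statuses always sum to the input count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

VARIANT_COLUMNS = [
    "variant_id", "chr", "pos", "effect_allele", "other_allele",
    "beta", "p", "maf_gwas", "maf_ref", "site", "qc_status",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class DosageError(ValueError):
    """Genotype dosages outside the valid [0, 2] range."""


@dataclass(frozen=True)
class IncidenceWeights:
    """Per-site combination weights for the composite GI-PRS.

    ``rates`` are age-standardized incidence rates per 100,000 person-years.
    The shipped defaults are order-of-magnitude stand-ins for UK rates
    (ESC 14, GC 11, CRC 70); analyses of real data should supply the
    published rates via configuration.  ``mode='mean_standardized'``
    rescales each site PRS to unit cohort mean before weighting (the
    alternative-construction sensitivity analysis).
    """

    rates: Mapping[str, float] = field(
        default_factory=lambda: {"ESC": 14.0, "GC": 11.0, "CRC": 70.0}
    )
    mode: str = "incidence_weighted"

    def __post_init__(self) -> None:
        for site, r in self.rates.items():
            if r <= 0:
                raise ValueError(f"incidence rate for {site} must be strictly positive")
        if self.mode not in ("incidence_weighted", "mean_standardized"):
            raise ValueError("mode must be 'incidence_weighted' or 'mean_standardized'")


def is_palindromic(a1: str, a2: str) -> bool:
    return {a1.upper(), a2.upper()} in ({"A", "T"}, {"C", "G"})


def _complement(allele: str) -> str:
    return "".join(_COMPLEMENT.get(b, b) for b in allele.upper())


# ---------------------------------------------------------------------------
# Harmonization filters
# ---------------------------------------------------------------------------

def filter_summary_stats(variants: pd.DataFrame,
                         p_threshold: float = 5e-8,
                         maf_threshold: float = 0.01) -> pd.DataFrame:
    """Mark variants passing the genome-wide significance and MAF filters.

    Keeps variants with ``p < p_threshold`` and ``maf_gwas >= maf_threshold``;
    all others receive an explicit failure status (never a silent drop).
    """
    df = variants.copy()
    p = pd.to_numeric(df["p"], errors="coerce")
    maf = pd.to_numeric(df["maf_gwas"], errors="coerce")
    status = np.full(len(df), "pass", dtype=object)
    status[(p >= p_threshold).to_numpy()] = "fail:p_threshold"
    status[(maf < maf_threshold).to_numpy()] = "fail:maf"
    status[(p.isna() | maf.isna()).to_numpy()] = "fail:missing_stats"
    prior = df["qc_status"].astype(str) if "qc_status" in df else pd.Series("pass", index=df.index)
    keep_prior = prior.str.startswith("fail").to_numpy()
    df["qc_status"] = np.where(keep_prior, prior, status)
    return df


def proxy_substitute(variant: pd.Series,
                     available: set[str],
                     ld_table: pd.DataFrame,
                     r2_threshold: float = 0.8,
                     positions: Mapping[str, int] | None = None) -> pd.Series:
    """Replace an unavailable variant by its best available LD proxy.

    If the variant itself is available it is returned unchanged.  Otherwise
    the available proxy with the largest r^2 is substituted, provided
    r^2 > ``r2_threshold`` strictly; ties in r^2 are broken by smallest
    genomic position.  With no qualifying proxy the status becomes
    ``fail:no_proxy``.
    """
    v = variant.copy()
    vid = v["variant_id"]
    if vid in available:
        return v
    pairs = ld_table[(ld_table["id_a"] == vid) | (ld_table["id_b"] == vid)]
    candidates = []
    for _, row in pairs.iterrows():
        other = row["id_b"] if row["id_a"] == vid else row["id_a"]
        if other in available:
            pos = positions.get(other, np.inf) if positions else np.inf
            candidates.append((float(row["r2"]), other, pos))
    qualifying = [c for c in candidates if c[0] > r2_threshold]
    if not qualifying:
        v["qc_status"] = "fail:no_proxy"
        return v
    best_r2 = max(c[0] for c in qualifying)
    best = min((c for c in qualifying if c[0] == best_r2), key=lambda c: c[2])
    v["qc_status"] = f"proxy:{vid}"
    v["variant_id"] = best[1]
    if positions and best[1] in positions:
        v["pos"] = positions[best[1]]
    return v


def qc_against_reference(variant: pd.Series,
                         reference: pd.Series | None,
                         maf_diff_threshold: float = 0.10,
                         palindromic_maf: float = 0.45) -> pd.Series:
    """Reconcile one variant with its reference-panel record.

    Allele pairs are matched allowing an effect/other swap and a strand
    flip; a swap negates the effect size so scores stay on the effect-allele
    scale of the harmonized record.  Failure reasons: ``not_in_reference``,
    ``allele_mismatch``, ``maf_discordant`` (|MAF difference| > 0.10), and
    ``palindromic`` (A/T or G/C alleles with MAF >= 0.45).
    """
    v = variant.copy()
    if str(v.get("qc_status", "pass")).startswith("fail"):
        return v
    if reference is None:
        v["qc_status"] = "fail:not_in_reference"
        return v

    ea, oa = str(v["effect_allele"]).upper(), str(v["other_allele"]).upper()
    rea, roa = str(reference["effect_allele"]).upper(), str(reference["other_allele"]).upper()

    if is_palindromic(ea, oa) and min(float(v["maf_gwas"]), 1 - float(v["maf_gwas"])) >= palindromic_maf:
        v["qc_status"] = "fail:palindromic"
        return v

    swapped = None
    if (ea, oa) == (rea, roa):
        swapped = False
    elif (ea, oa) == (roa, rea):
        swapped = True
    elif (_complement(ea), _complement(oa)) == (rea, roa):
        swapped = False
    elif (_complement(ea), _complement(oa)) == (roa, rea):
        swapped = True
    if swapped is None:
        v["qc_status"] = "fail:allele_mismatch"
        return v

    maf_ref = float(reference["maf_ref"]) if "maf_ref" in reference else float(reference["maf"])
    maf_gwas = float(v["maf_gwas"])
    # Compare frequencies on the harmonized effect-allele orientation.
    ref_freq = 1.0 - maf_ref if swapped else maf_ref
    if abs(maf_gwas - ref_freq) > maf_diff_threshold:
        v["qc_status"] = "fail:maf_discordant"
        return v

    if swapped:
        v["effect_allele"], v["other_allele"] = oa, ea
        v["beta"] = -float(v["beta"])
        v["maf_gwas"] = 1.0 - maf_gwas
    v["maf_ref"] = ref_freq if not swapped else 1.0 - ref_freq
    if not str(v.get("qc_status", "")).startswith("proxy"):
        v["qc_status"] = "pass"
    return v


# ---------------------------------------------------------------------------
# LD clumping
# ---------------------------------------------------------------------------

def _ld_lookup(ld_table: pd.DataFrame | Mapping) -> dict[frozenset, float]:
    if isinstance(ld_table, pd.DataFrame):
        return {
            frozenset((a, b)): float(r)
            for a, b, r in zip(ld_table["id_a"], ld_table["id_b"], ld_table["r2"])
        }
    return {frozenset(k): float(v) for k, v in ld_table.items()}


def ld_clump(variants: pd.DataFrame,
             ld_table: pd.DataFrame | Mapping,
             r2_threshold: float = 0.2,
             strict: bool = False) -> pd.DataFrame:
    """Greedy LD clumping within each cancer site.

    Repeatedly select the remaining variant with the smallest p-value as a
    locus index and discard every remaining variant with r^2 >= threshold
    to it.  Ties in p are broken by genomic position.  Missing LD entries
    are treated as r^2 = 0 (unlinked) unless ``strict``, in which case they
    raise.  Discarded variants receive ``fail:clumped:<index id>``.
    """
    ld = _ld_lookup(ld_table)
    df = variants.copy()
    status = df["qc_status"].astype(str).copy() if "qc_status" in df else pd.Series("pass", index=df.index, dtype=object)

    eligible = status.str.startswith(("pass", "proxy"))
    for site, idx in df[eligible].groupby("site").groups.items():
        block = df.loc[idx].sort_values(["p", "pos"], kind="mergesort")
        remaining = list(block.index)
        while remaining:
            index_variant = remaining.pop(0)
            index_id = df.at[index_variant, "variant_id"]
            survivors = []
            for other in remaining:
                key = frozenset((index_id, df.at[other, "variant_id"]))
                if key not in ld:
                    if strict:
                        raise KeyError(f"no LD entry for pair {sorted(key)}")
                    r2 = 0.0
                else:
                    r2 = ld[key]
                if r2 >= r2_threshold:
                    status.at[other] = f"fail:clumped:{index_id}"
                else:
                    survivors.append(other)
            remaining = survivors
    df["qc_status"] = status
    return df


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score_site_prs(dosages: pd.DataFrame | np.ndarray,
                   variants: pd.DataFrame) -> np.ndarray:
    """Dosage-weighted sum of effect sizes for one cancer site.

    ``dosages`` holds one column per passing variant (values in [0, 2]); a
    DataFrame is aligned to ``variants['variant_id']`` by column name.
    """
    passing = variants[variants["qc_status"].astype(str).str.startswith(("pass", "proxy"))]
    ids = list(passing["variant_id"])
    if isinstance(dosages, pd.DataFrame):
        missing = [i for i in ids if i not in dosages.columns]
        if missing:
            raise KeyError(f"dosage columns missing for variants: {missing[:5]}")
        mat = dosages[ids].to_numpy(dtype=float)
    else:
        mat = np.asarray(dosages, dtype=float)
        if mat.shape[1] != len(ids):
            raise ValueError(
                f"dosage matrix has {mat.shape[1]} columns, expected {len(ids)}"
            )
    if mat.size and (np.nanmin(mat) < 0 or np.nanmax(mat) > 2):
        raise DosageError("dosages must lie in [0, 2]")
    betas = passing["beta"].to_numpy(dtype=float)
    return mat @ betas


def combine_gi_prs(site_scores: pd.DataFrame,
                   weights: IncidenceWeights | None = None) -> pd.DataFrame:
    """Combine site-specific PRSs into the composite GI-PRS.

    Returns a DataFrame with the site scores, ``gi_prs``, the per-SD
    standardized ``gi_prs_z``, the empirical ``quintile`` (1-5) and the
    three-level ``genetic_category``.
    """
    weights = weights or IncidenceWeights()
    sites = [s for s in ("ESC", "GC", "CRC") if s in site_scores.columns]
    if len(sites) != 3:
        raise KeyError(f"site_scores must contain ESC, GC and CRC columns, got {list(site_scores.columns)}")
    out = site_scores[sites].copy()

    parts = []
    for site in sites:
        col = out[site].to_numpy(dtype=float)
        if weights.mode == "mean_standardized":
            mean = col.mean()
            if mean == 0.0:
                raise ZeroDivisionError(
                    f"site PRS mean for {site} is exactly 0; cannot mean-standardize"
                )
            col = col / mean
            out[f"{site}_rescaled"] = col
        parts.append(weights.rates[site] * col)
    gi = np.sum(parts, axis=0)
    out["gi_prs"] = gi
    sd = gi.std(ddof=0)
    if sd == 0:
        raise ValueError("GI-PRS has zero variance; cannot standardize")
    out["gi_prs_z"] = (gi - gi.mean()) / sd

    cats = assign_genetic_category(gi)
    out["quintile"] = cats["quintile"]
    out["genetic_category"] = cats["genetic_category"]
    return out


def assign_genetic_category(values: np.ndarray | pd.Series) -> pd.DataFrame:
    """Quintile-based genetic-risk categories.

    Low = bottom quintile, intermediate = quintiles 2-4, high = top
    quintile, with boundaries from the empirical distribution of the
    analysis cohort.  A value equal to a cut point goes to the lower
    quintile.
    """
    v = np.asarray(values, dtype=float)
    if np.unique(v).size < 5:
        raise ValueError("need at least 5 distinct score values for quintiles")
    cuts = np.quantile(v, [0.2, 0.4, 0.6, 0.8])
    quintile = 1 + np.searchsorted(cuts, v, side="left")
    category = np.where(quintile == 1, "low", np.where(quintile == 5, "high", "intermediate"))
    index = values.index if isinstance(values, pd.Series) else None
    return pd.DataFrame(
        {
            "quintile": quintile.astype(int),
            "genetic_category": pd.Categorical(
                category, categories=["low", "intermediate", "high"], ordered=True
            ),
        },
        index=index,
    )


# ---------------------------------------------------------------------------
# Pipeline-level harmonization and reporting
# ---------------------------------------------------------------------------

def harmonize(variants: pd.DataFrame,
              reference: pd.DataFrame,
              ld_table: pd.DataFrame | Mapping,
              available: set[str] | None = None,
              p_threshold: float = 5e-8,
              maf_threshold: float = 0.01,
              r2_proxy: float = 0.8,
              r2_clump: float = 0.2) -> pd.DataFrame:
    """Run the full per-site harmonization cascade on a summary-stat table.

    Order: significance/MAF filters, proxy substitution for variants absent
    from ``available`` (defaults to the reference panel ids), reference QC
    (alleles, frequency concordance, palindromes), then LD clumping.
    """
    ref_by_id = {r["variant_id"]: r for _, r in reference.iterrows()}
    positions = {r["variant_id"]: int(r["pos"]) for _, r in reference.iterrows()}
    if available is None:
        available = set(ref_by_id)
    if isinstance(ld_table, Mapping):
        ld_df = pd.DataFrame(
            [(a, b, r) for (a, b), r in ((tuple(k), v) for k, v in ld_table.items())],
            columns=["id_a", "id_b", "r2"],
        )
    else:
        ld_df = ld_table

    df = filter_summary_stats(variants, p_threshold, maf_threshold)
    rows = []
    for _, v in df.iterrows():
        if str(v["qc_status"]).startswith("fail"):
            rows.append(v)
            continue
        v = proxy_substitute(v, available, ld_df, r2_proxy, positions)
        if str(v["qc_status"]).startswith("fail"):
            rows.append(v)
            continue
        v = qc_against_reference(v, ref_by_id.get(v["variant_id"]))
        rows.append(v)
    out = pd.DataFrame(rows).reset_index(drop=True)
    return ld_clump(out, ld_table, r2_clump)


def harmonization_report(variants: pd.DataFrame) -> pd.DataFrame:
    """Terminal-status counts; rows sum to the input variant count."""
    status = variants["qc_status"].astype(str)
    terminal = status.str.replace(r"^(fail:clumped|proxy):.*$", r"\1", regex=True)
    counts = terminal.value_counts().rename_axis("status").reset_index(name="n")
    counts["fraction"] = counts["n"] / len(variants)
    return counts


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def read_summary_stats(path: str) -> pd.DataFrame:
    """Read a tab-separated GWAS summary-stat or scoring file."""
    df = pd.read_csv(path, sep="\t")
    if "qc_status" not in df.columns:
        df["qc_status"] = "pass"
    return df


def write_scoring_file(variants: pd.DataFrame, path: str) -> None:
    cols = [c for c in VARIANT_COLUMNS if c in variants.columns]
    variants[cols].to_csv(path, sep="\t", index=False)


def read_dosage_matrix(path: str) -> pd.DataFrame:
    """Read a participant-by-variant dosage matrix CSV (index = participant id)."""
    return pd.read_csv(path, index_col=0)


def read_vcf_dosages(path: str) -> pd.DataFrame:
    """Extract dosages from a VCF (DS field if present, else GT allele count)."""
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(path)
    samples = vcf.samples
    data: dict[str, np.ndarray] = {}
    for record in vcf:
        try:
            ds = record.format("DS")
            dosage = np.asarray(ds, dtype=float).ravel()
        except (KeyError, TypeError):
            gts = np.asarray(record.gt_types)
            # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            dosage = np.where(gts == 3, 2.0, np.where(gts == 1, 1.0, 0.0))
        data[record.ID or f"{record.CHROM}:{record.POS}"] = dosage
    return pd.DataFrame(data, index=samples)
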