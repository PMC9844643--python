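"""Translation of fitted cohort outcomes into public-health quantities.

For each joint stratum (genetic-risk category x metabolic-syndrome status)
this module reports the 5-year absolute risk (crude cumulative incidence,
per mille), the absolute risk increase attributable to metabolic syndrome
within a genetic category, the number of exposed subjects per additional
case over 5 years (a number-needed-to-harm analogue), directly
standardized event rates, and bootstrap percentile confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .config import child_rng
from .survival import CoxFit, ModelSpec, fit_cox

GENETIC_LEVELS = ("low", "intermediate", "high")


@dataclass
class RiskStratumSummary:
    """One row of the joint risk table."""

    genetic_category: str
    n_cases_no_mets: int
    n_cases_mets: int
    person_years_no_mets: float
    person_years_mets: float
    hr_mets: float
    hr_ci: tuple[float, float]
    hr_p: float
    ar5_no_mets: float
    ar5_no_mets_ci: tuple[float, float]
    ar5_mets: float
    ar5_mets_ci: tuple[float, float]
    ari5: float
    ari5_ci: tuple[float, float]
    nnh: float
    nnh_ci: tuple[float, float]


# ---------------------------------------------------------------------------
# Absolute-risk arithmetic
# ---------------------------------------------------------------------------

def absolute_risk_5y(records: pd.DataFrame,
                     mask: pd.Series | np.ndarray | None = None,
                     horizon: float = 5.0,
                     method: str = "crude") -> float:
    """Absolute risk over a fixed horizon, per mille.

    ``crude`` (default): events within the horizon divided by the stratum
    size at baseline — subjects censored early stay in the denominator.
    ``km``: Kaplan-Meier cumulative incidence at the horizon, which
    corrects for censoring before the horizon.
    """
    df = records if mask is None else records[np.asarray(mask, dtype=bool)]
    if len(df) == 0:
        raise ValueError("empty stratum")
    event = df["event"].to_numpy(dtype=bool)
    time = df["time_years"].to_numpy(dtype=float)
    if method == "crude":
        return 1000.0 * float((event & (time <= horizon)).sum()) / len(df)
    if method == "km":
        from lifelines import KaplanMeierFitter

        km = KaplanMeierFitter().fit(time, event_observed=event)
        return 1000.0 * float(1.0 - km.predict(horizon))
    raise ValueError(f"unknown method {method!r}")


def absolute_risk_increase(ar_mets: float, ar_nomets: float) -> float:
    """Difference of two per-mille absolute risks (exposed minus unexposed)."""
    return ar_mets - ar_nomets


def number_needed(ari_per_mille: float) -> float:
    """Exposed subjects per one additional case: round(1000 / ARI).

    Undefined (NaN) for non-positive absolute risk increases.
    """
    if ari_per_mille <= 0 or not np.isfinite(ari_per_mille):
        return float("nan")
    return float(round(1000.0 / ari_per_mille))


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def bootstrap_ci(statistic: Callable[[pd.DataFrame], float],
                 records: pd.DataFrame,
                 B: int = 1000,
                 seed: int = 0,
                 alpha: float = 0.05,
                 method: str = "percentile") -> tuple[float, float]:
    """Nonparametric bootstrap CI; the resampling unit is the participant.

    ``percentile`` (default) returns the alpha/2 and 1-alpha/2 quantiles of
    the B resampled statistics; ``bca`` applies the bias-corrected and
    accelerated adjustment.  Raises if the statistic fails on more than 1%
    of resamples.
    """
    rng = child_rng(seed, "bootstrap")
    n = len(records)
    values = np.empty(B)
    failures = 0
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            values[b] = statistic(records.iloc[idx])
        except Exception:
            values[b] = np.nan
            failures += 1
    if failures > 0.01 * B:
        raise RuntimeError(f"statistic failed on {failures}/{B} bootstrap resamples")
    values = values[np.isfinite(values)]

    if method == "percentile":
        lo, hi = np.quantile(values, [alpha / 2, 1 - alpha / 2])
        return float(lo), float(hi)
    if method == "bca":
        from scipy import stats as sps

        theta = statistic(records)
        z0 = sps.norm.ppf((values < theta).mean().clip(1e-9, 1 - 1e-9))
        # jackknife acceleration on a subsample cap for tractability
        jn = min(n, 200)
        jack_idx = np.linspace(0, n - 1, jn).astype(int)
        jack = np.array([
            statistic(records.drop(records.index[i])) for i in jack_idx
        ])
        jm = jack.mean()
        a = ((jm - jack) ** 3).sum() / (6 * (((jm - jack) ** 2).sum()) ** 1.5 + 1e-300)
        za = sps.norm.ppf([alpha / 2, 1 - alpha / 2])
        adj = sps.norm.cdf(z0 + (z0 + za) / (1 - a * (z0 + za)))
        lo, hi = np.quantile(values, adj)
        return float(lo), float(hi)
    raise ValueError(f"unknown bootstrap method {method!r}")


def _stratified_ar_bootstrap(records: pd.DataFrame,
                             strata: pd.Series,
                             horizon: float,
                             B: int,
                             seed: int) -> dict[str, np.ndarray]:
    """Vectorized bootstrap of per-stratum crude 5-year risks.

    Resamples participants with replacement and recomputes every stratum's
    per-mille risk in each resample; far faster than calling
    :func:`bootstrap_ci` per stratum and keeps strata consistent within a
    resample (needed for risk differences).
    """
    rng = child_rng(seed, "bootstrap")
    n = len(records)
    labels, codes = np.unique(strata.astype(str).to_numpy(), return_inverse=True)
    k = len(labels)
    hit = (records["event"].to_numpy(dtype=bool)
           & (records["time_years"].to_numpy(dtype=float) <= horizon))
    out = np.empty((B, k))
    denom = np.empty((B, k))
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        c = codes[idx]
        denom[b] = np.bincount(c, minlength=k)
        out[b] = np.bincount(c, weights=hit[idx].astype(float), minlength=k)
    with np.errstate(invalid="ignore", divide="ignore"):
        risks = 1000.0 * out / denom
    return {label: risks[:, j] for j, label in enumerate(labels)}


# ---------------------------------------------------------------------------
# Standardized rates
# ---------------------------------------------------------------------------

def standardized_event_rate(records: pd.DataFrame,
                            stratifier: str,
                            standard_vars: Sequence[str] = ("age_group", "sex"),
                            per: float = 1000.0) -> pd.DataFrame:
    """Directly standardized event rates per stratum.

    Cell-specific event rates (events per person-year) are averaged with
    weights equal to the whole-cohort person-year distribution over the
    standardization cells (age group x sex by default).  Cells absent from
    a stratum are skipped with a warning.
    """
    import warnings

    df = records
    cell_key = df[list(standard_vars)].astype(str).agg("|".join, axis=1)
    py = df["time_years"].to_numpy(dtype=float)
    total_py_by_cell = pd.Series(py).groupby(cell_key.values).sum()
    weights = total_py_by_cell / total_py_by_cell.sum()

    rows = []
    for level, sub_idx in df.groupby(stratifier, observed=True).groups.items():
        sub = df.loc[sub_idx]
        sub_cells = cell_key.loc[sub_idx]
        rate = 0.0
        for cell, w in weights.items():
            m = sub_cells == cell
            cell_py = sub.loc[m, "time_years"].sum()
            if cell_py == 0:
                warnings.warn(f"stratum {level!r}: empty standardization cell {cell!r}; skipped")
                continue
            cell_events = sub.loc[m, "event"].sum()
            rate += w * cell_events / cell_py
        crude = sub["event"].sum() / sub["time_years"].sum()
        rows.append((level, per * rate, per * crude, int(sub["event"].sum()), float(sub["time_years"].sum())))
    return pd.DataFrame(rows, columns=[stratifier, "standardized_rate", "crude_rate", "events", "person_years"])


# ---------------------------------------------------------------------------
# Joint-effect outputs
# ---------------------------------------------------------------------------

def joint_cell_labels(records: pd.DataFrame) -> pd.Series:
    """The 6-level genetic x MetS exposure, reference ``low|no_mets``."""
    cat = records["genetic_category"].astype(str)
    mets = np.where(records["mets"].astype(bool), "mets", "no_mets")
    labels = cat + "|" + mets
    order = [f"{g}|{m}" for g in GENETIC_LEVELS for m in ("no_mets", "mets")]
    return pd.Series(pd.Categorical(labels, categories=order, ordered=True),
                     index=records.index, name="joint_cell")


def joint_effect_table(records: pd.DataFrame,
                       adjustment: str = "model2_pcs",
                       ties: str = "efron") -> tuple[pd.DataFrame, CoxFit]:
    """Six-cell joint-effect Cox model (3 genetic levels x MetS).

    A single fit with the 6-level exposure; the (low genetic risk, no MetS)
    cell is the reference with HR fixed at 1.
    """
    df = records.copy()
    df["joint_cell"] = joint_cell_labels(df)
    counts = df.groupby("joint_cell", observed=False)["event"].agg(["size", "sum"])
    empty = counts[(counts["size"] == 0) | (counts["sum"] == 0)]
    if len(empty):
        raise ValueError(f"joint cell(s) without events: {list(empty.index)}")

    fit = fit_cox(df, ModelSpec(exposure=("joint_cell",), adjustment=adjustment, ties=ties))
    rows = [("low|no_mets", 1.0, 1.0, 1.0, np.nan)]
    for cell in df["joint_cell"].cat.categories[1:]:
        term = f"joint_cell[{cell}]"
        lo, hi = fit.ci(term)
        rows.append((cell, fit.hr(term), lo, hi, fit.p(term)))
    table = pd.DataFrame(rows, columns=["joint_cell", "hr", "ci_low", "ci_high", "p"])
    cases = df[df["event"] == 1].groupby("joint_cell", observed=False).size()
    pys = df.groupby("joint_cell", observed=False)["time_years"].sum()
    table["cases"] = table["joint_cell"].map(cases).astype(int)
    table["person_years"] = table["joint_cell"].map(pys)
    return table, fit


def mets_within_genetic_table(records: pd.DataFrame,
                              adjustment: str = "model2_pcs",
                              horizon: float = 5.0,
                              B: int = 1000,
                              seed: int = 0,
                              ties: str = "efron") -> pd.DataFrame:
    """The within-genetic-category MetS risk table.

    For each genetic-risk category: the MetS-vs-no-MetS hazard ratio
    (adjusted Cox model within the category), crude 5-year absolute risks
    per mille for both MetS strata, their difference (absolute risk
    increase), and the number of MetS subjects per additional case, all
    with bootstrap percentile CIs (B resamples; HR CI is the Wald CI).
    """
    df = records.copy()
    df["joint_cell"] = joint_cell_labels(df)
    boot = _stratified_ar_bootstrap(df, df["joint_cell"], horizon, B, seed)

    rows = []
    for g in GENETIC_LEVELS:
        sub = df[df["genetic_category"].astype(str) == g]
        fit = fit_cox(sub, ModelSpec(exposure=("mets",), adjustment=adjustment, ties=ties))
        term = "mets[True]"
        lo, hi = fit.ci(term)

        m_no = ~sub["mets"].astype(bool)
        ar_no = absolute_risk_5y(sub, m_no, horizon)
        ar_yes = absolute_risk_5y(sub, ~m_no, horizon)
        ari = absolute_risk_increase(ar_yes, ar_no)
        nnh = number_needed(ari)

        b_no = boot[f"{g}|no_mets"]
        b_yes = boot[f"{g}|mets"]
        b_ari = b_yes - b_no
        with np.errstate(divide="ignore", invalid="ignore"):
            b_nnh = np.where(b_ari > 0, 1000.0 / b_ari, np.nan)
        b_nnh = b_nnh[np.isfinite(b_nnh)]
        q = lambda v: tuple(np.quantile(v[np.isfinite(v)], [0.025, 0.975]))

        rows.append(RiskStratumSummary(
            genetic_category=g,
            n_cases_no_mets=int((sub.loc[m_no, "event"]).sum()),
            n_cases_mets=int((sub.loc[~m_no, "event"]).sum()),
            person_years_no_mets=float(sub.loc[m_no, "time_years"].sum()),
            person_years_mets=float(sub.loc[~m_no, "time_years"].sum()),
            hr_mets=fit.hr(term), hr_ci=(lo, hi), hr_p=fit.p(term),
            ar5_no_mets=ar_no, ar5_no_mets_ci=q(b_no),
            ar5_mets=ar_yes, ar5_mets_ci=q(b_yes),
            ari5=ari, ari5_ci=q(b_ari),
            nnh=nnh,
            nnh_ci=(number_needed(q(b_ari)[1]), number_needed(q(b_ari)[0])),
        ))

    out = pd.DataFrame([r.__dict__ for r in rows])
    return out
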