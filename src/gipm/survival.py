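"""Cox proportional-hazards estimation and its inferential companions.

The association analyses follow a two-tier adjustment scheme:

* **Model 1** — age group, sex, qualification, Townsend deprivation index,
  family history of cancer.
* **Model 2** — Model 1 plus smoking status, alcohol consumption, physical
  activity, fruit intake, vegetable consumption, red/processed meat
  consumption, and regular aspirin/ibuprofen use.
* Models containing a genetic term additionally adjust for the top 10
  genetic principal components.

Estimation uses the Cox partial likelihood (Efron ties handling by
default; Breslow available) on the follow-up time scale in years since
baseline.  The proportional-hazards assumption is checked with the
Grambsch-Therneau test on scaled Schoenfeld residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

MODEL1_COVARIATES = ("age_group", "sex", "qualification", "townsend", "family_history")
MODEL2_EXTRA = ("smoking", "alcohol", "physical_activity", "fruit",
                "vegetables", "red_processed_meat", "aspirin")
PC_COLUMNS = tuple(f"pc{i}" for i in range(1, 11))

#: Reference levels for categorical terms (dropped from the design).
REFERENCE_LEVELS = {
    "sex": "female",
    "age_group": "40-49",
    "qualification": "degree",
    "family_history": "no",
    "smoking": "never",
    "alcohol": "lt_weekly",
    "physical_activity": "low",
    "fruit": "lt2_day",
    "vegetables": "lt2_day",
    "red_processed_meat": "lt2_wk",
    "aspirin": "no",
    "mets": False,
    "mets_band": "0",
    "genetic_category": "low",
    "joint_cell": "low|no_mets",
}

Z95 = stats.norm.ppf(0.975)


class ZeroEventStratumError(ValueError):
    """An exposure stratum contains no events."""


class ConvergenceError(RuntimeError):
    """The partial-likelihood maximization failed."""


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one Cox model.

    ``exposure`` columns are entered first in the design; categorical
    exposures are dummy-coded against their reference level.  ``adjustment``
    is one of ``model1``, ``model2``, ``model2_pcs`` or ``none``.
    """

    exposure: tuple[str, ...]
    adjustment: str = "model2"
    outcome: str = "GI"           # GI | ESC | GC | CRC
    ties: str = "efron"           # efron | breslow
    subgroup: Callable[[pd.DataFrame], pd.Series] | None = None

    def __post_init__(self) -> None:
        if self.adjustment not in ("none", "model1", "model2", "model2_pcs"):
            raise ValueError(f"unknown adjustment set {self.adjustment!r}")
        if self.outcome not in ("GI", "ESC", "GC", "CRC"):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.ties not in ("efron", "breslow"):
            raise ValueError(f"ties method must be 'efron' or 'breslow'")

    def adjustment_columns(self) -> tuple[str, ...]:
        if self.adjustment == "none":
            return ()
        cols = MODEL1_COVARIATES
        if self.adjustment in ("model2", "model2_pcs"):
            cols = cols + MODEL2_EXTRA
        if self.adjustment == "model2_pcs":
            cols = cols + PC_COLUMNS
        return cols


@dataclass
class CoxFit:
    """A fitted proportional-hazards model in tidy form.

    ``terms`` has one row per design column: coefficient (log HR), SE,
    HR with 95% CI, and Wald p.  ``cov`` is the coefficient covariance
    matrix (aligned with ``terms``), kept for joint Wald tests.
    """

    terms: pd.DataFrame
    cov: np.ndarray
    loglik: float
    n: int
    n_events: int
    ties: str
    converged: bool
    exposure_terms: tuple[str, ...] = ()

    def hr(self, term: str) -> float:
        return float(self.terms.loc[self.terms["term"] == term, "hr"].iloc[0])

    def loghr(self, term: str) -> float:
        return float(self.terms.loc[self.terms["term"] == term, "coef"].iloc[0])

    def se(self, term: str) -> float:
        return float(self.terms.loc[self.terms["term"] == term, "se"].iloc[0])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.terms.loc[self.terms["term"] == term].iloc[0]
        return float(row["ci_low"]), float(row["ci_high"])

    def p(self, term: str) -> float:
        return float(self.terms.loc[self.terms["term"] == term, "p"].iloc[0])


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

def _dummy_code(df: pd.DataFrame, col: str) -> pd.DataFrame:
    """Dummy-code a categorical column against its reference level.

    Empty levels are dropped; the reference is the configured level when
    present in the data, else the first observed level.
    """
    values = df[col]
    if isinstance(values.dtype, pd.CategoricalDtype):
        levels = [l for l in values.cat.categories if (values == l).any()]
    else:
        levels = sorted(values.dropna().unique(), key=str)
    ref = REFERENCE_LEVELS.get(col)
    if ref in levels:
        levels = [ref] + [l for l in levels if l != ref]
    out = {}
    for level in levels[1:]:
        out[f"{col}[{level}]"] = (values == level).astype(float)
    return pd.DataFrame(out, index=df.index)


def build_design(df: pd.DataFrame, columns: Iterable[str]) -> pd.DataFrame:
    """Assemble a full-rank design matrix from raw columns.

    Numeric columns pass through; object/categorical/boolean columns are
    dummy-coded against their reference level.  Zero-variance columns are
    dropped.
    """
    parts: list[pd.DataFrame] = []
    for col in columns:
        if col not in df.columns:
            raise KeyError(f"design column {col!r} not in records")
        s = df[col]
        if s.dtype == bool or s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            if s.dtype == bool:
                parts.append(pd.DataFrame({f"{col}[True]": s.astype(float)}, index=df.index))
            else:
                parts.append(_dummy_code(df, col))
        else:
            parts.append(pd.DataFrame({col: s.astype(float)}, index=df.index))
    X = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=df.index)
    keep = [c for c in X.columns if X[c].nunique() > 1]
    return X[keep]


def _status_vector(df: pd.DataFrame, outcome: str) -> np.ndarray:
    event = df["event"].to_numpy(dtype=float)
    if outcome == "GI":
        return event
    # site-specific outcome: other-site events are censored at their time
    return np.where((event > 0) & (df["site"].astype(str) == outcome), 1.0, 0.0)


# ---------------------------------------------------------------------------
# Cox fitting
# ---------------------------------------------------------------------------

def fit_cox(records: pd.DataFrame, spec: ModelSpec) -> CoxFit:
    """Maximize the Cox partial likelihood for one model specification."""
    df = records
    if spec.subgroup is not None:
        df = df[spec.subgroup(df).astype(bool)]

    time = df["time_years"].to_numpy(dtype=float)
    if (time < 0).any():
        raise ValueError("negative follow-up times")
    status = _status_vector(df, spec.outcome)
    if status.sum() < 1:
        raise ZeroEventStratumError(f"no {spec.outcome} events in the data")

    # zero-event exposure strata are a modelling error, not a numerics one
    for col in spec.exposure:
        s = df[col]
        if s.dtype == bool or s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            for level, sub in df.groupby(col, observed=True):
                if len(sub) and _status_vector(sub, spec.outcome).sum() == 0:
                    raise ZeroEventStratumError(
                        f"stratum {col}={level!r} has zero {spec.outcome} events"
                    )

    X_exp = build_design(df, spec.exposure)
    X_adj = build_design(df, spec.adjustment_columns())
    X = pd.concat([X_exp, X_adj], axis=1)
    if X.shape[1] == 0:
        raise ValueError("empty design matrix")
    # guard against rank deficiency (e.g. collinear exposure coding)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError(
            f"design matrix is rank deficient ({rank} < {X.shape[1]}); "
            "check exposure coding"
        )

    model = PHReg(time, X, status=status, ties=spec.ties)
    try:
        res = model.fit(maxiter=200)
    except Exception as err:  # pragma: no cover - numerics
        raise ConvergenceError(f"Cox fit failed: {err}") from err
    converged = bool(np.all(np.isfinite(res.params)) and np.all(np.isfinite(res.bse)))

    coefs = np.asarray(res.params, dtype=float)
    ses = np.asarray(res.bse, dtype=float)
    z = coefs / ses
    terms = pd.DataFrame(
        {
            "term": list(X.columns),
            "coef": coefs,
            "se": ses,
            "hr": np.exp(coefs),
            "ci_low": np.exp(coefs - Z95 * ses),
            "ci_high": np.exp(coefs + Z95 * ses),
            "p": 2 * stats.norm.sf(np.abs(z)),
        }
    )
    fit = CoxFit(
        terms=terms,
        cov=np.asarray(res.cov_params(), dtype=float),
        loglik=float(res.llf),
        n=len(df),
        n_events=int(status.sum()),
        ties=spec.ties,
        converged=converged,
        exposure_terms=tuple(X_exp.columns),
    )
    fit._time = time          # retained for residual diagnostics
    fit._status = status
    fit._X = X
    return fit


def wald_joint_test(fit: CoxFit, terms: Sequence[str]) -> tuple[float, int, float]:
    """Joint Wald chi-square test that a set of coefficients is zero."""
    names = list(fit.terms["term"])
    idx = [names.index(t) for t in terms]
    b = fit.terms["coef"].to_numpy()[idx]
    V = fit.cov[np.ix_(idx, idx)]
    chi2 = float(b @ np.linalg.solve(V, b))
    df = len(idx)
    return chi2, df, float(stats.chi2.sf(chi2, df))


# ---------------------------------------------------------------------------
# Trend test
# ---------------------------------------------------------------------------

def trend_test(records: pd.DataFrame, exposure: str, spec: ModelSpec | None = None) -> float:
    """Wald p-value for an ordinal exposure entered as a single score."""
    base = spec or ModelSpec(exposure=(exposure,))
    s = records[exposure]
    if isinstance(s.dtype, pd.CategoricalDtype) and s.cat.ordered:
        codes = s.cat.codes.astype(float)
    else:
        levels = sorted(s.dropna().unique(), key=str)
        codes = s.map({l: i for i, l in enumerate(levels)}).astype(float)
    if codes.nunique() < 3:
        raise ValueError("trend test needs an exposure with >= 3 ordered levels")
    df = records.copy()
    df["_trend_score"] = codes
    fit = fit_cox(df, ModelSpec(exposure=("_trend_score",),
                                adjustment=base.adjustment,
                                outcome=base.outcome, ties=base.ties,
                                subgroup=base.subgroup))
    return fit.p("_trend_score")


# ---------------------------------------------------------------------------
# Proportional-hazards diagnostics
# ---------------------------------------------------------------------------

def schoenfeld_ph_test(fit: CoxFit, time_transform: str = "identity") -> pd.DataFrame:
    """Grambsch-Therneau test of the proportional-hazards assumption.

    Correlates Schoenfeld residuals with (transformed) event time.  Returns
    one row per model term plus a joint ``GLOBAL`` row.  Transforms:
    ``identity`` (default), ``rank``, ``km`` (left-continuous
    Kaplan-Meier), ``log``.
    """
    if not hasattr(fit, "_X"):
        raise ValueError("fit lacks retained design; refit with fit_cox")
    time, status, X = fit._time, fit._status, fit._X
    d = int(status.sum())
    if d < 2:
        raise ValueError("PH test needs at least 2 events")

    order = np.argsort(time, kind="mergesort")
    t = time[order]
    s = status[order].astype(bool)
    Xs = X.to_numpy()[order]
    beta = fit.terms["coef"].to_numpy()
    w = np.exp(Xs @ beta)

    # risk-set sums from the tail (all subjects with time >= t_k)
    w_rev = w[::-1]
    xw_rev = (Xs * w[:, None])[::-1]
    cum_w = np.cumsum(w_rev)[::-1]
    cum_xw = np.cumsum(xw_rev, axis=0)[::-1]
    xbar = cum_xw / cum_w[:, None]

    resid = (Xs - xbar)[s]                 # Schoenfeld residuals at events
    t_events = t[s]

    if time_transform == "identity":
        g = t_events
    elif time_transform == "log":
        g = np.log(t_events)
    elif time_transform == "rank":
        g = stats.rankdata(t_events)
    elif time_transform == "km":
        # left-continuous KM of the censoring-inclusive survival curve
        n_at_risk = len(t) - np.searchsorted(t, t_events, side="left")
        km = np.cumprod(1.0 - 1.0 / n_at_risk)
        g = np.concatenate([[1.0], km[:-1]])
    else:
        raise ValueError(f"unknown time transform {time_transform!r}")
    gc = g - g.mean()

    V = fit.cov                             # inverse information
    gsum2 = float(gc @ gc)
    u = gc @ resid                          # p-vector

    rows = []
    for j, term in enumerate(fit.terms["term"]):
        chi2_j = d * u[j] ** 2 * V[j, j] / gsum2
        rows.append((term, chi2_j, 1, stats.chi2.sf(chi2_j, 1)))
    chi2_g = d * float(u @ V @ u) / gsum2
    p_terms = len(beta)
    rows.append(("GLOBAL", chi2_g, p_terms, stats.chi2.sf(chi2_g, p_terms)))
    return pd.DataFrame(rows, columns=["term", "chi2", "df", "p"])


# ---------------------------------------------------------------------------
# Interaction, logistic, spline, subgroup
# ---------------------------------------------------------------------------

def interaction_test(records: pd.DataFrame,
                     adjustment: str = "model2_pcs",
                     continuous: bool = False,
                     ties: str = "efron") -> float:
    """Multiplicative-scale interaction between MetS and genetic risk.

    Default coding: binary MetS x 3-level genetic category (two product
    terms; joint Wald, 2 df).  With ``continuous=True`` a single
    MetS x standardized-score product term is used instead (1 df).
    """
    df = records.copy()
    mets_num = df["mets"].astype(float)
    if continuous:
        df["_mets_x_z"] = mets_num * df["gi_prs_z"].astype(float)
        inter_cols = ("_mets_x_z",)
        main: tuple[str, ...] = ("mets", "gi_prs_z")
    else:
        cats = df["genetic_category"].astype(str)
        for level in ("intermediate", "high"):
            cell = (cats == level) & df["mets"].astype(bool)
            if not cell.any():
                raise ZeroEventStratumError(f"empty joint cell mets x {level}")
            df[f"_mets_x_{level}"] = mets_num * (cats == level).astype(float)
        inter_cols = ("_mets_x_intermediate", "_mets_x_high")
        main = ("mets", "genetic_category")
    fit = fit_cox(df, ModelSpec(exposure=main + inter_cols, adjustment=adjustment, ties=ties))
    present = [f"{c}[True]" if c == "mets" else c for c in inter_cols]
    names = set(fit.terms["term"])
    targets = [t for t in present if t in names]
    _, _, p = wald_joint_test(fit, targets)
    return p


def logistic_prs_on_mets(records: pd.DataFrame,
                         adjustment: str = "model2_pcs") -> dict[str, float]:
    """Odds ratio of metabolic syndrome per SD of the composite score,
    from a multivariable logistic regression."""
    import statsmodels.api as sm

    y = records["mets"].astype(float).to_numpy()
    if y.min() == y.max():
        raise ValueError("metabolic syndrome is constant; logistic model undefined")
    spec = ModelSpec(exposure=("gi_prs_z",), adjustment=adjustment)
    X = pd.concat(
        [build_design(records, ("gi_prs_z",)), build_design(records, spec.adjustment_columns())],
        axis=1,
    )
    X = sm.add_constant(X)
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    separated = bool(np.abs(res.params).max() > 15)
    coef = float(res.params["gi_prs_z"])
    se = float(res.bse["gi_prs_z"])
    return {
        "or": float(np.exp(coef)),
        "ci_low": float(np.exp(coef - Z95 * se)),
        "ci_high": float(np.exp(coef + Z95 * se)),
        "p": float(res.pvalues["gi_prs_z"]),
        "separation_flag": separated,
    }


def rcs_basis(x: np.ndarray, knots: Sequence[float]) -> np.ndarray:
    """Restricted cubic spline basis (linear tails) after Harrell.

    Returns ``len(x) x (k-1)`` columns: the linear term plus ``k-2``
    nonlinear terms for ``k`` knots.
    """
    knots = np.asarray(sorted(knots), dtype=float)
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing")
    k = len(knots)
    if k < 3:
        raise ValueError("need at least 3 knots")
    x = np.asarray(x, dtype=float)
    denom = (knots[-1] - knots[0]) ** 2

    def cub(u: np.ndarray) -> np.ndarray:
        return np.where(u > 0, u ** 3, 0.0)

    cols = [x]
    for j in range(k - 2):
        term = (
            cub(x - knots[j])
            - cub(x - knots[-2]) * (knots[-1] - knots[j]) / (knots[-1] - knots[-2])
            + cub(x - knots[-1]) * (knots[-2] - knots[j]) / (knots[-1] - knots[-2])
        ) / denom
        cols.append(term)
    return np.column_stack(cols)


def rcs_dose_response(records: pd.DataFrame,
                      score_col: str = "gi_prs_z",
                      adjustment: str = "model2_pcs",
                      knots: Sequence[float] | None = None,
                      grid: np.ndarray | None = None,
                      ties: str = "efron") -> tuple[pd.DataFrame, float]:
    """Flexible dose-response curve of hazard vs the continuous score.

    Default: 4 knots at the 5th/35th/65th/95th percentiles.  The curve is
    normalized to HR = 1 at the cohort median score.  Returns the pointwise
    curve and the Wald p-value of the nonlinear terms.
    """
    x = records[score_col].to_numpy(dtype=float)
    if knots is None:
        knots = np.percentile(x, [5, 35, 65, 95])
    basis = rcs_basis(x, knots)
    df = records.copy()
    names = [f"_rcs{j}" for j in range(basis.shape[1])]
    for j, nm in enumerate(names):
        df[nm] = basis[:, j]
    fit = fit_cox(df, ModelSpec(exposure=tuple(names), adjustment=adjustment, ties=ties))
    _, _, p_nonlin = wald_joint_test(fit, names[1:])

    if grid is None:
        grid = np.linspace(np.percentile(x, 1), np.percentile(x, 99), 101)
    ref = np.median(x)
    bg = rcs_basis(np.append(grid, ref), knots)
    beta = np.array([fit.loghr(nm) for nm in names])
    f = bg @ beta
    log_hr = f[:-1] - f[-1]
    names_idx = [list(fit.terms["term"]).index(nm) for nm in names]
    V = fit.cov[np.ix_(names_idx, names_idx)]
    contrast = bg[:-1] - bg[-1]
    se = np.sqrt(np.einsum("ij,jk,ik->i", contrast, V, contrast))
    curve = pd.DataFrame(
        {
            "score": grid,
            "hr": np.exp(log_hr),
            "ci_low": np.exp(log_hr - Z95 * se),
            "ci_high": np.exp(log_hr + Z95 * se),
        }
    )
    return curve, float(p_nonlin)


def subgroup_analysis(records: pd.DataFrame,
                      stratifier: str,
                      exposure: str = "mets",
                      adjustment: str = "model2",
                      ties: str = "efron") -> tuple[pd.DataFrame, float]:
    """Per-stratum exposure HRs plus an interaction-based heterogeneity p.

    The stratifier is removed from the within-stratum adjustment set.
    Strata with zero events are reported as non-estimable rows.
    """
    levels = [l for l in records[stratifier].dropna().unique()]
    if len(levels) < 2:
        raise ValueError(f"stratifier {stratifier!r} has fewer than 2 levels")

    rows = []
    for level in sorted(levels, key=str):
        sub = records[records[stratifier] == level]
        try:
            fit = fit_cox(sub, ModelSpec(exposure=(exposure,), adjustment=adjustment, ties=ties))
            term = fit.exposure_terms[0]
            lo, hi = fit.ci(term)
            rows.append((level, fit.n, fit.n_events, fit.hr(term), lo, hi, fit.p(term)))
        except ZeroEventStratumError:
            rows.append((level, len(sub), 0, np.nan, np.nan, np.nan, np.nan))
    table = pd.DataFrame(
        rows, columns=["stratum", "n", "events", "hr", "ci_low", "ci_high", "p"]
    )

    # heterogeneity: exposure x stratifier product terms in the pooled model
    df = records.copy()
    exp_num = df[exposure].astype(float) if df[exposure].dtype != object else (
        df[exposure] == sorted(df[exposure].unique(), key=str)[-1]
    ).astype(float)
    inter_names = []
    base_levels = sorted(levels, key=str)
    for level in base_levels[1:]:
        nm = f"_het_{level}"
        df[nm] = exp_num * (df[stratifier] == level).astype(float)
        inter_names.append(nm)
    # avoid duplicating the stratifier when it already sits in the
    # adjustment set
    pooled_exposure = [exposure, *inter_names]
    if stratifier not in ModelSpec(exposure=("mets",), adjustment=adjustment).adjustment_columns():
        pooled_exposure.insert(1, stratifier)
    fit = fit_cox(df, ModelSpec(exposure=tuple(pooled_exposure),
                                adjustment=adjustment, ties=ties))
    _, _, p_het = wald_joint_test(fit, inter_names)
    return table, float(p_het)
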