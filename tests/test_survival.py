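import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from gipm import survival
from gipm.survival import ModelSpec, ZeroEventStratumError, fit_cox

from conftest import make_survival_frame


# ---------------------------------------------------------------------------
# Partial-likelihood oracle
# ---------------------------------------------------------------------------

def exact_partial_loglik(beta, x, time, event):
    """Brute-force Cox partial log-likelihood for distinct event times."""
    ll = 0.0
    for i in np.where(event == 1)[0]:
        risk = time >= time[i]
        ll += beta * x[i] - np.log(np.exp(beta * x[risk]).sum())
    return ll


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_cox_matches_bruteforce_partial_likelihood(seed):
    """On tiny data with distinct event times the fitted coefficient
    maximizes the exact partial likelihood."""
    rng = np.random.default_rng(seed)
    n = 8
    x = rng.normal(size=n)
    time = rng.exponential(1.0, n) + np.arange(n) * 1e-3  # distinct
    event = np.ones(n)
    event[rng.integers(0, n)] = 0
    df = pd.DataFrame({"x": x, "time_years": time, "event": event,
                       "site": np.where(event == 1, "CRC", "")})
    fit = fit_cox(df, ModelSpec(exposure=("x",), adjustment="none"))
    res = optimize.minimize_scalar(
        lambda b: -exact_partial_loglik(b, x, time, event), bounds=(-5, 5),
        method="bounded", options={"xatol": 1e-10},
    )
    assert fit.loghr("x") == pytest.approx(res.x, abs=1e-4)


def test_cox_close_to_exponential_rate_ratio_mle():
    """Uncensored exponential two-arm data: the Cox HR approximates the
    exact exponential rate-ratio MLE (e1/T1)/(e0/T0)."""
    df = make_survival_frame(200, np.log(2.0), seed=5, censor=np.inf)
    fit = fit_cox(df, ModelSpec(exposure=("arm",), adjustment="none"))
    e1 = df.loc[df["arm"] == 1, "event"].sum()
    t1 = df.loc[df["arm"] == 1, "time_years"].sum()
    e0 = df.loc[df["arm"] == 0, "event"].sum()
    t0 = df.loc[df["arm"] == 0, "time_years"].sum()
    mle = (e1 / t1) / (e0 / t0)
    assert abs(fit.hr("arm") - mle) / mle < 0.10


def test_efron_equals_breslow_without_ties():
    df = make_survival_frame(300, 0.4, seed=2)
    assert df["time_years"].nunique() >= (df["event"] == 1).sum()
    f1 = fit_cox(df, ModelSpec(exposure=("arm",), adjustment="none", ties="efron"))
    f2 = fit_cox(df, ModelSpec(exposure=("arm",), adjustment="none", ties="breslow"))
    assert f1.loghr("arm") == pytest.approx(f2.loghr("arm"), abs=1e-10)


def test_time_rescaling_invariance():
    df = make_survival_frame(300, 0.4, seed=4)
    f1 = fit_cox(df, ModelSpec(exposure=("arm",), adjustment="none"))
    df2 = df.copy()
    df2["time_years"] = df2["time_years"] * 3.7
    f2 = fit_cox(df2, ModelSpec(exposure=("arm",), adjustment="none"))
    assert f1.loghr("arm") == pytest.approx(f2.loghr("arm"), abs=1e-8)


def test_cox_agrees_with_lifelines():
    """Independent-engine cross-check on a multivariable fit."""
    from lifelines import CoxPHFitter

    rng = np.random.default_rng(11)
    n = 400
    df = pd.DataFrame({
        "a": rng.normal(size=n),
        "b": rng.integers(0, 2, n).astype(float),
    })
    t = rng.exponential(1 / np.exp(0.5 * df["a"] - 0.3 * df["b"]))
    df["event"] = (t <= 1.5).astype(int)
    df["time_years"] = np.minimum(t, 1.5)
    df["site"] = np.where(df["event"] == 1, "CRC", "")
    fit = fit_cox(df, ModelSpec(exposure=("a", "b"), adjustment="none"))
    ll = CoxPHFitter().fit(df[["a", "b", "time_years", "event"]],
                           duration_col="time_years", event_col="event")
    assert fit.loghr("a") == pytest.approx(ll.params_["a"], abs=1e-6)
    assert fit.loghr("b") == pytest.approx(ll.params_["b"], abs=1e-6)
    assert fit.se("a") == pytest.approx(ll.standard_errors_["a"], abs=1e-6)


def test_hr_ci_p_consistent_with_coefficients():
    df = make_survival_frame(500, 0.5, seed=9)
    fit = fit_cox(df, ModelSpec(exposure=("arm",), adjustment="none"))
    row = fit.terms.iloc[0]
    assert row["hr"] == pytest.approx(np.exp(row["coef"]))
    assert row["ci_low"] == pytest.approx(np.exp(row["coef"] - 1.959964 * row["se"]), rel=1e-5)
    assert row["p"] == pytest.approx(2 * stats.norm.sf(abs(row["coef"] / row["se"])))


def test_zero_event_stratum_is_named():
    df = make_survival_frame(100, 0.0, seed=1)
    df["group"] = np.where(df.index < 50, "a", "b")
    df.loc[df["group"] == "b", "event"] = 0
    with pytest.raises(ZeroEventStratumError, match="group='b'"):
        fit_cox(df, ModelSpec(exposure=("group",), adjustment="none"))


def test_negative_times_rejected():
    df = make_survival_frame(50, 0.0, seed=1)
    df.loc[0, "time_years"] = -1.0
    with pytest.raises(ValueError, match="negative"):
        fit_cox(df, ModelSpec(exposure=("arm",), adjustment="none"))


# ---------------------------------------------------------------------------
# Trend test
# ---------------------------------------------------------------------------

def test_trend_requires_three_levels():
    df = make_survival_frame(200, 0.3, seed=3)
    df["band"] = np.where(df["arm"] == 1, "hi", "lo")
    with pytest.raises(ValueError, match="3 ordered levels"):
        survival.trend_test(df, "band")


def test_trend_detects_monotone_hazard():
    rng = np.random.default_rng(6)
    n = 3000
    level = rng.integers(0, 3, n)
    t = rng.exponential(1 / (0.3 * np.exp(0.4 * level)))
    df = pd.DataFrame({
        "band": pd.Categorical.from_codes(level, ["0", "1-2", ">=3"], ordered=True),
        "time_years": np.minimum(t, 3.0),
        "event": (t <= 3.0).astype(int),
        "site": "",
    })
    df.loc[df["event"] == 1, "site"] = "CRC"
    spec = ModelSpec(exposure=("band",), adjustment="none")
    assert survival.trend_test(df, "band", spec) < 1e-6


# ---------------------------------------------------------------------------
# Proportional-hazards diagnostics
# ---------------------------------------------------------------------------

def test_schoenfeld_test_agrees_with_lifelines():
    from lifelines import CoxPHFitter
    from lifelines.statistics import proportional_hazard_test

    df = make_survival_frame(600, 0.5, seed=21)
    fit = fit_cox(df, ModelSpec(exposure=("arm",), adjustment="none"))
    mine = survival.schoenfeld_ph_test(fit, "identity")
    ll = CoxPHFitter().fit(df[["arm", "time_years", "event"]],
                           duration_col="time_years", event_col="event")
    theirs = proportional_hazard_test(ll, df[["arm", "time_years", "event"]],
                                      time_transform="identity")
    p_mine = float(mine.loc[mine["term"] == "arm", "p"].iloc[0])
    p_theirs = float(np.ravel(theirs.p_value)[0])
    assert p_mine == pytest.approx(p_theirs, abs=1e-6)


def test_schoenfeld_detects_reversing_effect():
    """An effect that flips sign mid-follow-up violates proportionality."""
    rng = np.random.default_rng(30)
    n = 20_000
    x = rng.integers(0, 2, n).astype(float)
    # piecewise hazard: HR=2 before t=1, HR=1/2 after
    lam1 = 0.5 * np.exp(np.log(2.0) * x)
    t1 = rng.exponential(1 / lam1)
    lam2 = 0.5 * np.exp(-np.log(2.0) * x)
    t = np.where(t1 < 1.0, t1, 1.0 + rng.exponential(1 / lam2))
    event = t <= 3.0
    df = pd.DataFrame({"arm": x, "time_years": np.minimum(t, 3.0),
                       "event": event.astype(int),
                       "site": np.where(event, "CRC", "")})
    fit = fit_cox(df, ModelSpec(exposure=("arm",), adjustment="none"))
    ph = survival.schoenfeld_ph_test(fit, "identity")
    assert float(ph.loc[ph["term"] == "GLOBAL", "p"].iloc[0]) < 1e-6


def test_schoenfeld_needs_events():
    df = make_survival_frame(50, 0.0, seed=2)
    df["event"] = 0
    df.loc[0, "event"] = 1
    fit = fit_cox(df, ModelSpec(exposure=("arm",), adjustment="none"))
    with pytest.raises(ValueError, match="2 events"):
        survival.schoenfeld_ph_test(fit)


# ---------------------------------------------------------------------------
# Interaction / logistic / spline / subgroup
# ---------------------------------------------------------------------------

def test_interaction_null_p_in_unit_interval(smoke_analysis_frame):
    p = survival.interaction_test(smoke_analysis_frame, adjustment="model1")
    assert 0.0 < p <= 1.0
    p2 = survival.interaction_test(smoke_analysis_frame, adjustment="model1",
                                   continuous=True)
    assert 0.0 < p2 <= 1.0


def test_interaction_empty_cell_rejected(smoke_analysis_frame):
    df = smoke_analysis_frame[
        ~((smoke_analysis_frame["genetic_category"] == "high")
          & smoke_analysis_frame["mets"])
    ]
    with pytest.raises(ZeroEventStratumError, match="high"):
        survival.interaction_test(df, adjustment="model1")


def test_collinear_exposure_rejected():
    df = make_survival_frame(200, 0.3, seed=3)
    df["arm2"] = df["arm"]
    with pytest.raises(ValueError, match="rank deficient"):
        fit_cox(df, ModelSpec(exposure=("arm", "arm2"), adjustment="none"))


def test_logistic_degenerate_outcome_rejected(smoke_analysis_frame):
    df = smoke_analysis_frame.copy()
    df["mets"] = True
    with pytest.raises(ValueError, match="constant"):
        survival.logistic_prs_on_mets(df)


def test_logistic_null_or_near_one(smoke_analysis_frame):
    out = survival.logistic_prs_on_mets(smoke_analysis_frame, adjustment="model1")
    assert 0.8 < out["or"] < 1.25
    assert not out["separation_flag"]


def test_rcs_basis_properties():
    x = np.linspace(-3, 3, 400)
    basis = survival.rcs_basis(x, [-2, -0.5, 0.5, 2])
    assert basis.shape == (400, 3)
    # linear beyond the boundary knots: second differences vanish
    tail = basis[x > 2.5]
    second = np.diff(tail, n=2, axis=0)
    assert np.abs(second).max() < 1e-8
    with pytest.raises(ValueError, match="strictly increasing"):
        survival.rcs_basis(x, [0, 0, 1, 2])


def test_rcs_reference_hr_is_one(smoke_analysis_frame):
    ref = float(np.median(smoke_analysis_frame["gi_prs_z"]))
    grid = np.array([ref - 1, ref, ref + 1])
    curve, p = survival.rcs_dose_response(smoke_analysis_frame, grid=grid,
                                          adjustment="model1")
    assert curve.loc[1, "hr"] == pytest.approx(1.0, abs=1e-12)
    assert 0.0 < p <= 1.0


def test_subgroup_analysis_reports_strata_and_heterogeneity(smoke_analysis_frame):
    table, p_het = survival.subgroup_analysis(smoke_analysis_frame, "sex",
                                              adjustment="model1")
    assert set(table["stratum"]) == {"female", "male"}
    assert 0.0 < p_het <= 1.0


def test_subgroup_constant_stratifier_rejected(smoke_analysis_frame):
    df = smoke_analysis_frame.copy()
    df["only"] = "one"
    with pytest.raises(ValueError, match="fewer than 2"):
        survival.subgroup_analysis(df, "only")
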