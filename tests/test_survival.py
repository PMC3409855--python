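"""Cox engine: brute-force oracle, lifelines cross-check, baseline hazard,
risk classification, and the mediation comparison."""

import numpy as np
import pandas as pd
import pytest

from cortisurv.survival import (
    AttenuationSummary,
    CoxFit,
    RiskProfile,
    adjusted_survival,
    classify_risk,
    cohort_summary,
    compare_mediation,
    dichotomize_cesd,
    fit_cox,
    hr_table,
)


# ---------------------------------------------------------------------------
# risk classification and CES-D dichotomisation


@pytest.mark.parametrize("n,expected", [(0, "low"), (1, "low"), (2, "intermediate"),
                                        (3, "high"), (7, "high")])
def test_classify_risk_rule(n, expected):
    flags = dict.fromkeys(
        ["karnofsky_lt80", "calcium_ge10", "low_hemoglobin", "high_ldh",
         "prior_radiation", "mets_ge2", "interval_le1yr"][:n], True)
    assert classify_risk(RiskProfile(**flags)) == expected
    assert classify_risk(n) == expected


@pytest.mark.parametrize("score,expected", [(16, 1), (15, 0), (0, 0), (35.5, 1)])
def test_dichotomize_cesd(score, expected):
    assert dichotomize_cesd(score) == expected


def test_dichotomize_rejects_negative():
    with pytest.raises(ValueError):
        dichotomize_cesd(-1)


# ---------------------------------------------------------------------------
# Cox partial likelihood


def _brute_partial_loglik(beta, time, event, x, ties):
    """Exhaustive one-covariate partial log likelihood (independent oracle)."""
    ll = 0.0
    for t in sorted(set(time[event])):
        D = [i for i in range(len(time)) if event[i] and time[i] == t]
        R = [i for i in range(len(time)) if time[i] >= t]
        wD = sum(np.exp(beta * x[i]) for i in D)
        wR = sum(np.exp(beta * x[i]) for i in R)
        ll += sum(beta * x[i] for i in D)
        d = len(D)
        for el in range(d):
            if ties == "efron":
                ll -= np.log(wR - el / d * wD)
            else:
                ll -= np.log(wR)
    return ll


@pytest.mark.parametrize("ties", ["efron", "breslow"])
def test_fit_matches_grid_search_oracle(ties):
    # interleaved covariate keeps the partial likelihood strictly concave
    # with an interior maximum (a covariate perfectly ordered with event
    # time is separated: the likelihood is monotone in beta)
    time = np.array([1.0, 2, 3, 4, 5, 6])
    event = np.ones(6, dtype=bool)
    x = np.array([1.0, 0, 1, 0, 0, 1])
    fit = fit_cox(time, event, x, ties=ties)
    grid = np.arange(-5, 5, 1e-4)
    lls = np.array([_brute_partial_loglik(b, time, event, x, ties) for b in grid])
    assert fit.beta[0] == pytest.approx(grid[lls.argmax()], abs=1e-3)
    assert fit.loglik == pytest.approx(lls.max(), abs=1e-6)


@pytest.mark.parametrize("ties", ["efron", "breslow"])
def test_fit_matches_grid_search_oracle_with_ties_and_censoring(ties):
    time = np.array([2.0, 2, 2, 3, 3, 5, 5, 7])
    event = np.array([1, 1, 0, 1, 1, 1, 0, 1], dtype=bool)
    x = np.array([0.5, 1, 0, 1, 0, 0, 1, 0])
    fit = fit_cox(time, event, x, ties=ties)
    grid = np.arange(-5, 5, 1e-4)
    lls = np.array([_brute_partial_loglik(b, time, event, x, ties) for b in grid])
    assert fit.beta[0] == pytest.approx(grid[lls.argmax()], abs=1e-3)


def test_fit_matches_lifelines_on_tied_data(rng):
    lifelines = pytest.importorskip("lifelines")
    n = 250
    X = rng.normal(size=(n, 2))
    T = np.ceil(rng.exponential(1 / (0.5 * np.exp(X @ [0.6, -0.4]))) * 4) / 4
    C = rng.uniform(0.25, 8, n)
    t, e = np.minimum(T, C), T <= C
    fit = fit_cox(t, e, X, names=["a", "b"])
    df = pd.DataFrame(X, columns=["a", "b"]).assign(t=t, e=e.astype(int))
    cph = lifelines.CoxPHFitter().fit(df, "t", "e")
    # lifelines stops at a looser gradient tolerance; agree to ~1e-4
    np.testing.assert_allclose(fit.beta, cph.params_.values, atol=1e-4)
    np.testing.assert_allclose(fit.se, cph.standard_errors_.values, atol=1e-4)
    assert fit.loglik == pytest.approx(cph.log_likelihood_, abs=1e-3)


def test_null_covariate_recovers_hr_one(rng):
    n = 3000
    x = rng.normal(size=n)
    T = rng.exponential(2.0, n)
    C = rng.uniform(0, 6, n)
    fit = fit_cox(np.minimum(T, C), T <= C, x)
    assert np.exp(fit.beta[0]) == pytest.approx(1.0, abs=0.08)


def test_parameter_recovery_within_3_se(rng):
    beta0 = np.log(1.9)
    n = 800
    x = rng.normal(size=n)
    T = rng.exponential(1 / (0.4 * np.exp(beta0 * x)))
    C = rng.uniform(0, 8, n)
    fit = fit_cox(np.minimum(T, C), T <= C, x)
    assert abs(fit.beta[0] - beta0) < 3 * fit.se[0]


def test_covariate_scaling_invariance(rng):
    n = 300
    x = rng.normal(size=n)
    T = rng.exponential(1 / (0.4 * np.exp(0.5 * x)))
    C = rng.uniform(0, 8, n)
    t, e = np.minimum(T, C), T <= C
    f1 = fit_cox(t, e, x)
    f10 = fit_cox(t, e, 10 * x)
    assert f10.beta[0] == pytest.approx(f1.beta[0] / 10, rel=1e-6)
    # HR per original unit unchanged
    assert np.exp(10 * f10.beta[0]) == pytest.approx(np.exp(f1.beta[0]), rel=1e-6)


def test_no_events_is_an_error():
    with pytest.raises(ValueError, match="event"):
        fit_cox([1.0, 2.0], [False, False], [0.0, 1.0])


def test_constant_covariate_rejected():
    time = np.array([1.0, 2, 3, 4, 5, 6])
    event = np.ones(6, dtype=bool)
    with pytest.raises(ValueError, match="constant"):
        fit_cox(time, event, np.zeros(6))


@pytest.mark.parametrize(
    "x", [[5.0, 4, 3, 2, 1, 0], [1.0, 1, 1, 0, 0, 0]], ids=["monotone", "grouped"]
)
def test_separation_flagged_not_reported(x):
    # a covariate perfectly ordered with event time has a monotone partial
    # likelihood; the fit must flag it instead of reporting a huge beta
    time = np.array([1.0, 2, 3, 4, 5, 6])
    event = np.ones(6, dtype=bool)
    fit = fit_cox(time, event, np.array(x))
    assert not fit.converged
    assert "separation" in fit.message or "diverging" in fit.message
    with pytest.raises(ValueError, match="non-converged"):
        hr_table(fit)


# ---------------------------------------------------------------------------
# baseline hazard and adjusted survival


def test_breslow_steps_two_subject_hand_computation():
    # two subjects, events at t=1,2, beta=0: risk sets of 2 then 1 give
    # cumulative-hazard steps 1/2 then 1/1, so S(1)=e^-0.5, S(2)=e^-1.5
    from cortisurv.survival import _breslow_baseline

    time = np.array([1.0, 2.0])
    event = np.array([True, True])
    X = np.array([[1.0], [0.0]])
    times, cumhaz = _breslow_baseline(np.zeros(1), time, event, X)
    np.testing.assert_allclose(times, [1.0, 2.0])
    np.testing.assert_allclose(cumhaz, [0.5, 1.5], atol=1e-12)
    np.testing.assert_allclose(np.exp(-cumhaz), [np.exp(-0.5), np.exp(-1.5)])


def test_breslow_baseline_equals_nelson_aalen_at_null(rng):
    # at beta = 0 with no ties the Breslow baseline is exactly Nelson–Aalen
    from cortisurv.survival import _breslow_baseline

    n = 400
    T = rng.exponential(2.0, n)
    C = rng.uniform(0, 5, n)
    t, e = np.minimum(T, C), T <= C
    order = np.argsort(t, kind="stable")
    ts, es = t[order], e[order]
    X = rng.normal(size=(n, 1))[order]
    times, cumhaz = _breslow_baseline(np.zeros(1), ts, es, X)
    na_steps = []
    for ti in times:
        at_risk = (ts >= ti).sum()
        na_steps.append((es & (ts == ti)).sum() / at_risk)
    np.testing.assert_allclose(cumhaz, np.cumsum(na_steps), rtol=1e-10)


def test_adjusted_survival_contract(rng):
    n = 200
    x = rng.normal(size=n)
    T = rng.exponential(1 / (0.4 * np.exp(0.5 * x)))
    C = rng.uniform(0, 8, n)
    fit = fit_cox(np.minimum(T, C), T <= C, x, names=["slope"])
    for val in (-1.3, 0.0, 0.7):
        curve = adjusted_survival(fit, {"slope": val})
        assert curve["survival"].iloc[0] == 1.0
        assert (np.diff(curve["survival"]) <= 1e-12).all()
        assert (curve["survival"] >= 0).all()
    with pytest.raises(KeyError):
        adjusted_survival(fit, {"slope": 0.0, "extra": 1.0})
    with pytest.raises(KeyError):
        adjusted_survival(fit, {})


# ---------------------------------------------------------------------------
# reporting


def _fake_fit(names, beta, se):
    p = len(names)
    return CoxFit(
        names=names, beta=np.array(beta, dtype=float), se=np.array(se, dtype=float),
        loglik=0.0, ties="efron", converged=True, n=10, n_events=5,
        baseline_times=np.array([1.0]), baseline_cumhaz=np.array([0.1]),
        n_iter=1, cov=np.eye(p),
    )


def test_hr_table_reproduces_published_arithmetic():
    # exp of multivariate coefficients reproduces the reported hazard ratios
    fit = _fake_fit(["poor", "intermediate", "slope", "cesd"],
                    [0.83, 0.42, 0.67, 0.27], [0.29, 0.28, 0.22, 0.31])
    tbl = hr_table(fit).set_index("covariate")
    assert round(tbl.loc["poor", "hr"], 2) == 2.29
    assert round(tbl.loc["intermediate", "hr"], 2) == 1.52
    assert tbl.loc["slope", "hr"] == pytest.approx(1.96, abs=0.02)
    assert tbl.loc["cesd", "hr"] == pytest.approx(1.32, abs=0.02)
    assert round(tbl.loc["slope", "ci_low"], 1) == 1.3
    assert round(tbl.loc["slope", "ci_high"], 1) == 3.0
    assert tbl.loc["slope", "p"] < 0.01


def test_compare_mediation_identical_fits_attenuation_zero():
    f = _fake_fit(["cesd"], [0.5], [0.2])
    res = compare_mediation(f, f, "cesd")
    assert res.attenuation == 0.0


def test_compare_mediation_published_attenuation():
    # univariate log HR ln(1.75) shrinking to ln(1.32) attenuates ~50%
    f0 = _fake_fit(["cesd"], [np.log(1.75)], [0.28])
    f1 = _fake_fit(["cesd", "slope"], [np.log(1.32), np.log(1.96)], [0.31, 0.22])
    res = compare_mediation(f0, f1, "cesd")
    assert res.attenuation == pytest.approx(0.504, abs=0.005)
    assert res.hr_adjusted < res.hr_unadjusted
    with pytest.raises(KeyError):
        compare_mediation(f0, f1, "absent")


def test_mediation_structured_cohort_shows_attenuation(rng):
    # depression -> flatter slope -> hazard: adjusting for the mediator
    # shrinks the exposure coefficient while the mediator stays significant
    n = 2500
    dep = (rng.random(n) < 0.3).astype(float)
    slope = rng.normal(-0.7 + 0.5 * dep, 0.4)
    lp = 0.9 * (slope + 0.7)
    T = rng.exponential(1 / (0.4 * np.exp(lp)))
    C = rng.uniform(0, 8, n)
    t, e = np.minimum(T, C), T <= C
    X = np.column_stack([dep, slope])
    f0 = fit_cox(t, e, dep[:, None], names=["dep"])
    f1 = fit_cox(t, e, X, names=["dep", "slope"])
    res = compare_mediation(f0, f1, "dep")
    assert res.hr_adjusted < res.hr_unadjusted
    assert res.attenuation > 0.3
    slope_p = hr_table(f1).set_index("covariate").loc["slope", "p"]
    assert slope_p < 0.01


# ---------------------------------------------------------------------------
# cohort summary


def test_cohort_summary_correlations(rng, default_cohort):
    df = pd.DataFrame({"a": rng.normal(size=4000), "b": rng.normal(size=4000)})
    desc, corr = cohort_summary(df)
    assert corr.loc["a", "a"] == pytest.approx(1.0)
    assert abs(corr.loc["a", "b"]) < 0.05
    desc, corr = cohort_summary(default_cohort.patients[["age", "cesd", "depressed"]])
    frac = desc.loc["depressed", "percent"] / 100
    assert frac == pytest.approx(0.23, abs=3 * np.sqrt(0.23 * 0.77 / 202))
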