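import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from bonestrain.phantom import CohortSpec, generate_cohort
from bonestrain.survival import (cox_fit, km_estimate, lsc, ph_test,
                                 power_schoenfeld)

# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def test_km_no_events_stays_at_one():
    km = km_estimate([5.0, 8.0, 12.0], [0, 0, 0])
    assert km.times.size == 0
    assert km.survival_at(100.0) == 1.0


def test_km_all_events_no_censoring_closed_form():
    km = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
    assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])


def test_km_hand_computed_table_with_censoring():
    # times 2, 3+, 5, 5, 8+, 10: risk sets 6, 4, 1
    times = [2.0, 3.0, 5.0, 5.0, 8.0, 10.0]
    events = [1, 0, 1, 1, 0, 1]
    km = km_estimate(times, events)
    assert np.allclose(km.times, [2.0, 5.0, 10.0])
    assert np.allclose(km.survival, [5 / 6, 5 / 6 * 2 / 4, 0.0])
    assert list(km.at_risk) == [6, 4, 1]
    # Greenwood at the first event time: S * sqrt(d / (n (n - d)))
    assert km.std_err[0] == pytest.approx(5 / 6 * np.sqrt(1 / 30))


def test_km_without_censoring_equals_empirical_survival():
    rng = np.random.default_rng(3)
    t = rng.exponential(100.0, size=200)
    km = km_estimate(t, np.ones_like(t))
    for q in (50.0, 100.0, 200.0):
        assert km.survival_at(q) == pytest.approx(np.mean(t > q))


def test_km_ci_clips_at_one():
    times = [50.0] + [100.0] * 19
    events = [1] + [0] * 19
    km = km_estimate(times, events)
    raw_upper = km.survival[0] + 1.959963985 * km.std_err[0]
    assert raw_upper > 1.0
    assert km.ci_high[0] == 1.0
    assert km.ci_low[0] < km.survival[0]


def test_km_reliability_flag_tracks_at_risk_fraction():
    # 10 subjects; events at 1..8 leave < 20% at risk from the 9th onward
    times = np.arange(1.0, 11.0)
    km = km_estimate(times, np.ones(10))
    assert km.reliable[0]
    assert not km.reliable[-1]
    np.testing.assert_array_equal(km.reliable, km.at_risk >= 2)


def test_km_matches_lifelines():
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(11)
    t = rng.exponential(300.0, 150)
    c = rng.uniform(100, 600, 150)
    obs = np.minimum(t, c)
    e = t <= c
    km = km_estimate(obs, e)
    ref = lifelines.KaplanMeierFitter().fit(obs, e)
    got = ref.survival_function_.loc[km.times, "KM_estimate"].to_numpy()
    assert np.allclose(km.survival, got, atol=1e-12)


def test_km_negative_times_rejected():
    with pytest.raises(ValueError):
        km_estimate([-1.0, 2.0], [1, 1])


# ---------------------------------------------------------------------------
# Cox regression
# ---------------------------------------------------------------------------

N5_TIMES = np.array([2.0, 5.0, 7.0, 11.0, 13.0])
N5_EVENTS = np.array([1, 0, 1, 1, 0], dtype=bool)
N5_X = np.array([0.5, -1.2, 0.3, 1.0, -0.4])


def brute_force_beta():
    """Direct maximization of the written-out partial likelihood."""
    def nll(b):
        ll = 0.0
        for i in range(len(N5_TIMES)):
            if N5_EVENTS[i]:
                risk = N5_TIMES >= N5_TIMES[i]
                ll += b * N5_X[i] - np.log(np.sum(np.exp(b * N5_X[risk])))
        return -ll
    res = optimize.minimize_scalar(nll, bounds=(-10, 10), method="bounded",
                                   options={"xatol": 1e-12})
    return res.x


def test_cox_newton_matches_brute_force_partial_likelihood():
    fit = cox_fit((N5_X[:, None], N5_TIMES, N5_EVENTS))
    assert fit.beta[0] == pytest.approx(brute_force_beta(), abs=1e-6)


def test_breslow_equals_efron_without_ties():
    fb = cox_fit((N5_X[:, None], N5_TIMES, N5_EVENTS), ties="breslow")
    fe = cox_fit((N5_X[:, None], N5_TIMES, N5_EVENTS), ties="efron")
    assert fb.beta[0] == pytest.approx(fe.beta[0], abs=1e-6)


def test_cox_null_covariate_gives_unit_hazard_ratio():
    df = generate_cohort(CohortSpec(n_patients=2000, seed=5))
    fit = cox_fit(df, ["bsi"])
    assert abs(fit.beta[0]) < 3 * fit.se[0]
    assert fit.hr[0] == pytest.approx(1.0, abs=0.15)


def test_cox_fit_is_local_maximum():
    df = generate_cohort(CohortSpec(n_patients=300, seed=9))
    fit = cox_fit(df, ["bsi", "bmd"])
    from bonestrain.survival import _cox_arrays, _partial_loglik
    X, t, e = _cox_arrays(df, ["bsi", "bmd"])
    order = np.argsort(t, kind="stable")
    X, t, e = X[order], t[order], e[order]
    Xc = X - X.mean(axis=0)
    ll_hat = _partial_loglik(fit.beta, Xc, t, e, "breslow")[0]
    for j in range(2):
        for delta in (-0.01, 0.01):
            b = fit.beta.copy()
            b[j] += delta
            assert _partial_loglik(b, Xc, t, e, "breslow")[0] <= ll_hat + 1e-12


def test_cox_matches_lifelines_with_ties():
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(21)
    n = 300
    x = rng.normal(size=(n, 2))
    lam = 0.01 * np.exp(x @ [0.4, -0.2])
    t = np.ceil(rng.exponential(1 / lam))      # integer times force ties
    e = rng.random(n) < 0.8
    df = pd.DataFrame({"a": x[:, 0], "b": x[:, 1], "T": t, "E": e})
    fit = cox_fit((x, t, e), covariate_names=["a", "b"], ties="efron")
    ref = lifelines.CoxPHFitter().fit(df, "T", "E")
    assert np.allclose(fit.beta, ref.params_.to_numpy(), atol=2e-4)
    assert np.allclose(fit.se, ref.standard_errors_.to_numpy(), atol=2e-4)


def test_cox_confidence_interval_shape():
    fit = cox_fit((N5_X[:, None], N5_TIMES, N5_EVENTS))
    assert fit.ci_low[0] == pytest.approx(np.exp(fit.beta[0] - 1.959963985 * fit.se[0]),
                                          rel=1e-6)
    assert fit.hr[0] > 0 and fit.ci_low[0] < fit.hr[0] < fit.ci_high[0]


def test_cox_requires_two_events():
    with pytest.raises(ValueError, match="events"):
        cox_fit((N5_X[:, None], N5_TIMES, np.array([1, 0, 0, 0, 0], bool)))


def test_cox_rejects_missing_covariates():
    df = generate_cohort(CohortSpec(n_patients=50, seed=2, tbs_missing_rate=0.3))
    with pytest.raises(ValueError, match="finite"):
        cox_fit(df, ["tbs"])
    fit = cox_fit(df.dropna(subset=["tbs"]), ["tbs"])
    assert fit.n < 50


# ---------------------------------------------------------------------------
# Proportional-hazards test
# ---------------------------------------------------------------------------

def test_ph_test_matches_lifelines_identity_transform():
    lifelines = pytest.importorskip("lifelines")
    from lifelines.statistics import proportional_hazard_test

    df = generate_cohort(CohortSpec(n_patients=400, seed=17))
    fit = cox_fit(df, ["bsi", "bmd"], ties="efron")
    mine = ph_test(fit, df, ["bsi", "bmd"], transform="identity")

    ldf = df[["bsi", "bmd", "time_days", "event"]]
    cph = lifelines.CoxPHFitter().fit(ldf, "time_days", "event")
    ref = proportional_hazard_test(cph, ldf, time_transform="identity")
    assert np.allclose(np.sort(mine), np.sort(ref.summary["p"].to_numpy()),
                       atol=1e-3)


def test_ph_test_detects_time_varying_effect():
    rng = np.random.default_rng(0)
    n = 2000
    x = rng.normal(size=n)
    h0, t0, b1, b2 = 0.002, 400.0, 0.5, -0.5
    E = -np.log(rng.uniform(size=n))
    lam1 = h0 * np.exp(b1 * x)
    t = np.where(E < lam1 * t0, E / lam1,
                 t0 + (E - lam1 * t0) / (h0 * np.exp(b2 * x)))
    c = rng.uniform(300, 3000, n)
    obs, e = np.minimum(t, c), t <= c
    fit = cox_fit((x[:, None], obs, e))
    assert ph_test(fit, (x[:, None], obs, e))[0] < 1e-6


def test_ph_test_requires_three_events():
    with pytest.raises(ValueError, match="3 events"):
        fit = cox_fit((N5_X[:, None], N5_TIMES, N5_EVENTS))
        ph_test(fit, (N5_X[:, None], N5_TIMES,
                      np.array([1, 0, 1, 0, 0], bool)))


# ---------------------------------------------------------------------------
# Power and LSC
# ---------------------------------------------------------------------------

def test_power_monotone_in_events_effect_and_sd():
    base = power_schoenfeld(61, 1.35, 1.35)
    assert power_schoenfeld(122, 1.35, 1.35) > base
    assert power_schoenfeld(61, 1.5, 1.35) > base
    assert power_schoenfeld(61, 1.35, 2.0) > base


def test_power_zero_effect_limit():
    # HR -> 1 drives the noncentrality to 0: power -> Phi(-z) = alpha/2
    p = power_schoenfeld(61, 1.0 + 1e-12, 1.35, alpha=0.05)
    assert p == pytest.approx(stats.norm.cdf(-stats.norm.ppf(0.975)), abs=1e-6)


def test_power_closed_form():
    d, hr, sd = 61, 1.35, 1.35
    expected = stats.norm.cdf(np.sqrt(d * sd ** 2 * np.log(hr) ** 2)
                              - stats.norm.ppf(0.975))
    assert power_schoenfeld(d, hr, sd) == pytest.approx(expected, rel=1e-12)


def test_power_input_validation():
    with pytest.raises(ValueError):
        power_schoenfeld(61, -1.0, 1.35)
    with pytest.raises(ValueError):
        power_schoenfeld(61, 1.0, 1.35)
    with pytest.raises(ValueError):
        power_schoenfeld(0, 1.35, 1.35)


def test_lsc_definition_and_linearity():
    assert lsc(0.0) == 0.0
    assert lsc(1.0) == pytest.approx(2.77)
    # a precision error three times larger gives an LSC three times larger
    assert lsc(3.0) / lsc(1.0) == pytest.approx(3.0)
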