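import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cnaload.survival import (SurvivalError, cox_fit, enrichment_tests,
                              interaction_analysis, is_hypermutator,
                              km_estimate, mrecist_and_logrank, mrecist_call,
                              power_twoarm, simulate_twoarm_times,
                              stratified_effect)
from cnaload.synthetic import simulate_exponential_survival


# ---------------------------------------------------------------------------
# Kaplan-Meier

def test_km_without_censoring_is_empirical_survival():
    df = pd.DataFrame({"time": np.arange(1, 11), "event": 1})
    res = km_estimate(df)[None]
    curve = res["curve"].set_index("time")["survival"]
    # steps of 0.1 at each event time; median at first S(t) <= 0.5
    assert curve.loc[1.0] == pytest.approx(0.9)
    assert curve.loc[10.0] == pytest.approx(0.0)
    assert res["median"] == 5


def test_km_all_censored_is_flat_one():
    df = pd.DataFrame({"time": [5.0, 7.0, 9.0], "event": 0})
    res = km_estimate(df)[None]
    assert (res["curve"]["survival"] == 1.0).all()
    assert np.isinf(res["median"])


def test_km_median_matches_exponential_closed_form(rng):
    lam = 0.2
    df = pd.DataFrame({"time": rng.exponential(1 / lam, 5000), "event": 1})
    res = km_estimate(df)[None]
    assert res["median"] == pytest.approx(np.log(2) / lam, rel=0.03)


# ---------------------------------------------------------------------------
# Cox fits

def test_null_two_arm_cox_is_near_one(rng):
    times, event, arm = simulate_twoarm_times(2000, 2000, 1.0, rng)
    df = pd.DataFrame({"time": times, "event": event, "bvz": arm})
    est = cox_fit(df, covariates=["bvz"])[0]
    assert 0.93 <= est.hazard_ratio <= 1.08
    assert est.ci_low <= est.hazard_ratio <= est.ci_high


def test_cox_recovers_binary_hazard_ratio(rng):
    times, event, arm = simulate_twoarm_times(2500, 2500, 0.5, rng)
    df = pd.DataFrame({"time": times, "event": event, "x": arm})
    est = cox_fit(df, covariates=["x"])[0]
    assert est.hazard_ratio == pytest.approx(0.5, abs=0.05)


def test_insufficient_events_raise():
    df = pd.DataFrame({"time": [1.0], "event": [1], "x": [0]})
    with pytest.raises(SurvivalError):
        cox_fit(df, covariates=["x"])


def test_constant_covariate_raises(rng):
    df = pd.DataFrame({"time": rng.exponential(1, 50), "event": 1, "x": 1})
    with pytest.raises(SurvivalError):
        cox_fit(df, covariates=["x"])


# ---------------------------------------------------------------------------
# interaction and stratified effects

def _two_stratum_cohort(rng, n=1200, hr_arm=1.0, hr_int=1.0):
    stratum = rng.integers(0, 2, n)
    arm = rng.integers(0, 2, n)
    lp = arm * np.log(hr_arm) + arm * stratum * np.log(hr_int) + 0.3 * stratum
    t, e = simulate_exponential_survival(lp, 0.1, None, rng)
    return pd.DataFrame({"time": t, "event": e, "bvz": arm, "cluster": stratum + 1})


def test_interaction_model_matches_stratified_fits(rng):
    """In the saturated two-stratum case the interaction model reproduces the
    per-stratum treatment effects."""
    df = _two_stratum_cohort(rng, n=4000, hr_arm=0.9, hr_int=0.6)
    strat = stratified_effect(df, "cluster")
    full = cox_fit(
        df.assign(cluster_2=(df["cluster"] == 2).astype(int),
                  bvz_x=(df["cluster"] == 2).astype(int) * df["bvz"]),
        covariates=["bvz", "cluster_2", "bvz_x"])
    by_term = {e.term: e for e in full}
    hr_s1 = by_term["bvz"].hazard_ratio
    hr_s2 = by_term["bvz"].hazard_ratio * by_term["bvz_x"].hazard_ratio
    assert hr_s1 == pytest.approx(strat[1].hazard_ratio, rel=0.05)
    assert hr_s2 == pytest.approx(strat[2].hazard_ratio, rel=0.05)


def test_interaction_null_p_values_are_uniform(rng):
    """With no generative interaction, interaction p-values are U(0,1)."""
    pvals = []
    for _ in range(200):
        df = _two_stratum_cohort(rng, n=300)
        est = interaction_analysis(df, stratum_col="cluster")
        pvals.append(est[0].p_value)
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


def test_interaction_recovery_of_generative_hr(rng):
    """An interaction hazard ratio of 0.49 is recovered at n = 2000."""
    hrs = []
    for _ in range(40):
        df = _two_stratum_cohort(rng, n=2000, hr_arm=1.0, hr_int=0.49)
        hrs.append(interaction_analysis(df, stratum_col="cluster")[0].hazard_ratio)
    assert np.mean(hrs) == pytest.approx(0.49, abs=0.07)


def test_null_stratum_effect_is_near_one(rng):
    df = _two_stratum_cohort(rng, n=3000)
    strat = stratified_effect(df, "cluster")
    for est in strat.values():
        assert 0.85 <= est.hazard_ratio <= 1.17


def test_missing_arm_stratum_is_skipped(rng):
    df = _two_stratum_cohort(rng, n=200)
    df.loc[df["cluster"] == 2, "bvz"] = 1
    with pytest.warns(UserWarning, match="one treatment arm"):
        out = stratified_effect(df, "cluster")
    assert 2 not in out


def test_empty_interaction_cell_is_an_error(rng):
    df = _two_stratum_cohort(rng, n=200)
    df.loc[df["cluster"] == 2, "bvz"] = 1
    with pytest.raises(SurvivalError, match="empty cell"):
        interaction_analysis(df, stratum_col="cluster")


# ---------------------------------------------------------------------------
# power

def test_power_at_null_equals_alpha():
    assert power_twoarm(100, 100, 1.0, alpha=0.05) == pytest.approx(0.05)


def test_schoenfeld_formula_example():
    # d = 211 events, equal allocation, HR 0.68 -> approximately 80% power
    p = power_twoarm(106, 105, 0.68, alpha=0.05, event_fraction=1.0)
    phi = stats.norm.cdf
    d, frac = 211, 106 / 211
    delta = np.sqrt(d * frac * (1 - frac)) * abs(np.log(0.68))
    z = stats.norm.ppf(0.975)
    assert p == pytest.approx(phi(delta - z) + phi(-delta - z), abs=1e-9)
    assert p == pytest.approx(0.80, abs=0.01)


def test_power_is_monotone_in_hazard_ratio():
    hrs = [0.5, 0.6, 0.7, 0.8, 0.9]
    powers = [power_twoarm(150, 150, h) for h in hrs]
    assert all(a > b for a, b in zip(powers, powers[1:]))
    assert power_twoarm(5000, 5000, 0.7) > 0.999


def test_simulated_power_agrees_with_schoenfeld():
    analytic = power_twoarm(120, 120, 0.65)
    simulated = power_twoarm(120, 120, 0.65, mode="simulate", seed=11,
                             n_reps=2000)
    assert simulated == pytest.approx(analytic, abs=0.02)


def test_invalid_power_inputs_raise():
    with pytest.raises(SurvivalError):
        power_twoarm(1, 100, 0.5)
    with pytest.raises(SurvivalError):
        power_twoarm(100, 100, -1)


# ---------------------------------------------------------------------------
# enrichment tests

def test_balanced_table_fisher_p_is_one():
    labels = pd.Series([1] * 100 + [2] * 100)
    flags = pd.DataFrame({"msi": [True] * 50 + [False] * 50 +
                                 [True] * 50 + [False] * 50})
    res = enrichment_tests(labels, flags=flags)["fisher"]
    assert (res["p_value"] == 1.0).all()


def test_fisher_matches_hypergeometric_enumeration():
    """[[10,0],[0,10]] against a brute-force hypergeometric oracle."""
    labels = pd.Series([1] * 10 + [2] * 10)
    flags = pd.DataFrame({"mut": [True] * 10 + [False] * 10})
    res = enrichment_tests(labels, flags=flags)["fisher"]
    p = res.loc[res["cluster"] == 1, "p_value"].iloc[0]
    # oracle: sum of P(X = x) over all tables at least as extreme
    pmf = [stats.hypergeom.pmf(x, 20, 10, 10) for x in range(11)]
    p_obs = pmf[10]
    oracle = sum(px for px in pmf if px <= p_obs + 1e-12)
    assert p == pytest.approx(oracle, rel=1e-6)
    assert p == pytest.approx(1.08e-5, rel=0.01)


def test_chisquare_on_clinical_variables(rng):
    labels = pd.Series(rng.choice([1, 2, 3], 300))
    clinical = pd.DataFrame({"t_stage": rng.choice([1, 2, 3, 4], 300)})
    res = enrichment_tests(labels, clinical=clinical)["chisq"]
    assert len(res) == 1 and 0 <= res["p_value"].iloc[0] <= 1


def test_hypermutator_rule_is_strict():
    assert is_hypermutator(11.0)
    assert not is_hypermutator(10.0)


# ---------------------------------------------------------------------------
# mRECIST

def test_halving_is_regression():
    call = mrecist_call([0, 7], [250, 100])
    assert call.best_response == "regression"


def test_thirtyfive_percent_growth_is_progression():
    call = mrecist_call([0, 10], [250, 340])
    assert call.best_response == "progression"
    assert call.time_to_progression == 10
    assert call.progressed


def test_flat_series_is_stable_and_censored():
    call = mrecist_call([0, 7, 14, 21], [250, 251, 249, 250])
    assert call.best_response == "stable"
    assert not call.progressed
    assert call.time_to_progression == 21


def test_regression_before_progression_is_regression():
    call = mrecist_call([0, 7, 14, 21], [250, 120, 200, 400])
    assert call.best_response == "regression"
    assert call.progressed and call.time_to_progression == 21


def test_mrecist_matches_analytic_crossing_on_noiseless_growth():
    from cnaload.synthetic import simulate_xenograft_series
    series = simulate_xenograft_series(n_per_arm=3, growth_rate=0.08,
                                       rate_sd=0.0, measurement_sd=0.0,
                                       seed=0)
    t_star = np.log(1.35) / 0.08  # analytic progression crossing
    res = mrecist_and_logrank({"control": series["control"],
                               "treated": series["treated"]})
    days = np.sort(series["control"]["day"].unique())
    expected_day = days[days >= t_star][0]
    for call in res["calls"]["control"]:
        assert call.progressed and call.time_to_progression == expected_day
    assert 0 <= res["logrank_p"] <= 1


def test_shrinking_arm_regresses_and_differs_by_logrank():
    from cnaload.synthetic import simulate_xenograft_series
    series = simulate_xenograft_series(
        n_per_arm=6, growth_rate=0.08, rate_sd=0.005,
        effect_multipliers={"control": 1.0, "combo": -0.9},
        measurement_sd=0.02, seed=3)
    res = mrecist_and_logrank(series)
    combo = res["calls"]["combo"]
    assert all(c.best_response == "regression" for c in combo)
    assert res["logrank_p"] < 0.01
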