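"""Exceedance counting, attributable cases, annual models, sensitivity tools."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from airlag import DailySeries
from airlag.burden import (annual_stratified_rr, attributable_cases,
                           count_exceedance_days, df_sensitivity, percent_change,
                           rr_trend_test, two_pollutant_fit)
from airlag.effects import rr_table
from airlag.glm import ModelSpec, fit_model

from conftest import indicator_cb


def _mini_series(pm25, admissions=None, start="2021-01-01"):
    n = len(pm25)
    df = pd.DataFrame({
        "date": pd.date_range(start, periods=n),
        "pm25": np.asarray(pm25, dtype=float),
        "pm10": 1.0, "so2": 1.0, "no2": 1.0, "o3": 1.0, "co": 1.0,
        "at": 10.0, "rh": 50.0,
    })
    if admissions is not None:
        df["admissions"] = admissions
    return DailySeries(df)


def test_exceedance_hand_count_strict_inequality():
    s = _mini_series([20.0, 30.0, 26.0, 25.0])
    assert count_exceedance_days(s, "pm25", 25.0, by_year=False) == 2


def test_all_below_threshold_gives_zero():
    s = _mini_series([10.0] * 30)
    assert count_exceedance_days(s, "pm25", 25.0, by_year=False) == 0


def test_exceedance_grouped_by_calendar_year():
    s = _mini_series([80.0] * 400, start="2021-06-01")
    out = count_exceedance_days(s, "pm25", 75.0)
    assert out.loc[2021] + out.loc[2022] == 400


def test_attribution_single_day_direct_evaluation():
    """n=20, C=35, threshold=25, beta=0.001: AN = 20 (1 - e^{-0.01})."""
    s = _mini_series([35.0], admissions=[20])
    row = attributable_cases(s, "pm25", 25.0, 0.001)[0]
    assert abs(row.excess_cases - 20.0 * (1 - np.exp(-0.01))) < 1e-10
    assert row.n_exceedance_days == 1


@pytest.mark.parametrize("beta,pm", [(0.0, [40.0, 90.0]), (0.002, [10.0, 20.0])])
def test_attribution_trivial_zero_cases(beta, pm):
    s = _mini_series(pm, admissions=[5, 7])
    rows = attributable_cases(s, "pm25", 25.0, beta)
    assert all(r.excess_cases == 0.0 for r in rows)


def test_attribution_matches_brute_force_day_loop():
    rng = np.random.default_rng(0)
    pm = rng.gamma(3.0, 25.0, 730)
    adm = rng.poisson(20, 730)
    s = _mini_series(pm, admissions=adm)
    beta, thr = 0.00095, 35.0
    rows = attributable_cases(s, "pm25", thr, beta)
    expected = {}
    for date, c, n in zip(s.df["date"], pm, adm):
        if c > thr:
            rr = np.exp(beta * (c - thr))
            expected[date.year] = expected.get(date.year, 0.0) + n * (rr - 1) / rr
    for row in rows:
        assert abs(row.excess_cases - expected.get(row.year, 0.0)) < 1e-10


@settings(deadline=None, derandomize=True, max_examples=30)
@given(
    thr1=st.floats(5.0, 60.0),
    delta=st.floats(0.1, 40.0),
    beta=st.floats(1e-5, 5e-3),
    seed=st.integers(0, 100),
)
def test_raising_threshold_never_increases_burden(thr1, delta, beta, seed):
    rng = np.random.default_rng(seed)
    s = _mini_series(rng.gamma(3.0, 25.0, 200), admissions=rng.poisson(15, 200))
    lo = attributable_cases(s, "pm25", thr1, beta, by_year=False)[0]
    hi = attributable_cases(s, "pm25", thr1 + delta, beta, by_year=False)[0]
    assert hi.n_exceedance_days <= lo.n_exceedance_days
    assert hi.excess_cases <= lo.excess_cases + 1e-12


def test_threshold_below_all_days_everything_contributes():
    rng = np.random.default_rng(1)
    s = _mini_series(rng.gamma(3.0, 25.0, 100) + 5.0, admissions=rng.poisson(15, 100) + 1)
    rows = attributable_cases(s, "pm25", 1.0, 0.001, by_year=False)
    assert rows[0].n_exceedance_days == 100
    assert rows[0].excess_cases > 0


def test_burden_bounded_by_total_admissions():
    rng = np.random.default_rng(2)
    adm = rng.poisson(15, 365)
    s = _mini_series(rng.gamma(3.0, 25.0, 365), admissions=adm)
    row = attributable_cases(s, "pm25", 25.0, 0.01, by_year=False)[0]
    assert 0 <= row.excess_cases <= adm.sum()


@pytest.mark.parametrize("before,after,display,headline", [
    (85.33, 46.04, 46.0, 46),   # PM2.5 annual means, first vs last year
    (33.07, 4.91, 85.2, 85),    # SO2 annual means
    (8183.0, 5146.0, 37.1, 37), # excess cases under the WHO target
    (12.0, 12.0, 0.0, 0),
])
def test_percent_change_worked_examples(before, after, display, headline):
    pc = percent_change(before, after)
    assert pc.display == display
    assert pc.headline == headline


def test_percent_change_requires_positive_baseline():
    with pytest.raises(ValueError, match="positive"):
        percent_change(0.0, 5.0)


def test_two_pollutant_gate_refuses_strongly_correlated_pair(small_panel):
    with pytest.raises(ValueError, match="not below the gate"):
        two_pollutant_fit(small_panel, "pm25", "pm10")


def test_two_pollutant_reports_both_models(small_panel):
    res = two_pollutant_fit(small_panel, "so2", "o3")
    assert abs(res.spearman_rho) < 0.6
    assert res.single.pollutant == "so2"
    assert res.adjusted.pollutant == "so2"
    assert res.co_adjusted.pollutant == "o3"
    assert res.single.lo95 <= res.single.rr <= res.single.hi95


def test_df_sweep_deterministic_and_consistent_with_main_fit(small_panel):
    cb = indicator_cb()
    tab1 = df_sensitivity(small_panel, "pm25", df_range=range(6, 9), cb_spec=cb)
    tab2 = df_sensitivity(small_panel, "pm25", df_range=range(6, 9), cb_spec=cb)
    pd.testing.assert_frame_equal(tab1, tab2)
    # the df=7 row reproduces the main-analysis estimate exactly
    main = fit_model(small_panel, ModelSpec(pollutant_terms={"pm25": cb},
                                            time_df_per_year=7.0))
    lag0 = next(e for e in rr_table(main, "pm25") if e.lag_def == "lag0")
    row7 = tab1[tab1["time_df_per_year"] == 7].iloc[0]
    assert row7["rr"] == pytest.approx(lag0.rr, abs=1e-12)


def test_annual_models_return_one_rr_per_year(small_panel):
    ann = annual_stratified_rr(small_panel, "pm25", lag=0, cb_spec=indicator_cb())
    assert [a.year for a in ann] == sorted(small_panel.years.unique())
    for a in ann:
        assert a.lo95 <= a.rr <= a.hi95
        assert a.significant == (a.lo95 > 1.0 or a.hi95 < 1.0)


def test_trend_test_reports_weighted_slope(small_panel):
    ann = annual_stratified_rr(small_panel, "pm25", lag=0, cb_spec=indicator_cb())
    out = rr_trend_test(ann)
    assert set(out) == {"slope", "se", "z", "p", "spearman_rho"}
    assert out["se"] > 0 and 0 <= out["p"] <= 1
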