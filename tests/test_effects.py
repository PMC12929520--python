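"""RR tables, exposure-response curves, rank correlations, descriptives."""

import numpy as np
import pandas as pd
import pytest

from airlag import DailySeries, ModelSpec, fit_model
from airlag.crossbasis import CrossBasisSpec
from airlag.effects import (descriptive_table, exposure_response_curve, rr_table,
                            spearman_matrix)
from airlag.glm import FitResult
from airlag.simulate import PollutantParams, SimulationConfig, simulate_panel
from airlag.splines import BasisSpec

from conftest import indicator_cb


def _manual_fit(theta, cov, spec, pollutant="pm25"):
    k = theta.size
    return FitResult(
        coefficients=theta, covariance=cov, dispersion=1.0, deviance=0.0,
        n_used=100, df_residual=100 - k,
        column_map={pollutant: np.arange(k)},
        col_names=[f"cb({pollutant})[{j}]" for j in range(k)],
        n_iter=1, converged=True, resolved={pollutant: spec},
    )


@pytest.fixture(scope="module")
def resolved_indicator():
    from airlag.crossbasis import build_cross_basis

    x = np.random.default_rng(0).gamma(3, 20, 400)
    _, spec = build_cross_basis(x, indicator_cb(7))
    return spec


def test_null_coefficients_give_unit_rr_with_degenerate_ci(resolved_indicator):
    fit = _manual_fit(np.zeros(8), np.zeros((8, 8)), resolved_indicator)
    for est in rr_table(fit, "pm25"):
        assert est.rr == est.lo95 == est.hi95 == 1.0


def test_reported_rr_orientation_round_trip(resolved_indicator):
    """A lag-0 coefficient of log(1.0099)/10 per unit prints RR 1.0099 per 10."""
    theta = np.zeros(8)
    theta[0] = np.log(1.0099) / 10.0
    fit = _manual_fit(theta, np.zeros((8, 8)), resolved_indicator)
    lag0 = next(e for e in rr_table(fit, "pm25", increment=10.0) if e.lag_def == "lag0")
    assert round(lag0.rr, 4) == 1.0099


def test_flat_lag_profile_cumulative_rr_closed_form(resolved_indicator):
    b = 0.002
    fit = _manual_fit(np.full(8, b), 1e-8 * np.eye(8), resolved_indicator)
    cum = next(e for e in rr_table(fit, "pm25", increment=10.0) if e.lag_def == "lag07")
    assert abs(cum.rr - np.exp(8 * 10 * b)) < 1e-8


def test_ci_symmetric_on_log_scale(small_fit):
    for est in rr_table(small_fit, "pm25"):
        if est.se == 0:
            continue
        up = np.log(est.hi95) - est.log_rr
        dn = est.log_rr - np.log(est.lo95)
        assert abs(up - dn) < 1e-10
        assert est.lo95 <= est.rr <= est.hi95


def test_spline_exposure_basis_refused_for_increment_rrs(small_panel):
    spec = CrossBasisSpec(max_lag=7, var_basis=BasisSpec(kind="ns", df=3))
    fit = fit_model(small_panel, ModelSpec(pollutant_terms={"pm25": spec}))
    with pytest.raises(ValueError, match="linear exposure basis"):
        rr_table(fit, "pm25")


def test_curve_is_one_at_center(small_panel):
    x = small_panel.df["pm25"]
    spec = CrossBasisSpec(max_lag=7, var_basis=BasisSpec(kind="ns", df=3),
                          center=float(x.min()))
    fit = fit_model(small_panel, ModelSpec(pollutant_terms={"pm25": spec}))
    curve = exposure_response_curve(fit, "pm25", [float(x.min()), 50.0, 100.0])
    assert abs(curve["RR"].iloc[0] - 1.0) < 1e-12


def test_monotone_truth_gives_monotone_fitted_curve():
    """Linear positive truth: fitted spline curve rank-correlates with exposure."""
    from scipy.stats import spearmanr

    cfg = SimulationConfig(
        n_years=8,
        pollutant_params={"pm25": PollutantParams(57.6, 47.9, 0.45, 15, 0.6)},
        true_effects={"pm25": np.array([np.log(1.01) / 10.0])},
        season_count_amplitude=0.15, dispersion=1.3, seed=12,
    )
    panel = simulate_panel(cfg)
    spec = CrossBasisSpec(max_lag=7, var_basis=BasisSpec(kind="ns", df=3),
                          lag_basis=indicator_cb(7).lag_basis,
                          center=float(panel.df["pm25"].min()))
    fit = fit_model(panel, ModelSpec(pollutant_terms={"pm25": spec}))
    grid = np.linspace(panel.df["pm25"].quantile(0.01), panel.df["pm25"].quantile(0.99), 25)
    curve = exposure_response_curve(fit, "pm25", grid)
    rho = spearmanr(grid, curve["RR"]).statistic
    assert rho > 0.9


def test_fitted_curve_band_covers_linear_truth_across_seeds():
    """Pointwise 95% bands around the spline curve cover the true log-linear line."""
    beta = np.log(1.01) / 10.0
    covered, total = 0, 0
    for seed in range(15):
        cfg = SimulationConfig(
            n_years=6,
            pollutant_params={"pm25": PollutantParams(57.6, 47.9, 0.3, 15, 0.5)},
            true_effects={"pm25": np.array([beta])},
            dispersion=1.3, seed=seed,
        )
        panel = simulate_panel(cfg)
        x = panel.df["pm25"]
        c = float(x.quantile(0.05))
        spec = CrossBasisSpec(max_lag=7, var_basis=BasisSpec(kind="ns", df=3),
                              lag_basis=indicator_cb(7).lag_basis, center=c)
        fit = fit_model(panel, ModelSpec(pollutant_terms={"pm25": spec}))
        grid = np.linspace(x.quantile(0.05), x.quantile(0.95), 15)
        curve = exposure_response_curve(fit, "pm25", grid)
        truth = np.exp(beta * (grid - c))
        covered += int(((curve["lo95"] <= truth) & (truth <= curve["hi95"])).sum())
        total += len(grid)
    assert covered / total >= 0.90


def test_spearman_self_and_monotone_transform():
    rng = np.random.default_rng(1)
    n = 200
    x = rng.gamma(3, 20, n)
    df = pd.DataFrame({
        "date": pd.date_range("2020-01-01", periods=n),
        "pm25": x, "pm10": np.exp(x / 50.0),          # strictly monotone in pm25
        "so2": rng.gamma(2, 5, n), "no2": rng.gamma(2, 15, n),
        "o3": rng.gamma(3, 30, n), "co": rng.gamma(3, 0.3, n),
        "at": rng.normal(15, 10, n), "rh": rng.uniform(10, 90, n),
    })
    data = DailySeries(df)
    m = spearman_matrix(data)
    assert m.loc["pm25", "pm25"] == 1.0
    assert abs(m.loc["pm25", "pm10"] - 1.0) < 1e-12


def test_spearman_hand_ranked_example():
    df = pd.DataFrame({
        "date": pd.date_range("2020-01-01", periods=5),
        "pm25": [1, 2, 3, 4, 5], "pm10": [2, 1, 4, 3, 5],
        "so2": 1.0, "no2": 1.0, "o3": 1.0, "co": 1.0,
        "at": [1, 2, 3, 4, 5.0], "rh": [10, 20, 30, 40, 50.0],
    })
    # d = (-1, 1, -1, 1, 0), sum d^2 = 4, rho = 1 - 6*4/(5*(25-1)) = 0.8
    m = spearman_matrix(DailySeries(df), ["pm25", "pm10"])
    assert abs(m.loc["pm25", "pm10"] - 0.8) < 1e-12


def test_constant_variable_flagged_undefined():
    df = pd.DataFrame({
        "date": pd.date_range("2020-01-01", periods=5),
        "pm25": [1, 2, 3, 4, 5.0], "pm10": [2, 1, 4, 3, 5.0],
        "so2": 1.0, "no2": 1.0, "o3": 1.0, "co": 1.0,
        "at": 20.0, "rh": 50.0,
    })
    m = spearman_matrix(DailySeries(df), ["pm25", "so2"])
    assert np.isnan(m.loc["pm25", "so2"])
    assert m.loc["so2", "so2"] == 1.0
    assert m.attrs["undefined"] == ["so2"]


def test_descriptive_constant_series():
    df = pd.DataFrame({
        "date": pd.date_range("2020-01-01", periods=10),
        "pm25": 42.0, "pm10": 42.0, "so2": 42.0, "no2": 42.0, "o3": 42.0, "co": 1.0,
        "at": 5.0, "rh": 50.0,
    })
    tab = descriptive_table(DailySeries(df))
    row = tab.loc["pm25"]
    assert row["mean"] == row["min"] == row["max"] == 42.0
    assert row["sd"] == 0.0


def test_quantile_convention_linear_interpolation():
    """P25 of 1..100 is 25.75 under the linear-interpolation convention."""
    df = pd.DataFrame({
        "date": pd.date_range("2020-01-01", periods=100),
        "pm25": np.arange(1.0, 101.0), "pm10": 1.0, "so2": 1.0, "no2": 1.0,
        "o3": 1.0, "co": 1.0, "at": 1.0, "rh": 50.0,
    })
    tab = descriptive_table(DailySeries(df))
    v = np.sort(np.arange(1.0, 101.0))
    # sorted-array oracle: x_(k) + frac * (x_(k+1) - x_(k)) at position 0.25(n-1)
    pos = 0.25 * (v.size - 1)
    k, frac = int(pos), pos - int(pos)
    assert tab.loc["pm25", "p25"] == v[k] + frac * (v[k + 1] - v[k]) == 25.75


def test_descriptive_table_includes_season_strata(small_panel):
    tab = descriptive_table(small_panel)
    assert {"cold_season", "warm_season", "male", "female"} <= set(tab.index)
    assert tab.loc["cold_season", "mean"] > tab.loc["warm_season", "mean"]
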