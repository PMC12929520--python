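"""Cross-basis tensor construction and lag-surface prediction."""

import numpy as np
import pytest

from airlag.crossbasis import CrossBasisSpec, build_cross_basis, predict_lag_surface
from airlag.splines import BasisSpec, evaluate_basis

from conftest import indicator_cb


def _linear_const(L):
    return CrossBasisSpec(max_lag=L, var_basis=BasisSpec(kind="linear"),
                          lag_basis=BasisSpec(kind="constant", df=1))


def test_moving_sum_hand_example():
    """Linear exposure x constant lag basis = lag-window moving sum."""
    CB, _ = build_cross_basis(np.array([1.0, 2.0, 3.0, 4.0]), _linear_const(2))
    assert CB.shape == (4, 1)
    assert np.all(np.isnan(CB[:2]))
    np.testing.assert_allclose(CB[2:, 0], [6.0, 9.0], atol=1e-8)


@pytest.mark.parametrize("var_df", [1, 2, 3])
def test_column_count_is_var_df_times_lag_df(var_df):
    spec = CrossBasisSpec(
        max_lag=7,
        var_basis=BasisSpec(kind="linear") if var_df == 1 else BasisSpec(kind="ns", df=var_df),
        lag_basis=BasisSpec(kind="ns", df=4, intercept=True))
    x = np.random.default_rng(0).gamma(3, 20, 300)
    CB, _ = build_cross_basis(x, spec)
    assert CB.shape[1] == 4 * var_df


def test_indicator_lag_basis_recovers_raw_lag_matrix():
    rng = np.random.default_rng(1)
    x = rng.gamma(3, 20, 60)
    L = 3
    CB, _ = build_cross_basis(x, indicator_cb(L))
    expected = np.column_stack([np.r_[[np.nan] * l, x[: 60 - l]] for l in range(L + 1)])
    np.testing.assert_allclose(CB[L:], expected[L:], atol=1e-12)


def test_series_shorter_than_lag_window_rejected():
    with pytest.raises(ValueError, match="shorter"):
        build_cross_basis(np.arange(5.0), _linear_const(7))


def test_null_coefficients_give_zero_surface():
    x = np.random.default_rng(2).gamma(3, 20, 200)
    _, spec = build_cross_basis(x, CrossBasisSpec(max_lag=7,
                                                  var_basis=BasisSpec(kind="ns", df=3)))
    surf = predict_lag_surface(np.zeros(12), np.zeros((12, 12)), spec,
                               at=np.quantile(x, [0.2, 0.5, 0.8]), center=x.min())
    assert np.all(surf.log_rr == 0.0)
    assert np.all(surf.se == 0.0)
    assert np.all(surf.cum_log_rr == 0.0)


def test_flat_lag_profile_cumulative_closed_form():
    """Slope b at every lag: cumulative lag 0-7 log-RR at c+10 is 8*10*b."""
    x = np.random.default_rng(3).gamma(3, 20, 200)
    _, spec = build_cross_basis(x, indicator_cb(7))
    b = 0.0042
    surf = predict_lag_surface(np.full(8, b), np.zeros((8, 8)), spec,
                               at=[10.0], center=0.0)
    assert abs(surf.cum_log_rr[0, 7] - 8 * 10 * b) < 1e-10
    np.testing.assert_allclose(surf.cum_log_rr[0], np.cumsum(surf.log_rr[0]), atol=1e-12)


def test_rr_is_one_at_the_center():
    x = np.random.default_rng(4).gamma(3, 20, 200)
    _, spec = build_cross_basis(x, CrossBasisSpec(max_lag=7,
                                                  var_basis=BasisSpec(kind="ns", df=3)))
    theta = np.random.default_rng(5).normal(scale=0.01, size=12)
    c = float(np.median(x))
    surf = predict_lag_surface(theta, 1e-6 * np.eye(12), spec, at=[c], center=c)
    np.testing.assert_allclose(np.exp(surf.log_rr[0]), 1.0, atol=1e-12)


def test_prediction_matches_direct_tensor_summation():
    """Brute-force oracle: sum theta_jk [Bv_j(x)-Bv_j(c)] Bl_k(l) cell by cell."""
    rng = np.random.default_rng(6)
    x = rng.gamma(3, 20, 400)
    spec0 = CrossBasisSpec(max_lag=7, var_basis=BasisSpec(kind="ns", df=3),
                           lag_basis=BasisSpec(kind="ns", df=4, intercept=True))
    _, spec = build_cross_basis(x, spec0)
    theta = rng.normal(scale=0.01, size=12)
    grid = np.quantile(x, [0.1, 0.3, 0.5, 0.7, 0.9])
    c = float(x.min())
    surf = predict_lag_surface(theta, np.eye(12), spec, at=grid, center=c)
    Bv = evaluate_basis(spec.var_basis, grid) - evaluate_basis(spec.var_basis, np.array([c]))
    Bl = evaluate_basis(spec.lag_basis, np.arange(8.0))
    direct = np.zeros((5, 8))
    for g in range(5):
        for l in range(8):
            for j in range(3):
                for k in range(4):
                    direct[g, l] += theta[j * 4 + k] * Bv[g, j] * Bl[l, k]
    assert np.max(np.abs(direct - surf.log_rr)) < 1e-10


def test_center_shift_adds_constant_per_lag_offset():
    """Moving the reference changes log-RR by the old-vs-new-center contrast."""
    rng = np.random.default_rng(8)
    x = rng.gamma(3, 20, 300)
    _, spec = build_cross_basis(x, CrossBasisSpec(max_lag=7,
                                                  var_basis=BasisSpec(kind="ns", df=3)))
    theta = rng.normal(scale=0.01, size=12)
    grid = np.quantile(x, [0.25, 0.5, 0.75])
    c1, c2 = float(np.quantile(x, 0.1)), float(np.quantile(x, 0.6))
    s1 = predict_lag_surface(theta, np.eye(12), spec, at=grid, center=c1)
    s2 = predict_lag_surface(theta, np.eye(12), spec, at=grid, center=c2)
    contrast = predict_lag_surface(theta, np.eye(12), spec, at=[c2], center=c1)
    diff = s1.log_rr - s2.log_rr
    np.testing.assert_allclose(diff, np.broadcast_to(contrast.log_rr[0], diff.shape),
                               atol=1e-10)


def test_extrapolation_is_flagged():
    x = np.random.default_rng(9).uniform(10, 90, 300)
    _, spec = build_cross_basis(x, CrossBasisSpec(max_lag=7,
                                                  var_basis=BasisSpec(kind="ns", df=3)))
    surf = predict_lag_surface(np.zeros(12), np.zeros((12, 12)), spec,
                               at=[0.0, 50.0, 200.0], center=50.0)
    assert surf.extrapolated.tolist() == [True, False, True]


def test_empty_grid_rejected():
    x = np.random.default_rng(10).gamma(3, 20, 100)
    _, spec = build_cross_basis(x, indicator_cb(7))
    with pytest.raises(ValueError, match="empty"):
        predict_lag_surface(np.zeros(8), np.zeros((8, 8)), spec, at=[])
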