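import numpy as np
import pytest

from airlag import ModelSpec, fit_model, shijiazhuang_like, simulate_panel
from airlag.crossbasis import CrossBasisSpec
from airlag.pipeline import indicator_lag_basis


def indicator_cb(max_lag: int = 7) -> CrossBasisSpec:
    """Linear-exposure cross-basis with one coefficient per lag."""
    return CrossBasisSpec(max_lag=max_lag, lag_basis=indicator_lag_basis(max_lag))


@pytest.fixture(scope="session")
def small_panel():
    """Two simulated years of the polluted-city preset (fixed seed)."""
    return simulate_panel(shijiazhuang_like(seed=42, n_years=2))


@pytest.fixture(scope="session")
def small_fit(small_panel):
    """Single-pollutant fit with the unconstrained (indicator) lag basis."""
    return fit_model(small_panel, ModelSpec(pollutant_terms={"pm25": indicator_cb()}))


def newton_poisson(y, X, iters=200, tol=1e-13):
    """Independent Newton-Raphson maximizer of the Poisson log-likelihood."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(y.mean() + 0.1)
    for _ in range(iters):
        mu = np.exp(X @ beta)
        step = np.linalg.solve((X * mu[:, None]).T @ X, X.T @ (y - mu))
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta
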