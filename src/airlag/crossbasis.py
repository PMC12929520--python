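"""Distributed-lag cross-basis and lag-response surfaces.

A cross-basis is the tensor product of an exposure-dimension basis
``B_var`` and a lag-dimension basis ``B_lag`` over lags ``0..L``.  Column
``(j, k)`` of the cross-basis at day ``t`` is

    sum_{l=0..L}  B_var_j(x_{t-l}) * B_lag_k(l)

so a single coefficient vector ``theta`` describes how the effect of an
exposure is distributed both over concentration and over the days elapsed
since exposure.  Columns are ordered var-major: index = j * lag_df + k.

Fitted coefficients translate back into lag-specific and cumulative
log-relative-risk surfaces through :func:`predict_lag_surface`, always as
contrasts against a centering concentration ``c`` (log-RR is identically
zero at ``x = c``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .splines import BasisSpec, evaluate_basis, make_basis

__all__ = ["CrossBasisSpec", "LagSurface", "build_cross_basis", "predict_lag_surface"]


@dataclass(frozen=True)
class CrossBasisSpec:
    """Exposure- and lag-dimension bases plus the lag window.

    The default exposure basis is linear, which makes per-increment relative
    risks well defined and centering-free; use an ns exposure basis for
    exposure-response curves.  The default lag basis is a natural cubic
    spline with 4 df spanning the constant, on the integer lags ``0..L`` —
    pass ``kind="strata"`` with ``df = L + 1`` for an unconstrained
    one-coefficient-per-lag model.
    """

    max_lag: int = 7
    var_basis: BasisSpec = field(default_factory=lambda: BasisSpec(kind="linear", df=1))
    lag_basis: BasisSpec = field(
        default_factory=lambda: BasisSpec(kind="ns", df=4, intercept=True)
    )
    center: float | None = None

    def __post_init__(self) -> None:
        if self.max_lag < 0:
            raise ValueError(f"max_lag must be >= 0, got {self.max_lag}")
        if self.lag_basis.df > self.max_lag + 1:
            raise ValueError(
                f"lag basis df={self.lag_basis.df} exceeds the {self.max_lag + 1} "
                "distinct lag values"
            )

    @property
    def n_columns(self) -> int:
        return self.var_basis.df * self.lag_basis.df


def _lag_matrix(x: np.ndarray, L: int) -> np.ndarray:
    """n x (L+1) matrix Q with Q[t, l] = x[t - l]; NaN where undefined."""
    n = x.size
    Q = np.full((n, L + 1), np.nan)
    for l in range(L + 1):
        Q[l:, l] = x[: n - l] if l else x
    return Q


def build_cross_basis(
    x, spec: CrossBasisSpec, name: str = "x"
) -> tuple[np.ndarray, CrossBasisSpec]:
    """Build the n x (var_df * lag_df) cross-basis matrix.

    The first ``max_lag`` rows have undefined lagged exposures and are
    returned as NaN; callers must exclude them from fitting.  The resolved
    spec fixes all knots so the identical bases can be re-evaluated on
    prediction grids.
    """
    x = np.asarray(x, dtype=float).ravel()
    L = spec.max_lag
    if x.size <= L:
        raise ValueError(
            f"series of length {x.size} is shorter than max_lag + 1 = {L + 1}"
        )
    _, var_res = make_basis(x, spec.var_basis, name=name)
    lags = np.arange(L + 1, dtype=float)
    C, lag_res = make_basis(lags, spec.lag_basis, name=f"{name}:lag")
    if lag_res.df != spec.lag_basis.df:
        raise ValueError("lag basis df changed during resolution; supply explicit knots")

    Q = _lag_matrix(x, L)
    v, d = var_res.df, lag_res.df
    n = x.size
    CB = np.full((n, v * d), np.nan)
    valid = slice(L, n)
    # A[t, l, j] = B_var_j(x_{t-l}) on valid rows
    A = evaluate_basis(var_res, Q[valid].ravel()).reshape(n - L, L + 1, v)
    CB[valid] = np.einsum("tlj,lk->tjk", A, C).reshape(n - L, v * d)
    resolved = replace(spec, var_basis=var_res, lag_basis=lag_res)
    return CB, resolved


@dataclass
class LagSurface:
    """Lag-specific and cumulative log-RR over an exposure grid.

    ``log_rr[g, l]`` is the log relative risk at exposure ``at[g]`` and lag
    ``l`` versus the centering value; ``cum_log_rr[g, k]`` accumulates lags
    ``0..k``.  Standard errors come from the delta-method quadratic form
    with the dispersion-scaled coefficient covariance.
    """

    at: np.ndarray
    lags: np.ndarray
    center: float
    log_rr: np.ndarray
    se: np.ndarray
    cum_log_rr: np.ndarray
    cum_se: np.ndarray
    extrapolated: np.ndarray

    @property
    def rr(self) -> np.ndarray:
        return np.exp(self.log_rr)

    def to_frame(self, pollutant: str = "", z: float = 1.959963984540054) -> pd.DataFrame:
        """Tidy long-format table: one row per (exposure, lag), with CIs."""
        rows = []
        for kind, m, s in (("single", self.log_rr, self.se),
                           ("cumulative", self.cum_log_rr, self.cum_se)):
            for gi, xv in enumerate(self.at):
                for li, lag in enumerate(self.lags):
                    rows.append({
                        "pollutant": pollutant, "kind": kind,
                        "exposure": xv, "lag": int(lag),
                        "logRR": m[gi, li], "se": s[gi, li],
                        "RR": np.exp(m[gi, li]),
                        "lo95": np.exp(m[gi, li] - z * s[gi, li]),
                        "hi95": np.exp(m[gi, li] + z * s[gi, li]),
                        "extrapolated": bool(self.extrapolated[gi]),
                    })
        return pd.DataFrame(rows)


def predict_lag_surface(
    theta,
    cov,
    spec: CrossBasisSpec,
    at,
    center: float | None = None,
) -> LagSurface:
    """Translate cross-basis coefficients into a lag-response surface.

    Parameters
    ----------
    theta, cov
        The cross-basis coefficient block (length ``v*d``, var-major) and
        its covariance.
    spec
        The *resolved* spec the coefficients were fitted with.
    at
        Exposure grid.
    center
        Reference concentration; defaults to ``spec.center``, else 0.
    """
    theta = np.asarray(theta, dtype=float).ravel()
    cov = np.asarray(cov, dtype=float)
    if not spec.var_basis.resolved or not spec.lag_basis.resolved:
        raise ValueError("spec must be resolved (built from data) before prediction")
    v, d = spec.var_basis.df, spec.lag_basis.df
    if theta.size != v * d or cov.shape != (v * d, v * d):
        raise ValueError(
            f"expected {v * d} coefficients with matching covariance, "
            f"got {theta.size} and {cov.shape}"
        )
    at = np.asarray(at, dtype=float).ravel()
    if at.size == 0:
        raise ValueError("empty exposure grid")
    c = center if center is not None else (spec.center if spec.center is not None else 0.0)

    lags = np.arange(spec.max_lag + 1, dtype=float)
    C = evaluate_basis(spec.lag_basis, lags)                       # (L+1, d)
    Z = evaluate_basis(spec.var_basis, at) - evaluate_basis(
        spec.var_basis, np.array([c])
    )                                                               # (g, v)
    g, L1 = at.size, lags.size

    # weight tensor W[g, l, :] = kron(Z[g], C[l]) in var-major order
    W = np.einsum("gj,lk->gljk", Z, C).reshape(g, L1, v * d)
    Wc = np.cumsum(W, axis=1)                                      # cumulative over lags

    log_rr = W @ theta
    cum = Wc @ theta
    se = np.sqrt(np.maximum(np.einsum("glp,pq,glq->gl", W, cov, W), 0.0))
    cum_se = np.sqrt(np.maximum(np.einsum("glp,pq,glq->gl", Wc, cov, Wc), 0.0))

    extrap = np.zeros(g, dtype=bool)
    if spec.var_basis.kind == "ns":
        a, b = spec.var_basis.boundary
        extrap = (at < a) | (at > b)
    return LagSurface(
        at=at, lags=lags.astype(int), center=float(c),
        log_rr=log_rr, se=se, cum_log_rr=cum, cum_se=cum_se,
        extrapolated=extrap,
    )
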