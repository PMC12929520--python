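"""Quasi-Poisson model assembly and fitting.

The model is a log-link count regression whose mean structure is

    log E[Hosp_t] = b0 + sum_i CB(pollutant_i; L, lag df)
                    + ns(AT_t) + ns(RH_t) + ns(t, 7 df per year) + DOW

with variance Var = phi * mu.  Every degree of freedom is fixed a priori,
so the "additive" model is an ordinary GLM over a constructed design
matrix: cross-basis blocks for the pollutants, natural cubic splines for
mean temperature, relative humidity and the sequential day index, and
day-of-week dummies (Monday reference).  Point estimates equal Poisson
maximum likelihood; the coefficient covariance is scaled by the Pearson
dispersion estimate.

Fitting is delegated to statsmodels' IRLS (``sm.GLM`` with a Poisson
family); this module owns design assembly, the column map from terms back
to coefficients, and dispersion scaling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .crossbasis import CrossBasisSpec, build_cross_basis
from .series import DailySeries
from .splines import BasisSpec, make_basis

__all__ = ["LaggedTerm", "ModelSpec", "FitResult", "Design", "build_design",
           "fit_quasipoisson", "fit_model"]


@dataclass(frozen=True)
class LaggedTerm:
    """A single-lag linear exposure term: the concentration ``lag`` days before."""

    lag: int = 0

    def __post_init__(self) -> None:
        if self.lag < 0:
            raise ValueError("lag must be >= 0")


def _default_met() -> dict[str, BasisSpec]:
    return {"at": BasisSpec(kind="ns", df=3), "rh": BasisSpec(kind="ns", df=3)}


@dataclass(frozen=False)
class ModelSpec:
    """Declarative description of the full regression.

    ``pollutant_terms`` maps pollutant column names to either a
    :class:`CrossBasisSpec` (distributed-lag term) or a :class:`LaggedTerm`
    (one column, the exposure at a fixed lag).  ``time_df_per_year`` sets
    the long-term-trend spline flexibility; the total df is rounded from
    df/year times the panel length in years.
    """

    pollutant_terms: dict = field(default_factory=dict)
    met_terms: dict = field(default_factory=_default_met)
    time_df_per_year: float = 7.0
    dow: bool = True
    offset: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.pollutant_terms:
            raise ValueError("at least one pollutant term is required")


@dataclass
class Design:
    X: np.ndarray
    y: np.ndarray | None
    column_map: dict[str, np.ndarray]
    col_names: list[str]
    kept: np.ndarray          # boolean row mask into the original panel
    resolved: dict            # term name -> resolved CrossBasisSpec / BasisSpec
    n_dropped: int


def _max_lag(term) -> int:
    return term.max_lag if isinstance(term, CrossBasisSpec) else term.lag


def build_design(data: DailySeries, spec: ModelSpec) -> Design:
    """Assemble the design matrix, dropping rows with undefined lags.

    Columns in order: intercept, one block per pollutant term, meteorology
    bases, time spline, six day-of-week dummies (Monday reference).  A rank
    check reports aliased columns by name.
    """
    df = data.df
    n = len(df)
    blocks: list[np.ndarray] = [np.ones((n, 1))]
    names: list[str] = ["intercept"]
    column_map: dict[str, np.ndarray] = {"intercept": np.array([0])}
    resolved: dict = {}
    col = 1
    drop_before = 0

    for pol, term in spec.pollutant_terms.items():
        x = df[pol].to_numpy(dtype=float)
        if np.any(~np.isfinite(x)):
            bad = df.loc[~np.isfinite(x), "date"].dt.date.astype(str).tolist()[:5]
            raise ValueError(f"missing values in {pol} on dates {bad}")
        if isinstance(term, CrossBasisSpec):
            CB, res = build_cross_basis(x, term, name=pol)
            blocks.append(np.nan_to_num(CB, nan=0.0))
            k = CB.shape[1]
            names += [f"cb({pol})[{j}]" for j in range(k)]
        elif isinstance(term, LaggedTerm):
            lagged = np.full(n, np.nan)
            if term.lag:
                lagged[term.lag:] = x[: n - term.lag]
            else:
                lagged[:] = x
            blocks.append(np.nan_to_num(lagged, nan=0.0)[:, None])
            k, res = 1, term
            names.append(f"{pol}.lag{term.lag}")
        else:
            raise TypeError(f"unsupported pollutant term {term!r}")
        column_map[pol] = np.arange(col, col + k)
        resolved[pol] = res
        col += k
        drop_before = max(drop_before, _max_lag(term))

    for met, bspec in spec.met_terms.items():
        v = df[met].to_numpy(dtype=float)
        B, res = make_basis(v, bspec, name=met)
        blocks.append(B)
        k = B.shape[1]
        column_map[met] = np.arange(col, col + k)
        resolved[met] = res
        names += [f"ns({met})[{j}]" for j in range(k)]
        col += k

    years = n / 365.25
    time_df = max(int(round(spec.time_df_per_year * years)), 2)
    t_idx = np.arange(n, dtype=float)
    T, tres = make_basis(t_idx, BasisSpec(kind="ns", df=time_df), name="time")
    blocks.append(T)
    column_map["time"] = np.arange(col, col + T.shape[1])
    resolved["time"] = tres
    names += [f"ns(time)[{j}]" for j in range(T.shape[1])]
    col += T.shape[1]

    if spec.dow:
        dow = df["date"].dt.dayofweek.to_numpy()       # Monday = 0 (reference)
        D = np.zeros((n, 6))
        for d in range(1, 7):
            D[:, d - 1] = dow == d
        blocks.append(D)
        column_map["dow"] = np.arange(col, col + 6)
        names += [f"dow[{d}]" for d in range(1, 7)]
        col += 6

    X = np.column_stack(blocks)
    kept = np.ones(n, dtype=bool)
    kept[:drop_before] = False

    y = None
    if data.has_counts:
        y = df["admissions"].to_numpy(dtype=float)
        bad = ~np.isfinite(y)
        if bad.any():
            dates = df.loc[bad, "date"].dt.date.astype(str).tolist()[:5]
            raise ValueError(f"missing admission counts on dates {dates}")
        y = y[kept]

    Xk = X[kept]
    rank = np.linalg.matrix_rank(Xk)
    if rank < Xk.shape[1]:
        # pivoted QR exposes which columns are linear combinations of earlier ones
        import scipy.linalg
        _, R, piv = scipy.linalg.qr(Xk, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        thresh = diag.max() * max(Xk.shape) * np.finfo(float).eps
        aliased = sorted(names[p] for p in piv[diag < thresh])
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {Xk.shape[1]}); "
            f"aliased columns: {aliased}"
        )
    return Design(X=Xk, y=y, column_map=column_map, col_names=names,
                  kept=kept, resolved=resolved, n_dropped=int((~kept).sum()))


@dataclass
class FitResult:
    """Converged quasi-Poisson fit with term bookkeeping."""

    coefficients: np.ndarray
    covariance: np.ndarray
    dispersion: float
    deviance: float
    n_used: int
    df_residual: int
    column_map: dict[str, np.ndarray]
    col_names: list[str]
    n_iter: int
    converged: bool
    resolved: dict = field(default_factory=dict)
    n_dropped: int = 0

    def term_block(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """Coefficient vector and covariance block for one model term."""
        idx = self.column_map[name]
        return self.coefficients[idx], self.covariance[np.ix_(idx, idx)]

    def to_json(self) -> str:
        return json.dumps({
            "coefficients": dict(zip(self.col_names, self.coefficients.tolist())),
            "dispersion": self.dispersion,
            "deviance": self.deviance,
            "n_used": self.n_used,
            "df_residual": self.df_residual,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "n_dropped_leading_rows": self.n_dropped,
            "column_map": {k: v.tolist() for k, v in self.column_map.items()},
        }, indent=2)


def fit_quasipoisson(
    y,
    X,
    tol: float = 1e-9,
    max_iter: int = 50,
    dispersion: str = "pearson",
    column_map: dict | None = None,
    col_names: list[str] | None = None,
) -> FitResult:
    """IRLS fit of the log-link Poisson score equations with Var = phi * mu.

    Point estimates are Poisson ML; ``phi`` is estimated from the Pearson
    chi-square (deviance-based behind ``dispersion="deviance"``) and scales
    the coefficient covariance ``phi * (X'WX)^{-1}``.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValueError("y must be nonnegative integer counts")
    if dispersion not in ("pearson", "deviance"):
        raise ValueError(f"unknown dispersion estimator {dispersion!r}")

    model = sm.GLM(y, X, family=sm.families.Poisson())
    res = model.fit(maxiter=max_iter, tol=tol, scale="X2")
    n_iter = len(res.fit_history["deviance"]) - 1
    if not getattr(res, "converged", True) or n_iter >= max_iter:
        dev = res.fit_history["deviance"]
        raise RuntimeError(
            f"IRLS did not converge in {max_iter} iterations; "
            f"last deviances {dev[-3:]}"
        )
    eta = X @ res.params
    if np.any(np.abs(eta) > 30):
        raise RuntimeError(
            "fitted linear predictor exceeds |eta| = 30; separation-like "
            "divergence or implausible covariate scaling"
        )
    df_resid = int(res.df_resid)
    if dispersion == "pearson":
        phi = float(res.pearson_chi2 / df_resid)
    else:
        phi = float(res.deviance / df_resid)
    mu = np.exp(eta)
    W = mu  # log-link Poisson working weights at convergence
    xtwx_inv = np.linalg.inv((X * W[:, None]).T @ X)
    cov = phi * xtwx_inv
    hist = res.fit_history["deviance"]
    rel = abs(hist[-1] - hist[-2]) / (abs(hist[-2]) + 1e-300) if len(hist) > 1 else 0.0
    p = X.shape[1]
    return FitResult(
        coefficients=np.asarray(res.params),
        covariance=cov,
        dispersion=phi,
        deviance=float(res.deviance),
        n_used=len(y),
        df_residual=df_resid,
        column_map=column_map or {"all": np.arange(p)},
        col_names=col_names or [f"x{j}" for j in range(p)],
        n_iter=n_iter,
        converged=bool(getattr(res, "converged", True)),
    )


def fit_model(data: DailySeries, spec: ModelSpec, **fit_kw) -> FitResult:
    """Build the design for ``spec`` on ``data`` and fit it; one-stop entry."""
    design = build_design(data, spec)
    if design.y is None:
        raise ValueError("data carries no admission counts; cannot fit")
    fr = fit_quasipoisson(design.y, design.X, column_map=design.column_map,
                          col_names=design.col_names, **fit_kw)
    fr.resolved = design.resolved
    fr.n_dropped = design.n_dropped
    return fr
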