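"""Reportable effect estimates: per-increment RRs, curves, descriptives.

Relative risks are reported per fixed concentration increment — 10 ug/m3
for all pollutants except CO, which is measured in mg/m3 and reported per
1 mg/m3 — across single-day lags 0..L and cumulative windows 0..k.  Wald
95% intervals use the dispersion-scaled covariance; the normal quantile
defaults to 1.96 to match the convention of the reported literature (the
exact quantile is available via ``z``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .crossbasis import predict_lag_surface
from .glm import FitResult, LaggedTerm
from .series import MET_VARS, POLLUTANTS, STRATA, DailySeries

__all__ = ["RREstimate", "DEFAULT_INCREMENTS", "rr_table",
           "exposure_response_curve", "spearman_matrix", "descriptive_table"]

#: reporting increments in each pollutant's native unit
DEFAULT_INCREMENTS = {"pm25": 10.0, "pm10": 10.0, "so2": 10.0, "no2": 10.0,
                      "o3": 10.0, "co": 1.0}

Z95 = 1.96


@dataclass(frozen=True)
class RREstimate:
    """Relative risk for one pollutant, increment and lag definition."""

    pollutant: str
    increment: float
    lag_def: str           # "lag3" (single-day) or "lag03" (cumulative 0..3)
    rr: float
    lo95: float
    hi95: float
    log_rr: float
    se: float

    @property
    def significant(self) -> bool:
        return self.lo95 > 1.0 or self.hi95 < 1.0


def _check_linear(spec) -> None:
    if isinstance(spec, LaggedTerm):
        return
    if spec.var_basis.kind != "linear":
        raise ValueError(
            "per-increment RRs require a linear exposure basis; for a spline "
            "exposure basis use exposure_response_curve instead"
        )


def _estimate(pollutant, increment, lag_def, log_rr, se, z) -> RREstimate:
    return RREstimate(
        pollutant=pollutant, increment=increment, lag_def=lag_def,
        rr=float(np.exp(log_rr)),
        lo95=float(np.exp(log_rr - z * se)),
        hi95=float(np.exp(log_rr + z * se)),
        log_rr=float(log_rr), se=float(se),
    )


def rr_table(
    fit: FitResult,
    pollutant: str,
    increment: float | None = None,
    z: float = Z95,
) -> list[RREstimate]:
    """Single-day RRs at each lag 0..L and cumulative RRs over 0..k windows.

    Requires the linear exposure basis (centering is then immaterial: the
    log-RR of an increment is increment times the lag-curve value).
    """
    spec = fit.resolved[pollutant]
    _check_linear(spec)
    if increment is None:
        increment = DEFAULT_INCREMENTS.get(pollutant, 10.0)
    theta, cov = fit.term_block(pollutant)
    out: list[RREstimate] = []
    if isinstance(spec, LaggedTerm):
        lr = increment * theta[0]
        se = increment * np.sqrt(cov[0, 0])
        return [_estimate(pollutant, increment, f"lag{spec.lag}", lr, se, z)]
    surf = predict_lag_surface(theta, cov, spec, at=[increment], center=0.0)
    for l in range(spec.max_lag + 1):
        out.append(_estimate(pollutant, increment, f"lag{l}",
                             surf.log_rr[0, l], surf.se[0, l], z))
    for k in range(1, spec.max_lag + 1):
        out.append(_estimate(pollutant, increment, f"lag0{k}",
                             surf.cum_log_rr[0, k], surf.cum_se[0, k], z))
    return out


def rr_frame(estimates: list[RREstimate]) -> pd.DataFrame:
    """Tidy DataFrame view of a list of RR estimates."""
    return pd.DataFrame([e.__dict__ for e in estimates])


def exposure_response_curve(
    fit: FitResult,
    pollutant: str,
    grid,
    lag: int = 0,
    center: float | None = None,
    z: float = Z95,
) -> pd.DataFrame:
    """RR versus concentration at a single lag, relative to the center.

    The center defaults to the spec's configured centering value (the
    minimum observed concentration by pipeline convention).  Grid points
    beyond the fitted exposure range are flagged as extrapolation.
    """
    spec = fit.resolved[pollutant]
    if isinstance(spec, LaggedTerm):
        raise ValueError("exposure-response curves need a cross-basis term")
    grid = np.asarray(grid, dtype=float).ravel()
    if grid.size == 0:
        raise ValueError("empty exposure grid")
    theta, cov = fit.term_block(pollutant)
    surf = predict_lag_surface(theta, cov, spec, at=grid, center=center)
    l = int(lag)
    return pd.DataFrame({
        "pollutant": pollutant,
        "exposure": grid,
        "lag": l,
        "RR": np.exp(surf.log_rr[:, l]),
        "lo95": np.exp(surf.log_rr[:, l] - z * surf.se[:, l]),
        "hi95": np.exp(surf.log_rr[:, l] + z * surf.se[:, l]),
        "logRR": surf.log_rr[:, l],
        "se": surf.se[:, l],
        "extrapolated": surf.extrapolated,
    })


def spearman_matrix(data: DailySeries, variables=None) -> pd.DataFrame:
    """Spearman rank-correlation matrix (average ranks for ties).

    Constant variables yield undefined (NaN) entries, flagged with a
    warning column-wise in the caller's hands; the diagonal is exactly 1.
    """
    variables = list(variables) if variables is not None else list(POLLUTANTS) + list(MET_VARS)
    sub = data.df[variables]
    if len(sub) < 3:
        raise ValueError("need at least 3 complete rows for rank correlation")
    out = sub.corr(method="spearman")     # average ranks for ties
    consts = [v for v in variables if sub[v].nunique() <= 1]
    for v in consts:
        out.loc[v, :] = np.nan
        out.loc[:, v] = np.nan
    for v in variables:
        out.loc[v, v] = 1.0
    if consts:
        out.attrs["undefined"] = consts
    return out


def _quantiles(v: np.ndarray) -> dict:
    # linear-interpolation quantile convention, stated in the docs
    return {
        "mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
        "min": float(np.min(v)), "p25": float(np.quantile(v, 0.25)),
        "p50": float(np.quantile(v, 0.50)), "p75": float(np.quantile(v, 0.75)),
        "max": float(np.max(v)),
    }


def descriptive_table(data: DailySeries) -> pd.DataFrame:
    """Per-variable mean/SD/min/quartiles/max, plus admission strata rows.

    Mirrors the conventional Table-1 layout of time-series studies:
    pollutants, meteorology, then total admissions with sex/age strata and
    the cold (November-March) / warm season split.
    """
    rows = {}
    df = data.df
    for col in POLLUTANTS + MET_VARS:
        rows[col] = _quantiles(df[col].to_numpy(dtype=float))
    if data.has_counts:
        rows["admissions"] = _quantiles(df["admissions"].to_numpy(dtype=float))
        for s in STRATA:
            if s in df.columns:
                rows[s] = _quantiles(df[s].to_numpy(dtype=float))
        season = data.season()
        for name in ("cold", "warm"):
            v = df.loc[season == name, "admissions"].to_numpy(dtype=float)
            if v.size:
                rows[f"{name}_season"] = _quantiles(v)
    out = pd.DataFrame(rows).T
    out.index.name = "variable"
    return out
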