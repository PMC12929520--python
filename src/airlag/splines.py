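"""Regression-spline bases for confounder adjustment and the cross-basis dimensions.

The workhorse is the natural cubic spline (``ns``): a cubic regression spline
constrained to be linear beyond its boundary knots, the standard choice in
environmental-epidemiology time series for smooth adjustment of temperature,
humidity and long-term trend.  Degrees of freedom are always fixed a priori;
there is no penalised smoothing here.

Conventions (documented because the literature rarely states them):

* interior knots default to equally spaced quantiles of the data, boundary
  knots to the data range;
* an ns basis *without* the constant has ``df`` columns and ``df - 1``
  interior knots; *with* the constant spanned, ``df`` columns and ``df - 2``
  interior knots (the R ``splines::ns`` convention);
* evaluation beyond the boundary knots extrapolates linearly (value and first
  derivative at the boundary).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["BasisSpec", "make_basis", "make_ns_basis", "evaluate_basis"]

_KINDS = ("ns", "linear", "poly", "strata", "constant")


@dataclass(frozen=True)
class BasisSpec:
    """Declarative description of a one-dimensional basis.

    Parameters
    ----------
    kind
        One of ``"ns"`` (natural cubic spline), ``"linear"`` (the identity,
        one column), ``"poly"`` (monomials ``x, x**2, ...``), ``"strata"``
        (indicator columns for bins delimited by ``knots``) or ``"constant"``
        (a single column of ones, used as a lag basis for moving sums).
    df
        Number of basis columns.
    knots
        Interior knots (``ns``) or bin cut points (``strata``).  ``None``
        means "resolve from the data at construction time".
    boundary
        Boundary-knot pair for ``ns``; defaults to the data range.
    intercept
        Whether the basis spans the constant function (``ns`` only; the
        default ``False`` is appropriate when the model has its own
        intercept).
    """

    kind: str = "ns"
    df: int = 3
    knots: tuple[float, ...] | None = None
    boundary: tuple[float, float] | None = None
    intercept: bool = False

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown basis kind {self.kind!r}; expected one of {_KINDS}")
        if self.df < 1:
            raise ValueError(f"df must be >= 1, got {self.df}")
        if self.knots is not None:
            k = np.asarray(self.knots, dtype=float)
            if k.ndim != 1 or np.any(np.diff(k) <= 0):
                raise ValueError("knots must be strictly increasing")
            if self.boundary is not None:
                a, b = self.boundary
                if k.size and (k[0] <= a or k[-1] >= b):
                    raise ValueError(
                        f"interior knots {tuple(k)} must lie strictly inside boundary {self.boundary}"
                    )
        if self.boundary is not None and not self.boundary[0] < self.boundary[1]:
            raise ValueError(f"boundary pair must be increasing, got {self.boundary}")

    @property
    def resolved(self) -> bool:
        """True when the basis can be evaluated at new points without data."""
        if self.kind in ("linear", "poly", "constant"):
            return True
        if self.kind == "strata":
            return self.knots is not None
        return self.knots is not None and self.boundary is not None

    def n_interior(self) -> int:
        """Interior-knot count implied by df for an ns basis."""
        return self.df - 1 if not self.intercept else self.df - 2


def _check_finite(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        bad = np.flatnonzero(~np.isfinite(x))
        raise ValueError(
            f"{name} contains {bad.size} non-finite entries (first at index {bad[0]}); "
            "pre-clean the data before basis construction"
        )
    return x


def _resolve_ns(x: np.ndarray, spec: BasisSpec, name: str) -> BasisSpec:
    m = spec.n_interior()
    if m < 0:
        raise ValueError(
            f"ns basis with intercept needs df >= 2, got df={spec.df}"
        )
    boundary = spec.boundary
    if boundary is None:
        boundary = (float(np.min(x)), float(np.max(x)))
        if boundary[0] == boundary[1]:
            raise ValueError(f"{name} is constant; cannot place boundary knots")
    knots = spec.knots
    if knots is None:
        n_distinct = np.unique(x).size
        if n_distinct < spec.df + 1:
            raise ValueError(
                f"{name} has {n_distinct} distinct values; "
                f"need at least df + 1 = {spec.df + 1} for quantile knots"
            )
        if m > 0:
            q = np.quantile(np.sort(x), np.arange(1, m + 1) / (m + 1))
            uq = np.unique(q)
            uq = uq[(uq > boundary[0]) & (uq < boundary[1])]
            if uq.size < m:
                warnings.warn(
                    f"{name}: {m - uq.size} duplicate/boundary quantile knots collapsed; "
                    f"effective df reduced to {uq.size + (1 if not spec.intercept else 2)}",
                    stacklevel=3,
                )
            knots = tuple(float(v) for v in uq)
        else:
            knots = ()
    eff_df = len(knots) + (1 if not spec.intercept else 2)
    return replace(spec, knots=tuple(knots), boundary=boundary, df=eff_df)


def _ns_design(x: np.ndarray, spec: BasisSpec) -> np.ndarray:
    a, b = spec.boundary
    t = np.concatenate([[a] * 4, spec.knots, [b] * 4])
    nb = t.size - 4
    spl = BSpline(t, np.eye(nb), 3, extrapolate=True)
    lo = 0 if spec.intercept else 1
    # natural constraint: second derivative vanishes at both boundaries
    con = spl.derivative(2)(np.array([a, b]))[:, lo:]
    q, _ = np.linalg.qr(con.T, mode="complete")
    proj = q[:, 2:]
    inside = np.clip(x, a, b)
    out = spl(inside)[:, lo:] @ proj
    d1 = spl.derivative(1)
    for bound, mask in ((a, x < a), (b, x > b)):
        if np.any(mask):
            val = (spl(np.array([bound]))[:, lo:] @ proj)[0]
            slope = (d1(np.array([bound]))[:, lo:] @ proj)[0]
            out[mask] = val + np.outer(x[mask] - bound, slope)
    return out


def _strata_design(x: np.ndarray, spec: BasisSpec) -> np.ndarray:
    cuts = np.asarray(spec.knots, dtype=float)
    idx = np.searchsorted(cuts, x, side="right")
    out = np.zeros((x.size, cuts.size + 1))
    out[np.arange(x.size), idx] = 1.0
    return out


def make_basis(x, spec: BasisSpec, name: str = "x") -> tuple[np.ndarray, BasisSpec]:
    """Construct a basis matrix from data, resolving knots where needed.

    Returns the ``n x df`` design matrix and a *resolved* spec with all knot
    locations fixed, so the identical basis can be re-evaluated at new points
    via :func:`evaluate_basis`.
    """
    x = _check_finite(x, name)
    if spec.kind == "ns":
        resolved = _resolve_ns(x, spec, name)
        return _ns_design(x, resolved), resolved
    if spec.kind == "linear":
        return x[:, None].copy(), replace(spec, df=1)
    if spec.kind == "poly":
        return np.column_stack([x**p for p in range(1, spec.df + 1)]), spec
    if spec.kind == "constant":
        return np.ones((x.size, 1)), replace(spec, df=1)
    if spec.kind == "strata":
        if spec.knots is None:
            m = spec.df - 1
            cuts = np.unique(np.quantile(x, np.arange(1, m + 1) / (m + 1)))
            spec = replace(spec, knots=tuple(float(c) for c in cuts), df=len(cuts) + 1)
        return _strata_design(x, spec), spec
    raise AssertionError(spec.kind)


def make_ns_basis(x, spec: BasisSpec | None = None, name: str = "x") -> tuple[np.ndarray, BasisSpec]:
    """Natural-cubic-spline basis; thin wrapper over :func:`make_basis`."""
    spec = spec if spec is not None else BasisSpec(kind="ns", df=3)
    if spec.kind != "ns":
        raise ValueError(f"make_ns_basis requires kind='ns', got {spec.kind!r}")
    return make_basis(x, spec, name=name)


def evaluate_basis(spec: BasisSpec, x_new) -> np.ndarray:
    """Evaluate a resolved basis at new points.

    Reproduces the construction matrix exactly at the original data and
    extrapolates linearly beyond the boundary knots for ``ns``.
    """
    if not spec.resolved:
        raise ValueError(
            "basis spec is unresolved (knots/boundary not fixed); "
            "build it with make_basis first"
        )
    x = _check_finite(x_new, "x_new")
    if spec.kind == "ns":
        return _ns_design(x, spec)
    if spec.kind == "linear":
        return x[:, None].copy()
    if spec.kind == "poly":
        return np.column_stack([x**p for p in range(1, spec.df + 1)])
    if spec.kind == "constant":
        return np.ones((x.size, 1))
    if spec.kind == "strata":
        return _strata_design(x, spec)
    raise AssertionError(spec.kind)
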