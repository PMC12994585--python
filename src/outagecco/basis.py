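"""Natural cubic spline and distributed-lag cross-basis construction.

The distributed-lag models used here represent an exposure's effect jointly
over its intensity and over lags 0-6 days as a tensor product of two bases:
a "var" basis in the exposure value (identity for a binary indicator, linear
or natural cubic spline for hours-without-power or temperature) and a "lag"
basis in lag number, a natural cubic spline that constrains the lag curve to
vary smoothly.

Knot conventions
----------------
* Covariate use (no intercept): ``df`` columns, ``df - 1`` interior knots,
  constant excluded — the convention of R's ``splines::ns``.
* Lag use (intercept included): ``df`` columns spanning the full natural
  spline space with ``df - 2`` interior knots, so lag df 3/4/5 corresponds
  to 1/2/3 interior knots.

Interior knots default to equally spaced quantiles of the data; boundary
knots to the data range. The basis is linear beyond the boundary knots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SplineSpec",
    "CrossBasisSpec",
    "CrossBasisMeta",
    "natural_spline_basis",
    "spline_design",
    "cross_basis",
]


@dataclass(frozen=True)
class SplineSpec:
    """Specification of a one-dimensional basis.

    kind: "linear" (single centered column) or "natural_cubic".
    df: number of basis columns.
    interior_knots / boundary_knots: explicit knot values; when omitted they
    are placed at equally spaced quantiles / the data range.
    """

    kind: str = "natural_cubic"
    df: int = 3
    interior_knots: tuple | None = None
    boundary_knots: tuple | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "natural_cubic"):
            raise ValueError(f"unknown spline kind {self.kind!r}")
        if self.df < 1:
            raise ValueError("df must be >= 1")
        if self.kind == "linear" and self.df != 1:
            raise ValueError("linear basis has df = 1")


def _resolve_knots(x: np.ndarray, spec: SplineSpec, include_intercept: bool):
    n_interior = spec.df - 2 if include_intercept else spec.df - 1
    if n_interior < 0:
        raise ValueError(f"natural_cubic df {spec.df} too small for this use")
    if spec.boundary_knots is not None:
        lo, hi = spec.boundary_knots
    else:
        lo, hi = float(np.min(x)), float(np.max(x))
    if spec.interior_knots is not None:
        interior = np.asarray(spec.interior_knots, dtype=float)
        if len(interior) != n_interior:
            raise ValueError(
                f"need {n_interior} interior knots for df={spec.df} "
                f"(intercept={include_intercept}), got {len(interior)}"
            )
    elif n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(np.asarray(x, dtype=float), qs)
    else:
        interior = np.array([])
    return interior, (lo, hi)


def _natural_cubic_columns(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Truncated-power natural cubic basis on `knots` (boundary included).

    Returns len(knots) columns: [1, x, N_1..N_{K-2}] where the N_k are
    combinations of truncated cubics constrained to be linear beyond the
    boundary knots (second and third derivatives vanish there).
    """
    x = np.asarray(x, dtype=float)
    xi = np.asarray(knots, dtype=float)
    M = len(xi)
    if M < 2:
        raise ValueError("need at least two knots")
    if len(np.unique(xi)) != M:
        raise ValueError("knots must be distinct")

    def d(k):
        return ((np.clip(x - xi[k], 0, None) ** 3 -
                 np.clip(x - xi[M - 1], 0, None) ** 3) / (xi[M - 1] - xi[k]))

    cols = [np.ones_like(x), x]
    dm1 = d(M - 2)
    for k in range(M - 2):
        cols.append(d(k) - dm1)
    return np.column_stack(cols)


def natural_spline_basis(
    x, spec: SplineSpec, include_intercept: bool = False
) -> np.ndarray:
    """Evaluate the basis of `spec` at `x`; shape (len(x), spec.df).

    The spanned function space contains all linear functions and every
    member has zero second derivative outside the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite")
    if spec.kind == "linear":
        return (x - x.mean())[:, None]
    if spec.df > len(np.unique(x)):
        raise ValueError(
            f"df={spec.df} exceeds the {len(np.unique(x))} distinct x values"
        )
    interior, (lo, hi) = _resolve_knots(x, spec, include_intercept)
    knots = np.concatenate([[lo], np.sort(interior), [hi]])
    if len(np.unique(knots)) < len(knots):
        # quantile knots of zero-inflated data can collide; spread evenly
        knots = np.linspace(lo, hi, len(knots))
    cols = _natural_cubic_columns(x, knots)
    if not include_intercept:
        cols = cols[:, 1:]
    return cols


@dataclass(frozen=True)
class _FrozenBasis:
    """A basis whose knots were fixed on training data, re-evaluable anywhere."""

    kind: str  # "identity" | "linear" | "natural_cubic"
    df: int
    knots: tuple = ()
    include_intercept: bool = False
    center: float = 0.0

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "identity":
            return x[..., None]
        if self.kind == "linear":
            return (x - self.center)[..., None]
        cols = _natural_cubic_columns(x.ravel(), np.asarray(self.knots))
        if not self.include_intercept:
            cols = cols[:, 1:]
        return cols.reshape(x.shape + (self.df,))


def spline_design(x, spec: SplineSpec, include_intercept: bool = False):
    """Like :func:`natural_spline_basis` but also returns a frozen re-evaluable
    basis (used so contrasts and predictions use the training knots)."""
    x = np.asarray(x, dtype=float)
    if spec.kind == "linear":
        fb = _FrozenBasis("linear", 1, center=float(x.mean()))
        return fb(x), fb
    interior, (lo, hi) = _resolve_knots(x.ravel(), spec, include_intercept)
    knots = np.concatenate([[lo], np.sort(interior), [hi]])
    if len(np.unique(knots)) < len(knots):
        knots = np.linspace(lo, hi, len(knots))
    fb = _FrozenBasis("natural_cubic", spec.df, tuple(knots), include_intercept)
    return fb(x), fb


@dataclass(frozen=True)
class CrossBasisSpec:
    """Tensor-product basis over (exposure value, lag 0..6).

    var_spec: "binary", "linear", or a SplineSpec for the value dimension.
    lag_spec: SplineSpec for the lag dimension; df may be 1..7, with df = 7
    meaning the unconstrained per-lag indicator basis.
    """

    var_spec: object = "binary"
    lag_spec: SplineSpec = field(default_factory=lambda: SplineSpec(df=5))
    lag_range: tuple = (0, 6)

    @property
    def n_lags(self) -> int:
        return self.lag_range[1] - self.lag_range[0] + 1


def lag_basis_matrix(spec: SplineSpec, n_lags: int = 7) -> np.ndarray:
    """Lag-dimension basis evaluated at integer lags; (n_lags, df).

    df == n_lags returns the identity (unconstrained per-lag indicators);
    otherwise a natural cubic spline with intercept, interior knots at
    equally spaced quantiles of {0..n_lags-1}, boundary knots at the ends.
    """
    if spec.df > n_lags:
        raise ValueError(f"lag df {spec.df} cannot exceed {n_lags} lags")
    lags = np.arange(n_lags, dtype=float)
    if spec.df == n_lags:
        return np.eye(n_lags)
    if spec.kind == "linear":
        return np.column_stack([np.ones(n_lags), lags])[:, : spec.df]
    return natural_spline_basis(lags, spec, include_intercept=True)


@dataclass(frozen=True)
class CrossBasisMeta:
    """Back-transformation metadata for a fitted cross-basis block.

    `var_basis(x)` re-evaluates the value-dimension basis at any x (with the
    training knots); `lag_matrix[l]` is the lag-basis row at lag l. The
    per-lag effect of contrast x1 vs x0 is
    ``(var_basis(x1) - var_basis(x0)) (x) lag_matrix[l] . beta_block``.
    """

    spec: CrossBasisSpec
    var_basis: _FrozenBasis
    lag_matrix: np.ndarray
    names: tuple

    @property
    def n_cols(self) -> int:
        return len(self.names)

    def contrast_weights(self, x1=1.0, x0=0.0) -> np.ndarray:
        """(n_lags, n_cols) matrix of per-lag coefficient weights for the
        contrast x1 vs x0."""
        dv = self.var_basis(np.array([x1])) - self.var_basis(np.array([x0]))
        dv = dv[0]  # (df_var,)
        # column order: var index major, lag index minor
        return np.stack(
            [np.kron(dv, self.lag_matrix[l]) for l in range(len(self.lag_matrix))]
        )


def cross_basis(hist: np.ndarray, spec: CrossBasisSpec, prefix: str = "cb"):
    """Build the tensor-product design block from lag histories.

    Parameters
    ----------
    hist : (n, n_lags) array, column l holding the exposure value at lag l.
    spec : CrossBasisSpec.

    Returns (Z, meta): Z is (n, df_var * df_lag); each column is
    sum_l f_i(x[t-l]) * c_j(l).
    """
    hist = np.asarray(hist, dtype=float)
    if hist.ndim != 2 or hist.shape[1] != spec.n_lags:
        raise ValueError(f"hist must be (n, {spec.n_lags})")
    if np.isnan(hist).any():
        raise ValueError("lag histories must be complete")

    C = lag_basis_matrix(spec.lag_spec, spec.n_lags)  # (L, df_lag)

    if spec.var_spec in ("binary", "linear"):
        var_b = _FrozenBasis("identity", 1)
        V = hist[:, :, None]  # (n, L, 1)
    elif isinstance(spec.var_spec, SplineSpec) and spec.var_spec.kind == "linear":
        var_b = _FrozenBasis("identity", 1)
        V = hist[:, :, None]
    else:
        vspec = spec.var_spec
        if vspec.interior_knots is None:
            # a rare exposure is mostly zero: placing knots at quantiles of the
            # full column collapses them onto 0, so use the positive values
            vals = hist.ravel()
            pos = vals[vals > 0]
            src = pos if pos.size >= 10 else vals
            n_int = vspec.df - 1
            if n_int > 0:
                qs = np.linspace(0, 1, n_int + 2)[1:-1]
                interior = np.quantile(src, qs)
                if len(np.unique(interior)) < n_int:  # ties on discrete values
                    interior = np.linspace(src.min(), src.max(), n_int + 2)[1:-1]
                interior = tuple(interior)
            else:
                interior = ()
            bounds = vspec.boundary_knots or (float(vals.min()), float(vals.max()))
            vspec = SplineSpec(vspec.kind, vspec.df, interior, tuple(bounds))
        _, var_b = spline_design(hist.ravel(), vspec, include_intercept=False)
        V = var_b(hist)  # (n, L, df_var)

    # Z[n, i, j] = sum_l V[n, l, i] * C[l, j]
    Z = np.einsum("nli,lj->nij", V, C)
    df_var, df_lag = V.shape[2], C.shape[1]
    Z = Z.reshape(len(hist), df_var * df_lag)
    names = tuple(
        f"{prefix}_v{i}_l{j}" for i in range(df_var) for j in range(df_lag)
    )
    meta = CrossBasisMeta(spec=spec, var_basis=var_b, lag_matrix=C, names=names)
    return Z, meta
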