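"""Cubic B-spline bases, curvature penalties, and tensor-product constructions.

These are the building blocks of the penalized fitness surface: univariate
cubic B-spline bases with exact integrated-squared-second-derivative
penalties, sum-to-zero identifiability constraints, and row-wise tensor
products of marginal bases with per-margin penalties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import BSpline

__all__ = ["MarginalBasis", "marginal_basis", "curvature_penalty",
           "sum_to_zero_transform", "row_kron"]

_DEGREE = 3  # cubic splines throughout


def _knot_vector(x: np.ndarray, k: int) -> np.ndarray:
    """Clamped knot vector for ``k`` cubic B-splines over the range of x.

    Interior knots are placed at quantiles of the unique covariate values,
    which keeps the basis well conditioned for right-skewed count traits.
    """
    lo, hi = float(np.min(x)), float(np.max(x))
    n_interior = k - _DEGREE - 1
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(np.unique(x), qs)
        # quantiles of discrete data may collide; fall back to even spacing
        interior = np.asarray(interior, dtype=float)
        if np.any(np.diff(np.r_[lo, interior, hi]) <= 0):
            interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    else:
        interior = np.empty(0)
    return np.r_[[lo] * (_DEGREE + 1), interior, [hi] * (_DEGREE + 1)]


def curvature_penalty(knots: np.ndarray, k: int) -> np.ndarray:
    """Exact penalty matrix S with S_ij = ∫ B_i''(t) B_j''(t) dt.

    The second derivative of a cubic B-spline is piecewise linear, so the
    integrand is piecewise quadratic and 2-point Gauss-Legendre per
    inter-knot interval is exact; 3 points are used for headroom.
    """
    gx, gw = leggauss(3)
    breaks = np.unique(knots)
    # map Gauss nodes into every interval
    mid = 0.5 * (breaks[1:] + breaks[:-1])
    half = 0.5 * np.diff(breaks)
    pts = (mid[:, None] + half[:, None] * gx[None, :]).ravel()
    wts = (half[:, None] * gw[None, :]).ravel()
    # second-derivative design at the quadrature points
    eye = np.eye(k)
    D2 = np.column_stack(
        [BSpline(knots, eye[j], _DEGREE).derivative(2)(pts) for j in range(k)]
    )
    return (D2 * wts[:, None]).T @ D2


def sum_to_zero_transform(colsums: np.ndarray) -> np.ndarray:
    """Orthonormal basis Z of the null space of the 1xk constraint row.

    Reparameterizing X -> XZ makes the smooth sum to zero over the
    training rows, absorbing its constant into the intercept.
    """
    c = np.asarray(colsums, dtype=float).reshape(-1, 1)
    q, _ = np.linalg.qr(c, mode="complete")
    return q[:, 1:]


def row_kron(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Kronecker product: column j*kb+l is a[:, j] * b[:, l]."""
    return (a[:, :, None] * b[:, None, :]).reshape(a.shape[0], -1)


@dataclass
class MarginalBasis:
    """A univariate cubic B-spline basis frozen to a training covariate.

    Attributes
    ----------
    name : covariate name in the dataset
    knots : clamped knot vector
    k : number of basis functions
    penalty : k x k integrated squared second derivative matrix
    Z : optional constraint transform (k x k-1) applied after evaluation
    lo, hi : training range, used to flag extrapolation
    """

    name: str
    knots: np.ndarray
    k: int
    penalty: np.ndarray
    Z: np.ndarray | None = None
    lo: float = 0.0
    hi: float = 1.0
    _bs: BSpline = field(init=False, repr=False)

    def __post_init__(self) -> None:
        # one vector-valued spline evaluates the whole basis at once
        self._bs = BSpline(self.knots, np.eye(self.k), _DEGREE,
                           extrapolate=True)

    @property
    def ncol(self) -> int:
        return self.k if self.Z is None else self.Z.shape[1]

    def raw(self, x: np.ndarray) -> np.ndarray:
        return self._bs(np.asarray(x, dtype=float))

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        B = self.raw(x)
        return B if self.Z is None else B @ self.Z

    def constrained_penalty(self) -> np.ndarray:
        if self.Z is None:
            return self.penalty
        return self.Z.T @ self.penalty @ self.Z


def marginal_basis(name: str, x: np.ndarray, k: int,
                   constrain: bool = False) -> MarginalBasis:
    """Build a cubic basis for covariate ``x`` with ``k`` functions.

    ``k`` is reduced to the number of unique covariate values when the
    data cannot support the requested dimension (minimum 4 for a cubic).
    With ``constrain=True`` the basis is reparameterized to sum to zero
    over the training rows.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError(f"empty covariate {name!r}")
    uniq = np.unique(x)
    if uniq.size < 2:
        raise ValueError(f"covariate {name!r} has zero variance")
    k_eff = int(min(k, max(uniq.size, 4)))
    if k_eff < 4:
        raise ValueError(f"covariate {name!r}: cubic basis needs k >= 4")
    if k_eff < k:
        import logging
        logging.getLogger(__name__).warning(
            "covariate %s: basis dimension reduced %d -> %d "
            "(only %d unique values)", name, k, k_eff, uniq.size)
    knots = _knot_vector(x, k_eff)
    S = curvature_penalty(knots, k_eff)
    mb = MarginalBasis(name=name, knots=knots, k=k_eff, penalty=S,
                       lo=float(uniq[0]), hi=float(uniq[-1]))
    if constrain:
        mb.Z = sum_to_zero_transform(mb.raw(x).sum(axis=0))
        mb.__post_init__()
    return mb
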