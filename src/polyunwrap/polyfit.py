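"""Local 3D polynomial phase model fitted by least squares.

A smooth true phase is modeled in a local neighborhood by a tensor-product
polynomial

    p(x, y, z) = sum_{l<=L} sum_{m<=M} sum_{n<=N} C_{l,m,n} x^l y^m z^n

fitted by linear least squares to voxels that are already unwrapped.  The
integer 2*pi offset of a not-yet-unwrapped voxel is then

    k = round((p(x0, y0, z0) - wrapped(x0, y0, z0)) / (2*pi)),

which is exact whenever the prediction error is below pi.

Coordinates are affinely normalized (centroid subtracted, axes scaled by
their half-extent) before monomials are built: raw voxel indices raised to
sixth-power cross terms would make the normal equations hopelessly
ill-conditioned.  The normalization is stored with the fit so that queries
are evaluated consistently.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .core import TWO_PI

__all__ = [
    "PolyFit",
    "n_terms",
    "polynomial_basis",
    "fit_local_polynomial",
    "estimate_voxel_offset",
]

#: fits with fewer points than this fall back to a constant (order 0) model
MIN_POINTS_LINEAR = 8
#: fits need at least this many points per coefficient, else orders drop;
#: requiring more starves the full model exactly where extrapolation across
#: curved phase (e.g. a smooth extremum) needs the quadratic terms
OVERSAMPLING = 1
#: relative singular-value cutoff for the minimum-norm least-squares solve
RCOND = 1e-10


def n_terms(orders: Tuple[int, int, int]) -> int:
    L, M, N = orders
    return (L + 1) * (M + 1) * (N + 1)


def effective_orders(n_points: int, orders: Tuple[int, int, int],
                     fallback: bool = True) -> Tuple[int, int, int]:
    """Reduce polynomial orders for sparse fits.

    Fewer points than coefficients → drop to (1,1,1); fewer than 8 points
    → drop to the mean model (0,0,0).  Prevents wild extrapolation from
    degenerate point sets near mask edges while keeping the quadratic
    terms available as soon as the system is determined (the minimum-norm
    solve absorbs any remaining rank deficiency).
    """
    if not fallback:
        return orders
    if n_points < MIN_POINTS_LINEAR:
        return (0, 0, 0)
    if n_points < OVERSAMPLING * n_terms(orders):
        return (1, 1, 1)
    return orders


def polynomial_basis(points, orders: Tuple[int, int, int],
                     center=(0.0, 0.0, 0.0), scale=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Design-matrix rows of tensor-product monomials.

    ``points`` is ``(n, 3)`` (or a single ``(3,)`` voxel).  Coordinates are
    normalized as ``(p - center) / scale`` per axis, then all monomials
    ``x^l y^m z^n`` with ``l <= L, m <= M, n <= N`` are produced in
    lexicographic ``(l, m, n)`` order; the first term is the constant 1.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != 3:
        raise ValueError("points must have shape (n, 3)")
    t = (pts - np.asarray(center, float)) / np.asarray(scale, float)
    L, M, N = orders
    px = np.stack([t[:, 0] ** l for l in range(L + 1)], axis=1)
    py = np.stack([t[:, 1] ** m for m in range(M + 1)], axis=1)
    pz = np.stack([t[:, 2] ** n for n in range(N + 1)], axis=1)
    # outer product over the three axes, flattened in (l, m, n) order
    A = (px[:, :, None, None] * py[:, None, :, None] * pz[:, None, None, :])
    return A.reshape(pts.shape[0], n_terms(orders))


@dataclass
class PolyFit:
    """A fitted local polynomial phase model.

    ``coeffs`` has one entry per monomial in lexicographic ``(l, m, n)``
    order; ``center``/``scale`` record the coordinate normalization applied
    before fitting; ``fit_rms`` is the root-mean-square residual (radians)
    over the fitting points.
    """

    orders: Tuple[int, int, int]
    coeffs: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    fit_rms: float

    def predict(self, points) -> np.ndarray:
        """Evaluate the fitted polynomial at ``(n, 3)`` voxel coordinates."""
        A = polynomial_basis(points, self.orders, self.center, self.scale)
        out = A @ self.coeffs
        return out if np.asarray(points).ndim > 1 else float(out[0])

    @property
    def term_exponents(self) -> list:
        L, M, N = self.orders
        return list(itertools.product(range(L + 1), range(M + 1), range(N + 1)))


def fit_local_polynomial(points, phases, orders: Tuple[int, int, int] = (2, 2, 2),
                         fallback: bool = True) -> PolyFit:
    """Least-squares fit of the local polynomial model to unwrapped phases.

    Parameters
    ----------
    points
        ``(n, 3)`` voxel coordinates of already-unwrapped voxels.
    phases
        Their *unwrapped* phase values (radians).
    orders
        Requested per-axis polynomial orders ``(L, M, N)``.
    fallback
        Automatically reduce orders for sparse point sets (see
        :func:`effective_orders`).

    The solution is the minimum-norm least-squares solution (singular values
    below ``1e-10`` of the largest are truncated), so rank-deficient point
    configurations — coplanar interfaces are common — are handled gracefully.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    ph = np.asarray(phases, dtype=float).ravel()
    if pts.shape[0] == 0:
        raise ValueError("cannot fit a polynomial to an empty point set")
    if pts.shape[0] != ph.size:
        raise ValueError("points and phases must have matching lengths")
    eff = effective_orders(pts.shape[0], orders, fallback)
    center = pts.mean(axis=0)
    half_extent = (pts.max(axis=0) - pts.min(axis=0)) / 2.0
    scale = np.maximum(1.0, half_extent)
    A = polynomial_basis(pts, eff, center, scale)
    coeffs, _, _, _ = np.linalg.lstsq(A, ph, rcond=RCOND)
    resid = ph - A @ coeffs
    rms = float(np.sqrt(np.mean(resid ** 2)))
    return PolyFit(orders=eff, coeffs=coeffs, center=center, scale=scale, fit_rms=rms)


def estimate_voxel_offset(fit: PolyFit, voxel, wrapped_phase: float) -> int:
    """Integer 2*pi offset of one voxel from a local fit.

    ``k = round((prediction - wrapped) / 2*pi)``; the unwrapped value is
    then ``wrapped + 2*pi*k``.
    """
    pred = fit.predict(np.asarray(voxel, dtype=float))
    if not np.isfinite(pred):
        raise ValueError("polynomial prediction is non-finite")
    return int(np.round((pred - wrapped_phase) / TWO_PI))
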