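"""Marginal B-spline bases and difference penalties for 2D P-splines.

The log-hazard surface is expanded in a tensor product of two marginal
B-spline bases, one along each time axis, with anisotropic difference
penalties on the rows and columns of the coefficient matrix (the standard
P-spline construction).  Coefficient matrices ``A`` (c_u x c_s) are
vectorized column-major, so that ``vec(Bu A Bs') = (Bs kron Bu) vec(A)``;
the penalty matrix below uses the same convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

DEFAULT_DEGREE = 3
DEFAULT_PENALTY_ORDER = 2


@dataclass(frozen=True)
class MarginalBasis:
    """B-spline basis on equally spaced knots over a closed domain."""

    degree: int
    n_seg: int
    domain: tuple
    B: np.ndarray  # n_points x c

    @property
    def c(self) -> int:
        return self.n_seg + self.degree

    @property
    def knots(self) -> np.ndarray:
        lo, hi = self.domain
        dx = (hi - lo) / self.n_seg
        return lo + dx * np.arange(-self.degree, self.n_seg + self.degree + 1)

    def evaluate(self, x) -> np.ndarray:
        """Evaluate the basis at new points (must lie inside the domain)."""
        return _design(np.asarray(x, dtype=float), self.domain,
                       self.n_seg, self.degree)


@dataclass(frozen=True)
class DifferencePenalty:
    """d-th order difference operator on a coefficient sequence."""

    order: int
    D: np.ndarray  # (c - d) x c


@dataclass(frozen=True)
class TensorSmoothSpec:
    """Marginal bases and penalties for one tensor-product smooth.

    The default segment counts (13 along u, 7 along s, cubic splines) give
    16 x 10 = 160 tensor coefficients on the standard 50 x 21 grid.
    """

    basis_u: MarginalBasis
    basis_s: MarginalBasis
    penalty_u: DifferencePenalty
    penalty_s: DifferencePenalty

    @property
    def c_u(self) -> int:
        return self.basis_u.c

    @property
    def c_s(self) -> int:
        return self.basis_s.c

    @classmethod
    def for_grid(cls, grid, nseg_u: int = 13, nseg_s: int = 7,
                 degree: int = DEFAULT_DEGREE,
                 penalty_order: int = DEFAULT_PENALTY_ORDER):
        """Build the spec for a grid, bases evaluated at the bin midpoints.

        Knots span the full grid range (bin edges), so derived quantities can
        be evaluated anywhere on the grid, including s = 0.
        """
        u_dom = (grid.u_min, grid.u_min + grid.n_u * grid.h_u)
        s_dom = (grid.s_min, grid.s_min + grid.n_s * grid.h_s)
        bu = bspline_basis(grid.u_mid, u_dom, nseg_u, degree)
        bs = bspline_basis(grid.s_mid, s_dom, nseg_s, degree)

        def pen(c):
            # a margin with c <= d coefficients cannot be differenced;
            # it gets an empty (vacuous) penalty
            if c > penalty_order:
                return difference_matrix(c, penalty_order)
            return DifferencePenalty(order=penalty_order,
                                     D=np.zeros((0, c)))

        return cls(basis_u=bu, basis_s=bs,
                   penalty_u=pen(bu.c), penalty_s=pen(bs.c))


def _design(x: np.ndarray, domain, n_seg: int, degree: int) -> np.ndarray:
    lo, hi = float(domain[0]), float(domain[1])
    if np.any(x < lo) or np.any(x > hi):
        raise ValueError(
            f"evaluation points outside the basis domain [{lo}, {hi}]"
        )
    dx = (hi - lo) / n_seg
    knots = lo + dx * np.arange(-degree, n_seg + degree + 1)
    return BSpline.design_matrix(x, knots, degree, extrapolate=False).toarray()


def bspline_basis(x, domain, n_seg: int, degree: int = DEFAULT_DEGREE
                  ) -> MarginalBasis:
    """B-spline basis on ``n_seg`` equal knot segments spanning ``domain``.

    The basis has ``n_seg + degree`` functions; knots are extended ``degree``
    segments beyond each end of the domain.  Rows sum to one (partition of
    unity) for any x inside the domain.
    """
    if n_seg < 1:
        raise ValueError("n_seg must be >= 1")
    if degree < 0:
        raise ValueError("degree must be >= 0")
    lo, hi = float(domain[0]), float(domain[1])
    if not hi > lo:
        raise ValueError("domain must be nondegenerate")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    B = _design(x, (lo, hi), n_seg, degree)
    return MarginalBasis(degree=degree, n_seg=n_seg, domain=(lo, hi), B=B)


def difference_matrix(c: int, d: int) -> DifferencePenalty:
    """d-th order difference matrix of shape (c - d) x c.

    Annihilates polynomial sequences of degree < d; e.g. for d = 2 each row
    is (..., 1, -2, 1, ...).
    """
    if d < 1:
        raise ValueError("difference order d must be >= 1")
    if c <= d:
        raise ValueError(f"need c > d (got c={c}, d={d})")
    D = np.diff(np.eye(c), n=d, axis=0)
    return DifferencePenalty(order=d, D=D)


def penalty_matrix(rho_u: float, rho_s: float,
                   Du: DifferencePenalty, Ds: DifferencePenalty,
                   c_u: int, c_s: int) -> np.ndarray:
    """Anisotropic tensor penalty on column-major vectorized coefficients.

    ``P = rho_u (I_s kron Du'Du) + rho_s (Ds'Ds kron I_u)`` so that the
    quadratic form ``vec(A)' P vec(A)`` equals
    ``rho_u ||Du A||_F^2 + rho_s ||A Ds'||_F^2``.
    """
    if rho_u < 0 or rho_s < 0:
        raise ValueError("smoothing parameters must be nonnegative")
    if Du.D.shape[1] != c_u or Ds.D.shape[1] != c_s:
        raise ValueError("difference matrices do not match basis sizes")
    PuTPu = Du.D.T @ Du.D
    PsTPs = Ds.D.T @ Ds.D
    return (rho_u * np.kron(np.eye(c_s), PuTPu)
            + rho_s * np.kron(PsTPs, np.eye(c_u)))
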