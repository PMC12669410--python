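"""Penalized composite link model (PCLM) for ungrouping coarse age intervals.

Registry data often report age at diagnosis in single years up to some age
and one open-ended top category (e.g. "90+").  To restore the fine regular
grid needed for array-based hazard smoothing, the open-ended category is
ungrouped with a two-dimensional PCLM: the observed coarse counts are
Poisson with means ``C_u Gamma C_s'`` where ``Gamma = exp(Bu Theta Bs')``
is a smooth positive latent surface on the fine grid and the composition
matrices aggregate fine bins into the observed categories.  The latent
surface carries the same anisotropic difference penalty as the hazard
model, with its own smoothing parameters selected by AIC over a log10 grid.

Only the open group's mass is redistributed: observed single-age rows pass
through unchanged, and within the open group the grouped total of each
s-column is split over the fine bins proportionally to the fitted latent
surface, conserving mass exactly.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .basis import TensorSmoothSpec, penalty_matrix
from .binning import BinnedCompRisks, TwoTimeGrid
from .fit import ETA_CAP

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CompositionMatrix:
    """Aggregation of fine grid rows/columns into observed coarse categories."""

    C_u: np.ndarray  # n_coarse_u x n_u, zero/one, contiguous blocks
    C_s: np.ndarray  # n_coarse_s x n_s (identity when s is not grouped)
    open_row: int | None = None    # index of the open-group coarse row
    fine_start: int | None = None  # first fine u-bin inside the open group


@dataclass
class PclmFit:
    """Fitted latent surface of one PCLM run."""

    theta_hat: np.ndarray     # c_u x c_s coefficients
    gamma_hat: np.ndarray     # n_u x n_s latent expected counts (positive)
    phi_u: float
    phi_s: float
    deviance: float
    ed: float
    aic: float
    converged: bool
    n_iter: int

    @property
    def fitted_coarse(self):
        return self._Cu @ self.gamma_hat @ self._Cs.T

    _Cu: np.ndarray = None
    _Cs: np.ndarray = None


def build_composition(grid: TwoTimeGrid, open_group_start: float
                      ) -> CompositionMatrix:
    """Composition for single fine bins below the cut plus one open group.

    ``open_group_start`` must coincide with a u-bin edge.  With it equal to
    the top edge the composition is the identity (no grouping).
    """
    edges = grid.u_edges
    pos = np.flatnonzero(np.isclose(edges, open_group_start, atol=1e-9))
    if pos.size == 0:
        raise ValueError(
            f"open_group_start={open_group_start} is not a u-bin edge")
    j0 = int(pos[0])
    n_u = grid.n_u
    if j0 == n_u:
        C_u = np.eye(n_u)
        return CompositionMatrix(C_u=C_u, C_s=np.eye(grid.n_s),
                                 open_row=None, fine_start=None)
    C_u = np.zeros((j0 + 1, n_u))
    C_u[np.arange(j0), np.arange(j0)] = 1.0
    C_u[j0, j0:] = 1.0
    return CompositionMatrix(C_u=C_u, C_s=np.eye(grid.n_s),
                             open_row=j0, fine_start=j0)


def fit_pclm(Y_coarse: np.ndarray, comp: CompositionMatrix,
             spec: TensorSmoothSpec, phi_u: float, phi_s: float,
             tol: float = 1e-7, max_iter: int = 50,
             theta0: np.ndarray | None = None) -> PclmFit:
    """Fit the 2D PCLM at fixed smoothing parameters (phi_u, phi_s).

    IWLS on the composite design ``X = diag(1/mu) C diag(gamma) B`` with
    Poisson weights ``W = diag(mu)``; the same scheme serves exposures
    treated as continuous nonnegative quasi-counts.
    """
    Y_coarse = np.asarray(Y_coarse, dtype=float)
    if np.any(Y_coarse < 0):
        raise ValueError("coarse counts must be nonnegative")
    Bu, Bs = spec.basis_u.B, spec.basis_s.B
    c_u, c_s = spec.c_u, spec.c_s
    n_u, n_s = Bu.shape[0], Bs.shape[0]
    if comp.C_u.shape[1] != n_u or comp.C_s.shape[1] != n_s:
        raise ValueError("composition does not match the fine grid")
    if Y_coarse.shape != (comp.C_u.shape[0], comp.C_s.shape[0]):
        raise ValueError("coarse counts do not match the composition")

    B = np.kron(Bs, Bu)                       # fine cells x (c_u c_s)
    C = np.kron(comp.C_s, comp.C_u)           # coarse cells x fine cells
    y = Y_coarse.ravel(order="F")
    P = penalty_matrix(phi_u, phi_s, spec.penalty_u, spec.penalty_s,
                       c_u, c_s)

    if theta0 is not None:
        theta = np.asarray(theta0, dtype=float).ravel(order="F").copy()
    else:
        # start from the flat surface carrying the observed total mass
        total = max(y.sum(), 1e-8)
        theta = np.full(c_u * c_s, np.log(total / (n_u * n_s)))

    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        gamma = np.exp(np.clip(B @ theta, -ETA_CAP, ETA_CAP))
        mu = C @ gamma
        mu = np.maximum(mu, 1e-12)
        X = (C * gamma[None, :]) @ B / mu[:, None]   # composite design
        z = X @ theta + (y - mu) / mu
        XtW = X.T * mu[None, :]
        lhs = XtW @ X + P
        rhs = XtW @ z
        theta_new = np.linalg.solve(lhs, rhs)
        delta = np.max(np.abs(theta_new - theta))
        theta = theta_new
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("PCLM did not converge in %d iterations "
                       "(phi_u=%.3g, phi_s=%.3g)", max_iter, phi_u, phi_s)

    gamma = np.exp(np.clip(B @ theta, -ETA_CAP, ETA_CAP))
    mu = np.maximum(C @ gamma, 1e-12)
    X = (C * gamma[None, :]) @ B / mu[:, None]
    XtW = X.T * mu[None, :]
    XtWX = XtW @ X
    ed = float(np.trace(np.linalg.solve(XtWX + P, XtWX)))
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(np.where(y > 0, y, 1.0) / mu), 0.0)
    dev = float(2.0 * np.sum(term - (y - mu)))
    return PclmFit(theta_hat=theta.reshape(c_u, c_s, order="F"),
                   gamma_hat=gamma.reshape(n_u, n_s, order="F"),
                   phi_u=phi_u, phi_s=phi_s, deviance=dev, ed=ed,
                   aic=dev + 2.0 * ed, converged=converged, n_iter=n_iter,
                   _Cu=comp.C_u, _Cs=comp.C_s)


def select_pclm_smoothing(Y_coarse, comp: CompositionMatrix,
                          spec: TensorSmoothSpec,
                          log10_lo: float = -1.0, log10_hi: float = 2.0,
                          step: float = 0.5) -> PclmFit:
    """Exhaustive AIC grid search over log10(phi_u), log10(phi_s).

    Default grid is [-1, 2] in steps of 0.5 on each axis (7 x 7 nodes).
    """
    grid = np.arange(log10_lo, log10_hi + 1e-9, step)
    best = None
    warm = None
    for lu, ls in itertools.product(grid, grid):
        f = fit_pclm(Y_coarse, comp, spec, 10.0 ** lu, 10.0 ** ls,
                     theta0=warm)
        warm = f.theta_hat
        if best is None or f.aic < best.aic:
            best = f
    if (np.isclose(np.log10(best.phi_u), (log10_lo, log10_hi)).any()
            or np.isclose(np.log10(best.phi_s), (log10_lo, log10_hi)).any()):
        logger.warning("PCLM smoothing parameters on the search boundary: "
                       "log10 phi=(%.1f, %.1f)",
                       np.log10(best.phi_u), np.log10(best.phi_s))
    return best


def _redistribute(arr_coarse: np.ndarray, comp: CompositionMatrix,
                  spec: TensorSmoothSpec, n_u: int,
                  phi_grid=(-1.0, 2.0, 0.5)) -> np.ndarray:
    """Ungroup one coarse array: pass observed rows through, split the open
    group proportionally to the fitted latent surface (mass-conserving)."""
    j0 = comp.fine_start
    fine = np.zeros((n_u, arr_coarse.shape[1]))
    fine[:j0] = arr_coarse[:j0]
    group = arr_coarse[comp.open_row]          # per s-column totals
    if group.sum() == 0:
        return fine
    pf = select_pclm_smoothing(arr_coarse, comp, spec,
                               log10_lo=phi_grid[0], log10_hi=phi_grid[1],
                               step=phi_grid[2])
    weights = pf.gamma_hat[j0:]                # latent surface in the group
    colsum = weights.sum(axis=0)
    weights = np.where(colsum > 0, weights / np.where(colsum > 0, colsum, 1.0),
                       1.0 / weights.shape[0])
    fine[j0:] = weights * group[None, :]
    return fine


def ungroup_dataset(Y1_coarse, Y2_coarse, R_coarse,
                    comp: CompositionMatrix, grid: TwoTimeGrid,
                    spec: TensorSmoothSpec,
                    phi_grid=(-1.0, 2.0, 0.5)) -> BinnedCompRisks:
    """Ungroup a coarse dataset back onto the fine grid.

    The PCLM is applied separately to each event-count matrix and to the
    exposure matrix (as a quasi-count surface).  Rows below the open group
    pass through unchanged; within the open group each s-column's total is
    redistributed proportionally to the fitted latent surface, so column
    sums over the group equal the grouped totals exactly.  Ungrouped counts
    are generally non-integer, which the Poisson working likelihood of the
    downstream hazard fit accepts.
    """
    if comp.open_row is None:
        return BinnedCompRisks(grid=grid, R=np.asarray(R_coarse, float),
                               Y=[np.asarray(Y1_coarse, float),
                                  np.asarray(Y2_coarse, float)])
    Y1 = _redistribute(np.asarray(Y1_coarse, float), comp, spec, grid.n_u,
                       phi_grid)
    Y2 = _redistribute(np.asarray(Y2_coarse, float), comp, spec, grid.n_u,
                       phi_grid)
    R = _redistribute(np.asarray(R_coarse, float), comp, spec, grid.n_u,
                      phi_grid)
    # an ungrouped cell may carry events but (numerically) no exposure;
    # give it the smallest positive exposure seen in the group
    bad = ((Y1 > 0) | (Y2 > 0)) & (R <= 0)
    if bad.any():
        rmin = R[R > 0].min()
        R[bad] = rmin
        logger.warning("%d ungrouped cell(s) had events but zero exposure; "
                       "floored exposure at %.3g", int(bad.sum()), rmin)
    return BinnedCompRisks(grid=grid, R=R, Y=[Y1, Y2])
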