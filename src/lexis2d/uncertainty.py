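"""Uncertainty: coefficient covariance, delta-method SEs, bootstrap CIs.

The coefficient variance-covariance of each penalized Poisson fit is the
inverse penalized information ``(B' W B + P)^-1`` (Bayesian argument for
P-splines).  Standard errors of the log-hazard follow by quadratic forms in
the evaluated tensor basis, and of the hazard itself by the delta method,
``se(lambda) = lambda se(eta)``.  Confidence intervals for cumulative
incidence functions come from a nonparametric bootstrap: individuals are
resampled with replacement, the full pipeline (optional ungrouping, hazard
fits, CIF quadrature) is re-run per replicate, and normal-based intervals
use the empirical standard deviation across replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import norm

from .basis import penalty_matrix
from .binning import bin_individuals
from .derived import cumulative_incidence
from .fit import FitControl, SearchControl, fit_cause, select_smoothing
from .glam import ArrayModelWorkspace, glam_inner
from .pclm import build_composition, ungroup_dataset

logger = logging.getLogger(__name__)


def coef_covariance(fit) -> np.ndarray:
    """Variance-covariance ``(B'WB + P)^-1`` of the tensor coefficients.

    Computed by a Cholesky solve against the identity; raises if the
    penalized information is not positive definite (near-zero smoothing on
    deficient data).
    """
    spec = fit.spec
    ws = ArrayModelWorkspace(spec.basis_u.B, spec.basis_s.B)
    F = glam_inner(ws, fit.mu_hat) + penalty_matrix(
        fit.rho_u, fit.rho_s, spec.penalty_u, spec.penalty_s,
        spec.c_u, spec.c_s)
    try:
        cf = cho_factor(F)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"penalized information is singular at rho_u={fit.rho_u}, "
            f"rho_s={fit.rho_s}; increase the smoothing parameters"
        ) from exc
    Sigma = cho_solve(cf, np.eye(F.shape[0]))
    return (Sigma + Sigma.T) / 2.0


def se_linear_predictor(Sigma: np.ndarray, fit, u_points, s_points
                        ) -> np.ndarray:
    """Pointwise standard error of the log-hazard surface.

    ``se(eta)(u, s) = sqrt(b' Sigma b)`` with ``b = Bs(s) kron Bu(u)`` the
    evaluated tensor basis row, computed for the outer product of the point
    vectors without forming the Kronecker rows.
    """
    Bu = fit.spec.basis_u.evaluate(np.atleast_1d(u_points))
    Bs = fit.spec.basis_s.evaluate(np.atleast_1d(s_points))
    c_u, c_s = fit.spec.c_u, fit.spec.c_s
    # F-order vec index (l + c_u*m) -> C-order reshape axes are (m, l)
    S4 = Sigma.reshape(c_s, c_u, c_s, c_u)
    var = np.einsum("il,jm,mlnp,ip,jn->ij", Bu, Bs, S4, Bu, Bs,
                    optimize=True)
    return np.sqrt(np.maximum(var, 0.0))


def se_hazard(lambda_hat: np.ndarray, se_eta: np.ndarray) -> np.ndarray:
    """Delta-method SE of the hazard: ``se(lambda) = lambda * se(eta)``."""
    return np.asarray(lambda_hat) * np.asarray(se_eta)


@dataclass
class BootstrapResult:
    """Bootstrap distribution of the CIFs on a (u, s) evaluation grid."""

    n_rep: int
    n_failed: int
    seed: int
    level: float
    u_values: np.ndarray
    s_values: np.ndarray
    estimate: np.ndarray   # (2, n_u, n_s) point-estimate CIFs
    replicates: np.ndarray  # (n_ok, 2, n_u, n_s)
    se: np.ndarray         # (2, n_u, n_s)
    ci_lo: np.ndarray
    ci_hi: np.ndarray


def _fit_pair(binned, spec, rho, criterion, search, control):
    fits = []
    for ell in (1, 2):
        if rho is not None:
            ru, rs = rho[ell - 1]
            fits.append(fit_cause(binned.Y[ell - 1], binned.R, spec,
                                  ru, rs, control=control, cause=ell))
        else:
            fits.append(select_smoothing(binned.Y[ell - 1], binned.R, spec,
                                         criterion=criterion, search=search,
                                         control=control, cause=ell))
    return fits


def bootstrap_cif(records, grid, spec, u_values, s_max: float,
                  delta: float = 0.01, n_rep: int = 500, seed: int = 0,
                  level: float = 0.95, rho=None, criterion: str = "bic",
                  open_group_start: float | None = None,
                  percentile: bool = False,
                  search: SearchControl | None = None,
                  control: FitControl | None = None) -> BootstrapResult:
    """Nonparametric bootstrap confidence intervals for the CIFs.

    Individuals are resampled with replacement (sample size n).  Each
    replicate re-runs the pipeline: binning, optional PCLM ungrouping of the
    open age group, both cause-specific fits, and the CIF quadrature at
    ``u_values`` over ``s in {0, delta, ..., s_max}``.  With ``rho`` given
    (a pair of ``(rho_u, rho_s)`` tuples, one per cause) the smoothing
    parameters are held fixed across replicates; otherwise they are
    re-selected in every replicate.  Intervals are normal-based by default
    (``estimate +/- z * se``); ``percentile=True`` switches to empirical
    quantiles.  Replicate seeds derive deterministically from ``seed``.
    """
    if n_rep < 2:
        raise ValueError("n_rep must be >= 2")
    records = list(records)
    n = len(records)
    u_values = np.atleast_1d(np.asarray(u_values, dtype=float))
    rng = np.random.default_rng(seed)
    comp = (build_composition(grid, open_group_start)
            if open_group_start is not None else None)

    def run(recs):
        binned = bin_individuals(recs, grid)
        if comp is not None and comp.open_row is not None:
            Yc = [comp.C_u @ Yl for Yl in binned.Y]
            Rc = comp.C_u @ binned.R
            binned = ungroup_dataset(Yc[0], Yc[1], Rc, comp, grid, spec)
        f1, f2 = _fit_pair(binned, spec, rho, criterion, search, control)
        s_nodes, I1, I2, _ = cumulative_incidence(f1, f2, u_values, s_max,
                                                  delta)
        return s_nodes, np.stack([I1, I2])

    s_values, estimate = run(records)

    reps = []
    n_failed = 0
    for b in range(n_rep):
        idx = rng.integers(0, n, size=n)
        try:
            _, Ib = run([records[i] for i in idx])
            reps.append(Ib)
        except Exception as exc:  # noqa: BLE001 - replicate-level robustness
            n_failed += 1
            logger.warning("bootstrap replicate %d failed: %r", b, exc)
    if n_failed > 0.1 * n_rep:
        raise RuntimeError(
            f"{n_failed}/{n_rep} bootstrap replicates failed")

    reps = np.stack(reps)
    se = reps.std(axis=0, ddof=1)
    if percentile:
        alpha = 1.0 - level
        ci_lo = np.quantile(reps, alpha / 2, axis=0)
        ci_hi = np.quantile(reps, 1 - alpha / 2, axis=0)
    else:
        z = norm.ppf(0.5 + level / 2.0)
        ci_lo = estimate - z * se
        ci_hi = estimate + z * se
    return BootstrapResult(n_rep=n_rep, n_failed=n_failed, seed=seed,
                           level=level, u_values=u_values, s_values=s_values,
                           estimate=estimate, replicates=reps, se=se,
                           ci_lo=ci_lo, ci_hi=ci_hi)
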