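"""Derived quantities: cumulative hazards, survival, cumulative incidences.

The fitted tensor-product log-hazard can be evaluated anywhere inside the
basis domains.  Because an individual's age at diagnosis ``u`` is fixed,
cumulative quantities are one-dimensional integrals along ``s`` at fixed
``u``; they are computed by a left-rectangle rule on a uniform step
``Delta``:

    Lambda(u, s) ~ sum_{k=0..K(s)} lambda(u, k Delta) Delta

with ``K(s)`` the largest integer with ``K(s) Delta < s``.  Survival is
``S = exp(-Lambda1 - Lambda2)`` and the cause-specific cumulative incidence
uses the survival at the same quadrature nodes.  Results can be reindexed
to the (t, s) parameterization (t = current age, u = t - s); the quadrature
itself always runs in (u, s), where the integration path is a vertical line.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_DELTA = 0.01


@dataclass
class DerivedSurfaces:
    """Cumulative hazards, survival and CIFs on a (u, s) prediction grid."""

    u_values: np.ndarray     # n_u_pts
    s_values: np.ndarray     # n_s_pts, uniform step delta starting at 0
    delta: float
    Lambda: np.ndarray       # (2, n_u_pts, n_s_pts)
    S: np.ndarray            # (n_u_pts, n_s_pts)
    I: np.ndarray            # (2, n_u_pts, n_s_pts)

    def at(self, u: float, s: float, tol: float | None = None):
        """Nearest-node lookup of (S, I1, I2) at one (u, s) point."""
        tol = self.delta / 2 if tol is None else tol
        iu = int(np.argmin(np.abs(self.u_values - u)))
        js = int(np.argmin(np.abs(self.s_values - s)))
        if abs(self.s_values[js] - s) > tol + 1e-12:
            raise ValueError(f"s={s} not on the evaluated grid")
        if abs(self.u_values[iu] - u) > 1e-9:
            raise ValueError(f"u={u} not among the evaluated u values")
        return (float(self.S[iu, js]), float(self.I[0, iu, js]),
                float(self.I[1, iu, js]))


def evaluate_hazard(fit, u_points, s_points):
    """Evaluate the fitted hazard surface at arbitrary in-domain points.

    Returns ``(lambda, eta)`` on the outer product of ``u_points`` and
    ``s_points``.  Points outside the marginal basis domains raise an error
    (extrapolation beyond the basis support is not defined).
    """
    Bu = fit.spec.basis_u.evaluate(np.atleast_1d(u_points))
    Bs = fit.spec.basis_s.evaluate(np.atleast_1d(s_points))
    eta = Bu @ fit.A_hat @ Bs.T
    return np.exp(eta), eta


def hazard_function(fit):
    """Wrap a fit as a callable ``lam(u_points, s_points) -> surface``."""
    def lam(u_points, s_points):
        return evaluate_hazard(fit, u_points, s_points)[0]
    return lam


def _as_hazard_fn(obj):
    if callable(obj):
        return obj
    return hazard_function(obj)


def _node_grid(s_max: float, delta: float) -> np.ndarray:
    if delta <= 0:
        raise ValueError("quadrature step delta must be positive")
    m = int(round(s_max / delta))
    if abs(m * delta - s_max) > 1e-9 * max(1.0, s_max):
        m = int(np.floor(s_max / delta))
    return delta * np.arange(m + 1)


def cumulative_hazard(fit_or_fn, u, s_max: float,
                      delta: float = DEFAULT_DELTA):
    """Left-rectangle cumulative hazard along s at fixed u.

    Returns ``(s_values, Lambda)`` where ``Lambda[..., m]`` integrates the
    hazard over ``[0, m delta)`` using nodes ``k delta, k < m``.
    """
    lam_fn = _as_hazard_fn(fit_or_fn)
    s_nodes = _node_grid(s_max, delta)
    u_arr = np.atleast_1d(np.asarray(u, dtype=float))
    lam = np.asarray(lam_fn(u_arr, s_nodes), dtype=float)
    if np.any(lam < 0):
        raise ValueError("hazard values must be nonnegative")
    Lambda = np.concatenate(
        [np.zeros((lam.shape[0], 1)), np.cumsum(lam[:, :-1], axis=1) * delta],
        axis=1)
    if np.isscalar(u) or np.ndim(u) == 0:
        return s_nodes, Lambda[0]
    return s_nodes, Lambda


def overall_survival(Lambda1, Lambda2):
    """Overall survival ``S = exp(-(Lambda1 + Lambda2))``."""
    L1 = np.asarray(Lambda1, dtype=float)
    L2 = np.asarray(Lambda2, dtype=float)
    if np.any(L1 < 0) or np.any(L2 < 0):
        raise ValueError("cumulative hazards must be nonnegative")
    return np.exp(-(L1 + L2))


def cumulative_incidence(fit1, fit2, u, s_max: float,
                         delta: float = DEFAULT_DELTA):
    """Cause-specific cumulative incidences with the competing cause.

    Returns ``(s_values, I1, I2, S)``; the survival entering the integrand
    is evaluated at the same left-rectangle quadrature nodes.
    """
    lam1 = _as_hazard_fn(fit1)
    lam2 = _as_hazard_fn(fit2)
    s_nodes = _node_grid(s_max, delta)
    u_arr = np.atleast_1d(np.asarray(u, dtype=float))
    l1 = np.asarray(lam1(u_arr, s_nodes), dtype=float)
    l2 = np.asarray(lam2(u_arr, s_nodes), dtype=float)
    zero = np.zeros((l1.shape[0], 1))
    L1 = np.concatenate([zero, np.cumsum(l1[:, :-1], axis=1) * delta], axis=1)
    L2 = np.concatenate([zero, np.cumsum(l2[:, :-1], axis=1) * delta], axis=1)
    S = overall_survival(L1, L2)
    I1 = np.concatenate(
        [zero, np.cumsum((l1 * S)[:, :-1], axis=1) * delta], axis=1)
    I2 = np.concatenate(
        [zero, np.cumsum((l2 * S)[:, :-1], axis=1) * delta], axis=1)
    if np.isscalar(u) or np.ndim(u) == 0:
        return s_nodes, I1[0], I2[0], S[0]
    return s_nodes, I1, I2, S


def derive_surfaces(fit1, fit2, u_values, s_max: float,
                    delta: float = DEFAULT_DELTA) -> DerivedSurfaces:
    """Evaluate all derived surfaces on the grid u_values x {0, delta, ...}."""
    u_values = np.atleast_1d(np.asarray(u_values, dtype=float))
    s_nodes, I1, I2, S = cumulative_incidence(fit1, fit2, u_values, s_max,
                                              delta)
    _, L1 = cumulative_hazard(fit1, u_values, s_max, delta)
    _, L2 = cumulative_hazard(fit2, u_values, s_max, delta)
    return DerivedSurfaces(u_values=u_values, s_values=s_nodes, delta=delta,
                           Lambda=np.stack([L1, L2]), S=S,
                           I=np.stack([I1, I2]))


def reparameterize_ts(fit_or_fn, t_points, s_points):
    """Evaluate a (u, s) hazard surface on (t, s) points via u = t - s.

    Only points with t > s are admissible (age exceeds time since
    diagnosis); ``u = t - s`` must lie inside the basis domain.
    """
    lam_fn = _as_hazard_fn(fit_or_fn)
    t = np.atleast_1d(np.asarray(t_points, dtype=float))
    s = np.atleast_1d(np.asarray(s_points, dtype=float))
    out = np.empty((t.size, s.size))
    for j, sj in enumerate(s):
        bad = t <= sj
        if bad.any():
            raise ValueError(
                f"t must exceed s (violated at t={t[bad][0]}, s={sj})")
        u = t - sj
        # each s needs its own u's: evaluate column by column
        out[:, j] = np.asarray(lam_fn(u, np.array([sj])))[:, 0]
    return out
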