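"""Penalized Poisson IWLS: deviance, convergence, ED, criteria, selection."""

import numpy as np
import pytest

import lexis2d as lx
from lexis2d.basis import penalty_matrix
from lexis2d.fit import (FitControl, SearchControl, effective_dimension,
                         information_criteria)
from lexis2d.glam import kron_design


def dense_penalized_poisson(Y, R, spec, rho_u, rho_s, n_iter=100):
    """Independent oracle: Newton iteration on the dense Kronecker design."""
    B = kron_design(spec.basis_u.B, spec.basis_s.B)
    P = penalty_matrix(rho_u, rho_s, spec.penalty_u, spec.penalty_s,
                       spec.c_u, spec.c_s)
    y = Y.ravel(order="F")
    r = R.ravel(order="F")
    keep = r > 0
    alpha = np.zeros(B.shape[1])
    for _ in range(n_iter):
        eta = B @ alpha
        mu = np.where(keep, r * np.exp(eta), 0.0)
        grad = B.T @ (y - mu) - P @ alpha
        H = B.T @ (mu[:, None] * B) + P
        step = np.linalg.solve(H, grad)
        alpha = alpha + step
        if np.abs(step).max() < 1e-12:
            break
    return alpha.reshape(spec.c_u, spec.c_s, order="F")


class TestPoissonDeviance:
    def test_perfect_fit_is_zero(self):
        Y = np.array([[1.0, 3.0], [0.0, 2.0]])
        assert lx.poisson_deviance(Y, np.where(Y > 0, Y, 1.0),
                                   mask=Y > 0) == pytest.approx(0.0)

    def test_closed_form_values(self):
        # y=2, mu=1 -> 4 ln 2 - 2; y=0, mu=1 -> 2 (0 ln 0 = 0 convention)
        assert lx.poisson_deviance(np.array([[2.0]]), np.array([[1.0]])) \
            == pytest.approx(4 * np.log(2) - 2)
        assert lx.poisson_deviance(np.array([[0.0]]), np.array([[1.0]])) \
            == pytest.approx(2.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            lx.poisson_deviance(np.array([[-1.0]]), np.array([[1.0]]))


class TestFitCause:
    def test_constant_basis_recovers_occurrence_exposure_rate(self):
        # with a single flat basis function the MLE is sum(Y)/sum(R)
        grid = lx.build_grid((0, 4), (0, 3), 1.0, 1.0)
        spec = lx.TensorSmoothSpec.for_grid(grid, nseg_u=1, nseg_s=1,
                                            degree=0, penalty_order=1)
        rng = np.random.default_rng(0)
        R = rng.uniform(1, 10, size=(4, 3))
        Y = rng.poisson(0.7 * R).astype(float)
        f = lx.fit_cause(Y, R, spec, 0.0, 0.0)
        np.testing.assert_allclose(np.exp(f.eta_hat), Y.sum() / R.sum(),
                                   rtol=1e-8)

    def test_huge_penalty_gives_bilinear_surface(self, small_problem):
        grid, spec, Y, R = small_problem
        spec2 = lx.TensorSmoothSpec.for_grid(grid, nseg_u=3, nseg_s=2,
                                             degree=3, penalty_order=2)
        f = lx.fit_cause(Y, R, spec2, 1e10, 1e10)
        # residual of eta from its own bilinear least-squares fit
        u, s = np.meshgrid(grid.u_mid, grid.s_mid, indexing="ij")
        X = np.column_stack([np.ones(u.size), u.ravel(), s.ravel(),
                             (u * s).ravel()])
        beta, *_ = np.linalg.lstsq(X, f.eta_hat.ravel(), rcond=None)
        resid = f.eta_hat.ravel() - X @ beta
        assert np.abs(resid).max() < 1e-4

    def test_gradient_vanishes_at_solution(self, small_problem):
        # oracle: central finite differences of the penalized deviance
        grid, spec, Y, R = small_problem
        rho_u, rho_s = 2.0, 5.0
        f = lx.fit_cause(Y, R, spec, rho_u, rho_s,
                         control=FitControl(tol=1e-10, max_iter=200))
        Du, Ds = spec.penalty_u.D, spec.penalty_s.D

        def pdev(A):
            mu = R * np.exp(spec.basis_u.B @ A @ spec.basis_s.B.T)
            return (lx.poisson_deviance(Y, mu)
                    + rho_u * np.sum((Du @ A) ** 2)
                    + rho_s * np.sum((A @ Ds.T) ** 2))

        h = 1e-6
        for idx in [(0, 0), (1, 2), (3, 1)]:
            Ap, Am = f.A_hat.copy(), f.A_hat.copy()
            Ap[idx] += h
            Am[idx] -= h
            g = (pdev(Ap) - pdev(Am)) / (2 * h)
            assert abs(g) < 1e-5

    def test_matches_dense_oracle(self, small_problem):
        grid, spec, Y, R = small_problem
        f = lx.fit_cause(Y, R, spec, 3.0, 0.5,
                         control=FitControl(tol=1e-12, max_iter=200))
        A_oracle = dense_penalized_poisson(Y, R, spec, 3.0, 0.5)
        np.testing.assert_allclose(f.A_hat, A_oracle, rtol=1e-6, atol=1e-8)

    def test_matches_statsmodels_unpenalized(self, small_problem):
        # independent GLM route: Poisson with log link and log-exposure offset
        sm = pytest.importorskip("statsmodels.api")
        grid, spec, Y, R = small_problem
        f = lx.fit_cause(Y, R, spec, 0.0, 0.0,
                         control=FitControl(tol=1e-12, max_iter=200))
        B = kron_design(spec.basis_u.B, spec.basis_s.B)
        model = sm.GLM(Y.ravel(order="F"), B, family=sm.families.Poisson(),
                       offset=np.log(R.ravel(order="F")))
        res = model.fit()
        np.testing.assert_allclose(f.A_hat.ravel(order="F"), res.params,
                                   rtol=1e-5, atol=1e-7)

    def test_fitted_total_matches_observed_total(self, small_problem):
        # intercept lies in the d=2 penalty null space, so sum(mu) = sum(y)
        grid, spec, Y, R = small_problem
        for rho in (0.1, 100.0):
            f = lx.fit_cause(Y, R, spec, rho, rho,
                             control=FitControl(tol=1e-10, max_iter=200))
            assert f.mu_hat.sum() == pytest.approx(Y.sum(), rel=1e-6)

    def test_zero_exposure_cells_excluded(self):
        grid = lx.build_grid((0, 5), (0, 4), 1.0, 1.0)
        spec = lx.TensorSmoothSpec.for_grid(grid, nseg_u=2, nseg_s=1,
                                            degree=1, penalty_order=1)
        rng = np.random.default_rng(1)
        R = rng.uniform(2, 10, size=(5, 4))
        R[0, :] = 0.0
        Y = rng.poisson(0.5 * R).astype(float)
        f = lx.fit_cause(Y, R, spec, 1.0, 1.0)
        assert f.n_bin == int((R > 0).sum())
        assert np.all(f.mu_hat[R == 0] == 0)

    def test_event_in_zero_exposure_cell_rejected(self, small_problem):
        grid, spec, Y, R = small_problem
        R = R.copy()
        Y = Y.copy()
        R[0, 0] = 0.0
        Y[0, 0] = 1.0
        with pytest.raises(ValueError, match="zero exposure"):
            lx.fit_cause(Y, R, spec, 1.0, 1.0)


class TestEffectiveDimension:
    def test_unpenalized_full_rank_equals_n_coef(self, small_problem):
        grid, spec, Y, R = small_problem
        f = lx.fit_cause(Y, R, spec, 0.0, 0.0)
        ed = effective_dimension(spec, f.mu_hat, 0.0, 0.0)
        assert ed == pytest.approx(spec.c_u * spec.c_s, rel=1e-8)

    def test_infinite_smoothing_limit_is_four(self, s1_binned, spec):
        f = lx.fit_cause(s1_binned.Y[0], s1_binned.R, spec, 1e10, 1e10)
        ed = effective_dimension(spec, f.mu_hat, 1e10, 1e10)
        assert ed == pytest.approx(4.0, abs=0.05)

    def test_matches_dense_hat_matrix_trace(self, small_problem):
        grid, spec, Y, R = small_problem
        f = lx.fit_cause(Y, R, spec, 2.0, 7.0)
        B = kron_design(spec.basis_u.B, spec.basis_s.B)
        P = penalty_matrix(2.0, 7.0, spec.penalty_u, spec.penalty_s,
                           spec.c_u, spec.c_s)
        w = f.mu_hat.ravel(order="F")
        H = B @ np.linalg.solve(B.T @ (w[:, None] * B) + P,
                                B.T * w[None, :])
        ed = effective_dimension(spec, f.mu_hat, 2.0, 7.0)
        assert ed == pytest.approx(np.trace(H), abs=1e-8)

    def test_monotone_in_smoothing(self, small_problem):
        grid, spec, Y, R = small_problem
        rhos = np.logspace(-1, 5, 5)
        W = lx.fit_cause(Y, R, spec, 1.0, 1.0).mu_hat
        ED = np.array([[effective_dimension(spec, W, ru, rs)
                        for rs in rhos] for ru in rhos])
        assert np.all(np.diff(ED, axis=0) <= 1e-8)
        assert np.all(np.diff(ED, axis=1) <= 1e-8)


class TestInformationCriteria:
    def test_arithmetic(self):
        aic, bic = information_criteria(100.0, 10.0, int(np.e ** 2) + 1)
        assert aic == pytest.approx(120.0)
        # with n_bin = e^2 exactly, BIC would be 120 as well
        assert information_criteria(100.0, 10.0, 8)[1] == \
            pytest.approx(100.0 + np.log(8) * 10.0)

    def test_self_consistency_on_fit(self, small_problem):
        grid, spec, Y, R = small_problem
        f = lx.fit_cause(Y, R, spec, 1.0, 1.0)
        aic, bic = information_criteria(f.deviance, f.ed, f.n_bin)
        assert f.aic == aic and f.bic == bic
        assert f.aic < f.bic  # n_bin = 30 > e^2


class TestSelectSmoothing:
    def test_selected_bic_beats_every_coarse_node(self, s1_binned, spec):
        Y, R = s1_binned.Y[0], s1_binned.R
        search = SearchControl(coarse_step=2.0)
        best = lx.select_smoothing(Y, R, spec, criterion="bic",
                                   search=search)
        grid_nodes = np.arange(-1.0, 8.0 + 1e-9, 2.0)
        for lu in grid_nodes:
            for ls in grid_nodes:
                node = lx.fit_cause(Y, R, spec, 10.0 ** lu, 10.0 ** ls)
                assert best.bic <= node.bic + 1e-6

    def test_bic_smooths_at_least_as_much_as_aic(self, s1_binned, spec):
        Y, R = s1_binned.Y[0], s1_binned.R
        search = SearchControl(coarse_step=2.0, refine=False)
        f_bic = lx.select_smoothing(Y, R, spec, "bic", search=search)
        f_aic = lx.select_smoothing(Y, R, spec, "aic", search=search)
        assert f_bic.ed <= f_aic.ed + 1e-8

    def test_invalid_criterion_rejected(self, s1_binned, spec):
        with pytest.raises(ValueError):
            lx.select_smoothing(s1_binned.Y[0], s1_binned.R, spec,
                                criterion="dic")


class TestFitCompetingRisks:
    def test_swapping_cause_labels_swaps_fits(self, grid):
        sc = lx.default_scenarios()["S2"]
        sc.n = 2000
        coh = lx.simulate_cohort(sc, seed=5)
        b = lx.bin_individuals(coh.records, grid)
        swapped = lx.BinnedCompRisks(grid=grid, R=b.R, Y=[b.Y[1], b.Y[0]])
        search = SearchControl(coarse_step=3.0, refine=False)
        f = lx.fit_competing_risks(b, lx.TensorSmoothSpec.for_grid(grid),
                                   search=search)
        g = lx.fit_competing_risks(swapped,
                                   lx.TensorSmoothSpec.for_grid(grid),
                                   search=search)
        np.testing.assert_allclose(f[1].A_hat, g[2].A_hat, atol=1e-9)
        np.testing.assert_allclose(f[2].A_hat, g[1].A_hat, atol=1e-9)

    def test_zero_event_cause_yields_null_hazard(self, grid, spec):
        sc = lx.default_scenarios()["S3"]  # cause 2 absent
        sc.n = 3000
        coh = lx.simulate_cohort(sc, seed=9)
        b = lx.bin_individuals(coh.records, grid)
        assert b.Y[1].sum() == 0
        search = SearchControl(coarse_step=3.0, refine=False)
        crf = lx.fit_competing_risks(b, spec, search=search)
        support = b.R > 0
        assert np.all(crf[2].lambda_hat[support] < 1e-6)
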