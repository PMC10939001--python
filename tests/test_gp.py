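"""Gaussian-process surrogate: kernel, posterior, fitting, acquisition."""

import numpy as np
import pytest

from glycosurf.coordinates import SearchSpace, Variable
from glycosurf.gp import (GPModel, fit_hyperparameters, kernel_matrix,
                          log_marginal_likelihood, minimize_surface,
                          propose_next)


def space_1d(periodic=False, hi=1.0):
    return SearchSpace([Variable("x", 0.0, hi, periodic, "translation_x")])


def space_nd(bounds, periodic):
    return SearchSpace([
        Variable(f"x{i}", lo, hi, per, "translation_x")
        for i, ((lo, hi), per) in enumerate(zip(bounds, periodic))])


def closed_form_posterior(space, X, y, xq, sv, ls, nv):
    """Textbook GP conditional via explicit matrix inversion (oracle)."""
    K = kernel_matrix(space, X, X, sv, ls) + nv * np.eye(len(X))
    Ks = kernel_matrix(space, X, xq, sv, ls)
    Kinv = np.linalg.inv(K)
    ym = y.mean()
    mean = Ks.T @ Kinv @ (y - ym) + ym
    var = sv - np.einsum("ij,ik,kj->j", Ks, Kinv, Ks)
    return mean, np.sqrt(np.clip(var, 0, None))


class TestPosterior:
    def test_matches_closed_form_on_grid(self):
        rng = np.random.default_rng(0)
        space = space_nd([(0, 1), (0, 2)], [False, True])
        X = rng.random((25, 2)) * np.array([1.0, 2.0])
        y = np.sin(3 * X[:, 0]) + np.cos(np.pi * X[:, 1])
        sv, ls, nv = 1.7, np.array([0.4, 0.6]), 1e-6
        model = GPModel(space, X, y, sv, ls, nv, float(y.mean()))
        g1, g2 = np.meshgrid(np.linspace(0, 1, 9), np.linspace(0, 2, 9))
        xq = np.column_stack([g1.ravel(), g2.ravel()])
        mean, sd = model.posterior(xq)
        m2, s2 = closed_form_posterior(space, X, y, xq, sv, ls, nv)
        # the implementation adds a tiny jitter; tolerance reflects that
        np.testing.assert_allclose(mean, m2, atol=1e-7)
        np.testing.assert_allclose(sd, s2, atol=1e-6)

    def test_interpolates_at_low_noise(self):
        rng = np.random.default_rng(1)
        space = space_1d()
        X = rng.random((12, 1))
        y = np.sin(6 * X[:, 0])
        model = fit_hyperparameters(space, X, y, seed=0, fixed_noise=1e-10)
        mean, sd = model.posterior(X)
        np.testing.assert_allclose(mean, y, atol=1e-5)
        assert sd.max() < 1e-3

    def test_reverts_to_prior_far_from_data(self):
        space = space_1d(hi=100.0)
        X = np.array([[1.0], [2.0]])
        y = np.array([5.0, 7.0])
        model = GPModel(space, X, y, 4.0, np.array([0.5]), 1e-8,
                        float(y.mean()))
        mean, sd = model.posterior(np.array([[90.0]]))
        assert mean[0] == pytest.approx(6.0, abs=1e-6)
        assert sd[0] == pytest.approx(2.0, abs=1e-6)

    def test_invariant_under_data_reordering(self):
        rng = np.random.default_rng(3)
        space = space_1d()
        X = rng.random((15, 1))
        y = np.cos(5 * X[:, 0])
        model = fit_hyperparameters(space, X, y, seed=0)
        perm = rng.permutation(15)
        model_p = GPModel(space, X[perm], y[perm], model.signal_var,
                          model.lengthscales, model.noise_var,
                          model.prior_mean)
        xq = rng.random((6, 1))
        np.testing.assert_allclose(model.posterior(xq)[0],
                                   model_p.posterior(xq)[0], atol=1e-8)


class TestKernel:
    def test_periodic_property(self):
        space = space_nd([(0, 2.5)], [True])
        x = np.array([[0.3]])
        k_self = kernel_matrix(space, x, x, 1.0, np.array([0.7]))[0, 0]
        k_shift = kernel_matrix(space, x, x + 2.5, 1.0, np.array([0.7]))[0, 0]
        assert k_shift == pytest.approx(k_self, abs=1e-14)

    def test_se_decays(self):
        space = space_nd([(0, 10)], [False])
        k = kernel_matrix(space, np.array([[0.0]]), np.array([[5.0]]),
                          1.0, np.array([0.5]))[0, 0]
        assert k < 1e-20


class TestFitting:
    def test_lengthscale_recovery_within_factor_two(self):
        rng = np.random.default_rng(7)
        space = space_1d(hi=5.0)
        true_ls = 0.8
        X = rng.random((200, 1)) * 5.0
        K = kernel_matrix(space, X, X, 2.0, np.array([true_ls]))
        y = rng.multivariate_normal(np.zeros(200), K + 1e-8 * np.eye(200))
        model = fit_hyperparameters(space, X, y, seed=0, fixed_noise=1e-6)
        assert true_ls / 2 <= model.lengthscales[0] <= true_ls * 2

    def test_duplicate_points_fit_via_jitter(self):
        space = space_1d()
        X = np.array([[0.5], [0.5], [0.2]])
        y = np.array([1.0, 1.0, 0.0])
        model = fit_hyperparameters(space, X, y, seed=0)
        assert np.isfinite(model.posterior(np.array([[0.4]]))[0][0])

    def test_constant_target_gives_constant_mean(self):
        rng = np.random.default_rng(9)
        space = space_1d()
        X = rng.random((10, 1))
        y = np.full(10, 3.3)
        model = fit_hyperparameters(space, X, y, seed=0)
        mean, _ = model.posterior(rng.random((5, 1)))
        np.testing.assert_allclose(mean, 3.3, atol=1e-3)

    def test_fitted_likelihood_beats_random_draws(self):
        rng = np.random.default_rng(5)
        space = space_1d()
        X = rng.random((30, 1))
        y = np.sin(8 * X[:, 0]) + 0.01 * rng.normal(size=30)
        model = fit_hyperparameters(space, X, y, seed=0, n_restarts=3)
        best = log_marginal_likelihood(model)
        for _ in range(10):
            trial = GPModel(space, X, y,
                            float(np.exp(rng.uniform(-4, 2))),
                            np.exp(rng.uniform(-3, 1, 1)),
                            float(np.exp(rng.uniform(-9, -2))),
                            model.prior_mean)
            assert log_marginal_likelihood(trial) <= best + 1e-6

    def test_needs_two_observations(self):
        with pytest.raises(ValueError):
            fit_hyperparameters(space_1d(), np.array([[0.1]]),
                                np.array([1.0]))


class TestAcquisition:
    def _model(self):
        rng = np.random.default_rng(2)
        space = space_1d()
        X = rng.random((20, 1))
        y = (X[:, 0] - 0.3) ** 2
        return space, fit_hyperparameters(space, X, y, seed=0,
                                          fixed_noise=1e-8)

    def test_kappa_zero_is_posterior_mean(self):
        space, model = self._model()
        xq = np.linspace(0, 1, 11)[:, None]
        np.testing.assert_allclose(model.acquisition(xq, 0.0),
                                   model.posterior(xq)[0], atol=1e-12)

    def test_monotone_in_kappa(self):
        space, model = self._model()
        xq = np.linspace(0, 1, 11)[:, None]
        assert np.all(model.acquisition(xq, 3.0) <= model.acquisition(xq, 1.0) + 1e-12)

    def test_argmin_matches_grid_scan(self):
        space, model = self._model()
        x = propose_next(model, space, kappa=1.0, seed=0)
        grid = np.linspace(0, 1, 2001)[:, None]
        vals = model.acquisition(grid, 1.0)
        best = vals.min()
        got = model.acquisition(np.atleast_2d(x), 1.0)[0]
        assert got <= best + 1e-6

    def test_proposal_within_bounds(self):
        space, model = self._model()
        for seed in range(3):
            x = propose_next(model, space, seed=seed)
            assert space.lower[0] - 1e-12 <= x[0] <= space.upper[0] + 1e-12

    def test_convex_posterior_minimum_located(self):
        space, model = self._model()
        x, _ = minimize_surface(lambda Q: model.posterior(Q)[0], space,
                                seed=0, n_starts=40)
        grid = np.linspace(0, 1, 4001)[:, None]
        xg = grid[np.argmin(model.posterior(grid)[0])]
        assert abs(x[0] - xg[0]) < 1e-2
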