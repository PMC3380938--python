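"""Joint and Laplace likelihood: closed forms, oracles, gradients."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from numpy.polynomial.hermite_e import hermegauss

from lgcpindex import (LGCPModel, LGCPConfig, LatentState, ModelParams,
                       assign_cells)
from lgcpindex._reference import laplace_nll_dense


def _model(samples, grid, years, **cfg_kw):
    return LGCPModel(samples, grid, years, LGCPConfig(**cfg_kw))


@pytest.fixture
def rich_point():
    """A parameter point exercising every component."""
    return ModelParams(sigma0_sq=1.3, sigma_sq=0.8, sigma_y_sq=0.4,
                       log_alpha=-5.2, log_beta=-0.8, intercept=-23.3,
                       a_spawn1=0.2, a_spawn2=5e-4, a_thc1=0.05, a_thc2=2e-3)


class TestJointNll:
    def test_zero_counts_poisson_part_is_sum_of_intensities(
            self, small_grid, sample_factory, rich_point):
        rng = np.random.default_rng(0)
        df = assign_cells(sample_factory(15, small_grid, (2000, 2001), rng,
                                         counts=np.zeros(15, dtype=int)),
                          small_grid)
        model = _model(df, small_grid, (2000, 2001))
        latent = LatentState(field=rng.normal(size=(small_grid.n_cells, 2)),
                             year_effect=rng.normal(size=2),
                             nugget=rng.normal(size=15))
        parts = model.joint_nll(rich_point, latent, parts=True)
        assert parts["obs"] == pytest.approx(np.exp(parts["eta"]).sum(), rel=1e-12)

    def test_single_sample_matches_scipy_densities(self, small_grid):
        df = pd.DataFrame({"sample_id": ["a"], "lat": [53.1], "lon": [0.1],
                           "year": [2000], "day_of_year": [180], "hour": [12],
                           "count": [3], "thermocline_depth_m": [15.0]})
        df = assign_cells(df, small_grid)
        model = _model(df, small_grid, (2000, 2000), include_field=False,
                       include_year_effect=False)
        p = ModelParams(sigma0_sq=1.7, sigma_sq=0, sigma_y_sq=0, intercept=0.4,
                        a_spawn1=0, a_spawn2=0, a_thc1=0, a_thc2=0)
        eps = 0.6
        latent = LatentState(field=np.zeros((small_grid.n_cells, 1)),
                             year_effect=np.zeros(1), nugget=np.array([eps]))
        expected = -(st.poisson.logpmf(3, np.exp(0.4 + eps))
                     + st.norm.logpdf(eps, 0, np.sqrt(1.7)))
        assert model.joint_nll(p, latent) == pytest.approx(expected, rel=1e-12)

    def test_permutation_invariance(self, small_grid, sample_factory, rich_point):
        rng = np.random.default_rng(1)
        df = assign_cells(sample_factory(40, small_grid, (2000, 2002), rng), small_grid)
        perm = rng.permutation(40)
        m1 = _model(df, small_grid, (2000, 2002))
        m2 = _model(df.iloc[perm].reset_index(drop=True), small_grid, (2000, 2002))
        assert m1.laplace_nll(rich_point) == pytest.approx(
            m2.laplace_nll(rich_point), rel=1e-9)


class TestLaplaceOracles:
    def test_gaussian_observations_laplace_is_exact(self, tiny_grid, sample_factory):
        """With Gaussian observations the Laplace marginal equals the closed form."""
        rng = np.random.default_rng(2)
        df = assign_cells(sample_factory(18, tiny_grid, (2000, 2001), rng), tiny_grid)
        df["count"] = rng.normal(0.0, 1.0, len(df))       # real-valued observations
        tau = 0.7
        model = _model(df, tiny_grid, (2000, 2001), family="gaussian", obs_sigma=tau)
        p = ModelParams(sigma0_sq=0.9, sigma_sq=1.1, sigma_y_sq=0.5,
                        log_alpha=-4.5, log_beta=-0.9, intercept=0.3,
                        a_spawn1=0.01, a_spawn2=1e-5, a_thc1=0.01, a_thc2=1e-4)
        nll = model.laplace_nll(p)

        # closed form: y ~ N(X gamma, A Sigma A' + tau^2 I)
        theta = model.pack(p)
        ctx = model._context(theta)
        Sigma_z = np.linalg.inv(ctx["Qz"])
        B = model.B.toarray()
        cov = B @ Sigma_z @ B.T + p.sigma0_sq * np.eye(model.n) \
            + tau ** 2 * np.eye(model.n)
        expected = -st.multivariate_normal.logpdf(df["count"], ctx["eta_fixed"], cov)
        assert nll == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("sigma0_sq", [0.5, 1.5, 2.5])
    @pytest.mark.parametrize("count, intercept", [(0, 0.2), (3, 0.5)])
    def test_poisson_single_latent_vs_gauss_hermite(self, small_grid, sigma0_sq,
                                                    count, intercept):
        """1-d Laplace within 1% of 61-node Gauss-Hermite quadrature."""
        df = pd.DataFrame({"sample_id": ["a"], "lat": [53.1], "lon": [0.1],
                           "year": [2000], "day_of_year": [180], "hour": [0],
                           "count": [count], "thermocline_depth_m": [15.0]})
        df = assign_cells(df, small_grid)
        model = _model(df, small_grid, (2000, 2000), include_field=False,
                       include_year_effect=False, thermocline_effect=False)
        p = ModelParams(sigma0_sq=sigma0_sq, sigma_sq=0, sigma_y_sq=0,
                        intercept=intercept, a_spawn1=0, a_spawn2=0,
                        a_thc1=0, a_thc2=0)
        nll = model.laplace_nll(p)

        nodes, weights = hermegauss(61)      # weight exp(-x^2/2), probabilists'
        eps = np.sqrt(sigma0_sq) * nodes
        lik = st.poisson.pmf(count, np.exp(intercept + eps))
        marginal = (weights * lik).sum() / np.sqrt(2 * np.pi)
        assert nll == pytest.approx(-np.log(marginal), rel=0.01)

    def test_no_latent_limit_is_poisson_regression(self, small_grid, sample_factory):
        rng = np.random.default_rng(3)
        df = assign_cells(sample_factory(30, small_grid, (2000, 2000), rng), small_grid)
        model = _model(df, small_grid, (2000, 2000), include_field=False,
                       include_year_effect=False, include_nugget=False)
        p = ModelParams(sigma0_sq=0, sigma_sq=0, sigma_y_sq=0, intercept=0.1,
                        a_spawn1=1e-3, a_spawn2=1e-6, a_thc1=0.01, a_thc2=1e-4)
        theta = model.pack(p)
        eta = model.X @ theta[model.n_var:]
        from scipy.special import gammaln
        expected = np.sum(np.exp(eta) - df["count"].to_numpy() * eta
                          + gammaln(df["count"].to_numpy() + 1.0))
        assert model.laplace_nll(p) == pytest.approx(expected, rel=1e-12)


class TestStructuredVsDense:
    def test_kronecker_path_agrees_with_dense_reference(self, small_grid,
                                                        sample_factory, rich_point):
        rng = np.random.default_rng(4)
        df = assign_cells(sample_factory(60, small_grid, (2000, 2002), rng),
                          small_grid)
        model = _model(df, small_grid, (2000, 2002))
        assert model.laplace_nll(rich_point) == pytest.approx(
            laplace_nll_dense(model, rich_point), abs=1e-8)


class TestAnalyticGradient:
    def _fd_check(self, model, params, rtol):
        theta = model.pack(params)
        _, grad, _ = model._laplace_grad(theta)
        for j in range(len(theta)):
            h = 1e-5 * max(1.0, abs(theta[j]))
            tp = theta.copy(); tp[j] += h
            tm = theta.copy(); tm[j] -= h
            fd = (model.laplace_nll(tp) - model.laplace_nll(tm)) / (2 * h)
            assert grad[j] == pytest.approx(fd, rel=rtol, abs=1e-6), \
                model.theta_names[j]

    def test_gradient_all_components(self, small_grid, sample_factory, rich_point):
        rng = np.random.default_rng(5)
        df = assign_cells(sample_factory(50, small_grid, (2000, 2002), rng),
                          small_grid)
        model = _model(df, small_grid, (2000, 2002))
        self._fd_check(model, rich_point, rtol=1e-4)

    def test_gradient_with_hour_and_shift(self, small_grid, sample_factory):
        rng = np.random.default_rng(6)
        df = assign_cells(sample_factory(60, small_grid, (2000, 2005), rng),
                          small_grid)
        model = _model(df, small_grid, (2000, 2005), hour_effect=True,
                       period_cut=(2002, 2003))
        mu = np.linspace(-0.5, 0.5, 24)
        p = ModelParams(sigma0_sq=0.8, sigma_sq=0.6, sigma_y_sq=0.3,
                        log_alpha=-5.0, log_beta=-1.0, intercept=-23.5,
                        a_spawn1=0.2, a_spawn2=5e-4, a_thc1=0.05, a_thc2=2e-3,
                        mu_hour=mu - mu.mean(), period_shift=-0.7)
        self._fd_check(model, p, rtol=1e-4)

    def test_gradient_tied_year_variance(self, tiny_grid, sample_factory):
        rng = np.random.default_rng(7)
        df = assign_cells(sample_factory(30, tiny_grid, (2000, 2002), rng), tiny_grid)
        model = _model(df, tiny_grid, (2000, 2002), tie_sigma_y=True)
        p = ModelParams(sigma0_sq=0.8, sigma_sq=0.6, sigma_y_sq=0.6,
                        log_alpha=-5.0, log_beta=-1.0, intercept=-23.4,
                        a_spawn1=0.2, a_spawn2=5e-4, a_thc1=0.05, a_thc2=2e-3)
        self._fd_check(model, p, rtol=1e-4)


class TestHourIdentifiability:
    def test_equal_hour_offsets_equal_intercept_shift(self, small_grid,
                                                      sample_factory):
        """Sum-to-zero hour offsets: a flat hour profile is the same model as
        no hour effect with a shifted intercept."""
        rng = np.random.default_rng(8)
        df = assign_cells(sample_factory(40, small_grid, (2000, 2001), rng),
                          small_grid)
        base = ModelParams(sigma0_sq=0.9, sigma_sq=0.7, sigma_y_sq=0.3,
                           log_alpha=-5.0, log_beta=-1.0, intercept=-23.2,
                           a_spawn1=0.2, a_spawn2=5e-4, a_thc1=0.05, a_thc2=2e-3)
        m_hour = _model(df, small_grid, (2000, 2001), hour_effect=True)
        m_flat = _model(df, small_grid, (2000, 2001), hour_effect=False)
        with_zero_offsets = base.replace(mu_hour=np.zeros(24))
        nll_hour = m_hour.laplace_nll(with_zero_offsets)
        nll_flat = m_flat.laplace_nll(base)
        assert nll_hour == pytest.approx(nll_flat, rel=1e-10)
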