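"""Ricciardi transfer function, self-consistency, and alpha-mixed dynamics."""

import numpy as np
import pytest

from diffhomeo import meanfield as mf


class TestTransferRate:
    def test_gauss_legendre_matches_adaptive_quadrature(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            mu = rng.uniform(3.0, 9.0)
            sigma = rng.uniform(1.0, 3.5)
            theta = rng.uniform(6.0, 12.0)
            a = mf.transfer_rate(mu, sigma, theta)
            b = mf.transfer_rate_quad(mu, sigma, theta)
            assert a == pytest.approx(b, rel=1e-8)

    def test_monotone_increasing_in_mu(self):
        mus = np.linspace(3, 9, 30)
        rates = mf.transfer_rate(mus, 2.0, 10.0)
        assert np.all(np.diff(rates) > 0)

    def test_monotone_decreasing_in_theta(self):
        thetas = np.linspace(7, 13, 30)
        rates = mf.transfer_rate(5.7, 2.4, thetas)
        assert np.all(np.diff(rates) < 0)

    def test_rate_diverges_as_threshold_approaches_mean(self):
        near = mf.transfer_rate(5.7, 0.5, 5.8)
        far = mf.transfer_rate(5.7, 0.5, 10.0)
        assert near > 100 * max(far, 1e-12)

    def test_distant_threshold_underflows_to_zero(self):
        assert mf.transfer_rate(1.0, 0.5, 30.0) == 0.0

    def test_threshold_below_reset_rejected(self):
        with pytest.raises(ValueError):
            mf.transfer_rate(5.0, 1.0, -1.0, v_r=0.0)


class TestSelfConsistency:
    def test_uncoupled_population_solves_in_closed_form(self):
        rng = np.random.default_rng(1)
        mu_ext = rng.normal(5.7, 0.4, size=200)
        theta = np.full(200, 10.0)
        nu, phi = mf.solve_self_consistent(mu_ext, theta, J=0.0)
        direct = mf.transfer_rate(mu_ext, np.sqrt(mu_ext), theta)
        assert nu == pytest.approx(direct.mean(), rel=1e-12)

    def test_solution_invariant_to_damping(self):
        rng = np.random.default_rng(2)
        mu_ext = rng.normal(5.0, 0.4, size=100)
        theta = np.full(100, 10.0)
        nu1, _ = mf.solve_self_consistent(mu_ext, theta, J=0.05, C=100, damping=0.1)
        nu2, _ = mf.solve_self_consistent(mu_ext, theta, J=0.05, C=100, damping=0.5)
        assert nu1 == pytest.approx(nu2, abs=2e-4)

    def test_residual_below_tolerance(self):
        rng = np.random.default_rng(3)
        mu_ext = rng.normal(5.0, 0.4, size=100)
        theta = np.full(100, 10.0)
        nu, phi = mf.solve_self_consistent(mu_ext, theta, J=0.05, C=100, tol_hz=1e-4)
        assert abs(phi.mean() - nu) < 1e-4


class TestAlphaDynamics:
    def test_alpha_zero_drives_every_rate_to_target(self):
        pop = mf.draw_alpha_population(300, delta=0.4, alpha=0.0, phi0=2.0, seed=4)
        phi = pop.run_to_steady(tol=5e-4)
        assert np.max(np.abs(phi - 2.0)) < 1e-3 * 2.0 * 2  # |phi - phi0| ~ tol*phi0

    def test_alpha_one_regulates_only_population_mean(self):
        pop = mf.draw_alpha_population(300, delta=0.4, alpha=1.0, phi0=2.0, seed=5)
        phi0_spread = pop.rates().std()
        phi = pop.run_to_steady(tol=5e-4)
        assert phi.mean() == pytest.approx(2.0, rel=0.01)
        # individual differences survive: spread comparable to initial
        assert phi.std() > 0.3 * phi0_spread

    def test_rate_variance_increases_with_alpha(self):
        # after a fixed run (population mean converged), a more global
        # read-out leaves more individual-rate heterogeneity
        variances = []
        for alpha in (0.0, 0.5, 0.9):
            pop = mf.draw_alpha_population(300, delta=0.4, alpha=alpha, phi0=2.0, seed=6)
            phi = pop.evolve(25.0)
            variances.append(phi.var())
        assert variances[0] < variances[1] < variances[2]
        assert pop.rates().mean() == pytest.approx(2.0, abs=0.05)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            mf.AlphaPopulation(mu=np.array([5.7]), alpha=1.5)


class TestCovariancePopulation:
    def test_requested_correlation_realized(self):
        cp = mf.build_covariance_population(0.6, 10000, seed=7)
        assert abs(cp.empirical_correlation() - 0.6) < 0.02

    def test_high_covariance_narrows_rates(self):
        v = {}
        for rho in (0.6, 0.99):
            cp = mf.build_covariance_population(rho, 10000, seed=8)
            v[rho] = cp.rates().var()
        assert v[0.99] < v[0.6]

    def test_zero_covariance_maximal_variance(self):
        v = []
        for rho in (0.0, 0.5, 0.9):
            cp = mf.build_covariance_population(rho, 10000, seed=9)
            v.append(cp.rates().var())
        assert v[0] == max(v)

    def test_infeasible_correlation_rejected(self):
        with pytest.raises(ValueError):
            mf.build_covariance_population(1.5, 100)


class TestResponseLinearitySweep:
    def test_narrow_inputs_high_r2_everywhere(self):
        rows = mf.response_linearity_sweep(
            [0.0, 0.9], [0.1], n=200, n_trials=3, seed=10)
        assert all(r["r2"] > 0.9 for r in rows)

    def test_wide_inputs_lower_r2_at_high_alpha(self):
        rows = mf.response_linearity_sweep(
            [0.0, 0.95], [1.0], n=300, n_trials=4, seed=11)
        lo = np.mean([r["r2"] for r in rows if r["alpha"] == 0.0])
        hi = np.mean([r["r2"] for r in rows if r["alpha"] == 0.95])
        narrow = mf.response_linearity_sweep([0.95], [0.1], n=300, n_trials=4, seed=12)
        assert hi < np.mean([r["r2"] for r in narrow])
        assert hi < 0.9
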