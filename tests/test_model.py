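"""WLS and mixed-effects estimation, and the marginal likelihood itself."""

import numpy as np
import pytest
from scipy.stats import norm

import pkmodsel as pk
from pkmodsel.model import FitSettings, SumOfExponentials


@pytest.fixture(scope="module")
def grid3():
    """Tiny symmetric grid t = (1/2, 1, 2) for closed-form oracles."""
    return pk.make_time_grid(3, 2.0)


class TestDesignMatrix:
    def test_reciprocal_pairing_gives_exp_minus_one(self, grid11, lambdas11):
        X = pk.design_matrix(grid11, lambdas11, pk.evenly_spaced_model(11, 11))
        np.testing.assert_allclose(np.diag(X), np.exp(-1.0), rtol=1e-12)

    def test_full_design_is_invertible(self, grid11, lambdas11):
        X = pk.design_matrix(grid11, lambdas11, pk.evenly_spaced_model(11, 11))
        assert X.shape == (11, 11)
        assert np.linalg.matrix_rank(X) == 11
        assert np.isfinite(np.linalg.cond(X))

    def test_dimension_mismatch_rejected(self, grid11, lambdas11):
        with pytest.raises(ValueError, match="dimensions"):
            pk.design_matrix(grid11, lambdas11, pk.evenly_spaced_model(5, 3))


class TestWLS:
    def test_full_model_interpolates_single_individual(self, grid11):
        # noise-free data: K = M exponentials give a perfect fit
        pop = pk.simulate_population(grid11, 1, 0.0, 0.0, seed=1)
        fit = pk.wls_fit(pop, pk.evenly_spaced_model(11, 11))
        np.testing.assert_allclose(fit.predict(), pop.values[0],
                                   rtol=0, atol=1e-9)
        assert fit.converged
        assert fit.D == 12

    def test_gaussian_loglik_constant(self, grid3):
        # zero-residual observations contribute only log(2 pi sigma2 w^2);
        # at t = 1 (w = 1) with sigma2 = 1 that is log(2 pi) per point
        pop = pk.PopulationData(
            grid=grid3, values=np.ones((1, 3)) / grid3.times[None, :],
            eta_true=np.zeros(1), sigma2_true=1.0, omega2_true=0.0,
            weights=1.0 / grid3.times, seed=0)
        alpha = np.linalg.solve(
            np.exp(-np.outer(grid3.times, 1.0 / grid3.times)),
            1.0 / grid3.times)
        ofv = pk.marginal_ofv(pop, alpha, 1.0, 0.0)
        expected = 3 * np.log(2 * np.pi) + 2 * np.sum(np.log(1 / grid3.times))
        assert ofv == pytest.approx(expected, abs=1e-8)
        assert expected == pytest.approx(3 * np.log(2 * np.pi), abs=1e-12)

    def test_ofv_decreases_along_nested_masks(self, grid11):
        pop = pk.simulate_population(grid11, 2, 0.5, 0.0, seed=9)
        chain = [(6,), (6, 1), (6, 1, 11), (6, 1, 11, 3), (6, 1, 11, 3, 9)]
        ofvs = [pk.wls_fit(pop, pk.ModelSpec.from_indices(11, idx)).ofv
                for idx in chain]
        assert all(b <= a + 1e-8 for a, b in zip(ofvs, ofvs[1:]))

    def test_parameter_count_and_sparsity(self, grid11):
        pop = pk.simulate_population(grid11, 5, 0.5, 0.0, seed=2)
        spec = pk.evenly_spaced_model(11, 4)
        fit = pk.wls_fit(pop, spec)
        assert fit.D == 5  # four alphas plus sigma2
        inactive = [m for m in range(11) if m not in spec.active]
        assert np.all(fit.alpha[inactive] == 0.0)
        assert fit.sigma2 > 0
        assert fit.bse_alpha() is not None and fit.bse_alpha().shape == (4,)

    def test_summary_smoke(self, grid11):
        pop = pk.simulate_population(grid11, 5, 0.5, 0.0, seed=2)
        text = pk.wls_fit(pop, pk.evenly_spaced_model(11, 6)).summary()
        assert "10101010101" in text
        assert "sigma2" in text

    def test_from_dataframe_roundtrip(self, grid11):
        pop = pk.simulate_population(grid11, 5, 0.5, 0.0, seed=4)
        spec = pk.evenly_spaced_model(11, 6)
        direct = pk.wls_fit(pop, spec)
        via_frame = SumOfExponentials.from_dataframe(pop.to_frame(), spec).fit("wls")
        assert via_frame.ofv == pytest.approx(direct.ofv, rel=1e-12)
        np.testing.assert_allclose(via_frame.alpha, direct.alpha, rtol=1e-10)


class TestMarginalLikelihood:
    def test_zero_omega2_reduces_to_wls_ofv(self, grid11):
        pop = pk.simulate_population(grid11, 5, 0.5, 0.0, seed=2)
        fit = pk.wls_fit(pop, pk.evenly_spaced_model(11, 6))
        mo = pk.marginal_ofv(pop, fit.alpha, fit.sigma2, 0.0)
        assert mo == pytest.approx(fit.ofv, abs=1e-8)

    def test_quadrature_matches_dense_integration(self):
        # brute-force trapezoid oracle on a tiny instance
        grid = pk.make_time_grid(2, 10.0)
        pop = pk.simulate_population(grid, 2, 0.5, 0.3, seed=3)
        alpha = np.array([0.4, 0.7])
        sigma2, omega2 = 0.6, 0.3
        quad = pk.marginal_ofv(pop, alpha, sigma2, omega2, n_quad=31)
        t = grid.times
        f = np.exp(-np.outer(t, 1.0 / t)) @ alpha
        eta = np.linspace(-8 * np.sqrt(omega2), 8 * np.sqrt(omega2), 200_001)
        loglik = 0.0
        for i in range(pop.N):
            dens = norm.pdf(eta, 0.0, np.sqrt(omega2))
            for j in range(grid.M):
                dens = dens * norm.pdf(pop.values[i, j], np.exp(eta) * f[j],
                                       np.sqrt(sigma2) / t[j])
            loglik += np.log(np.trapezoid(dens, eta))
        assert quad == pytest.approx(-2.0 * loglik, rel=1e-6)

    def test_quadrature_stable_under_node_doubling(self, grid11):
        pop = pk.simulate_population(grid11, 5, 0.5, 0.1, seed=5)
        alpha = np.zeros(11)
        alpha[pk.evenly_spaced_model(11, 6).active] = [0.9, 0.8, 1.1, 0.7, 1.0, 0.9]
        a = pk.marginal_ofv(pop, alpha, 0.5, 0.1, n_quad=21)
        b = pk.marginal_ofv(pop, alpha, 0.5, 0.1, n_quad=42)
        assert abs(a - b) < 1e-6

    def test_single_node_is_laplace_approximation(self, grid11):
        pop = pk.simulate_population(grid11, 5, 0.5, 0.1, seed=5)
        fit = pk.nlme_fit(pop, pk.evenly_spaced_model(11, 6))
        laplace = pk.marginal_ofv(pop, fit.alpha, fit.sigma2, fit.omega2, n_quad=1)
        full = pk.marginal_ofv(pop, fit.alpha, fit.sigma2, fit.omega2, n_quad=21)
        assert laplace == pytest.approx(full, abs=1.0)  # close but not exact

    @pytest.mark.parametrize(
        "kwargs, message",
        [({"sigma2": 0.0}, "sigma2"), ({"sigma2": -1.0}, "sigma2"),
         ({"omega2": -0.1}, "omega2"), ({"n_quad": 0}, "n_quad")],
    )
    def test_invalid_parameters_rejected(self, grid11, kwargs, message):
        pop = pk.simulate_population(grid11, 2, 0.5, 0.0, seed=1)
        args = {"alpha": np.ones(11), "sigma2": 0.5, "omega2": 0.1, "n_quad": 5}
        args.update(kwargs)
        with pytest.raises(ValueError, match=message):
            pk.marginal_ofv(pop, **args)


class TestMixedFit:
    def test_omega2_zero_data_recovers_wls_limit(self, grid11):
        # the mixed model nests WLS at omega2 = 0: its OFV is never above
        # the WLS one, the boundary gain is a chi2(1)-scale fluctuation at
        # most, and omega2_hat is small once N is moderately large
        pop = pk.simulate_population(grid11, 100, 0.5, 0.0, seed=4)
        spec = pk.evenly_spaced_model(11, 6)
        mixed = pk.nlme_fit(pop, spec)
        wls = pk.wls_fit(pop, spec)
        assert mixed.converged
        assert mixed.omega2 == pytest.approx(0.0, abs=0.03)
        assert mixed.ofv <= wls.ofv + 1e-2
        assert wls.ofv - mixed.ofv <= 4.0
        assert mixed.D == wls.D + 1

    def test_refit_is_deterministic(self, grid11):
        pop = pk.simulate_population(grid11, 5, 0.5, 0.1, seed=7)
        spec = pk.evenly_spaced_model(11, 6)
        a = pk.nlme_fit(pop, spec)
        b = pk.nlme_fit(pop, spec)
        assert a.ofv == b.ofv
        np.testing.assert_array_equal(a.alpha, b.alpha)
        assert (a.sigma2, a.omega2) == (b.sigma2, b.omega2)

    def test_requires_two_individuals(self, grid11):
        pop = pk.simulate_population(grid11, 1, 0.5, 0.1, seed=1)
        with pytest.raises(ValueError, match="N"):
            pk.nlme_fit(pop, pk.evenly_spaced_model(11, 4))

    def test_settings_control_quadrature(self, grid11):
        pop = pk.simulate_population(grid11, 5, 0.5, 0.1, seed=8)
        fit = pk.nlme_fit(pop, pk.evenly_spaced_model(11, 4),
                          FitSettings(n_quad=9))
        assert fit.n_quad == 9
        assert fit.converged
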