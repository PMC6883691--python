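"""E-step conditional moments, M-step updates, likelihood, full EM fit."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from methdecon import (
    ModelParams,
    ValidationError,
    e_step,
    fit_model,
    m_step,
    observed_loglik,
    region_weights,
)
from methdecon.simulate import SimulationConfig, default_blood_z, simulate_mixtures

from conftest import dense_conditional_oracle, make_region_matrix, make_region_state

THETA = ModelParams(0.2, 0.8, 0.01, 0.02, 0.005)


def _random_instance(rng, R=4, N=3, K=2, missing=0):
    Zm = rng.integers(0, 2, size=(R, K))
    while np.linalg.matrix_rank(Zm) < K:
        Zm = rng.integers(0, 2, size=(R, K))
    P = rng.dirichlet(np.ones(K), N)
    Y = np.clip(rng.normal(0.5, 0.2, (R, N)), 0, 1)
    for _ in range(missing):
        Y[rng.integers(R), rng.integers(N)] = np.nan
    return make_region_state(Zm), make_region_matrix(Y), P


class TestRegionWeights:
    def test_pure_sample(self):
        Z = make_region_state([[1, 0], [0, 1], [1, 1]])
        W0, W1 = region_weights(np.array([[1.0, 0.0]]), Z)
        np.testing.assert_allclose(W0[:, 0], [0, 1, 0])
        np.testing.assert_allclose(W1[:, 0], [1, 0, 1])

    def test_even_mixture(self):
        Z = make_region_state([[1, 0], [0, 1], [1, 1]])
        W0, W1 = region_weights(np.array([[0.5, 0.5]]), Z)
        np.testing.assert_allclose(W0[0], 0.5)
        np.testing.assert_allclose(W1[0], 0.5)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_weights_sum_to_one_on_simplex(self, seed):
        rng = np.random.default_rng(seed)
        Z, _, P = _random_instance(rng, R=6, N=4, K=3)
        W0, W1 = region_weights(P, Z)
        np.testing.assert_allclose(W0 + W1, 1.0, atol=1e-12)


class TestEStep:
    def test_degenerate_prior_returns_constants(self):
        Z, Y, P = _random_instance(np.random.default_rng(1))
        theta = ModelParams(0.2, 0.8, 0.0, 0.0, 0.005)
        mom, stats = e_step(Y, Z, theta, P)
        R = Z.n_regions
        np.testing.assert_allclose(mom.mean_delta0, 0.2)
        np.testing.assert_allclose(mom.var_delta0, 0.0)
        assert stats.T1 == pytest.approx(R * 0.2)
        assert stats.T3 == pytest.approx(R * 0.2**2)

    def test_uninformative_likelihood_limit(self):
        # tau^2 -> infinity: posterior falls back to the prior
        Z, Y, P = _random_instance(np.random.default_rng(2))
        theta = ModelParams(0.2, 0.8, 0.01, 0.02, 1e8)
        mom, _ = e_step(Y, Z, theta, P)
        np.testing.assert_allclose(mom.mean_delta0, 0.2, atol=1e-4)
        np.testing.assert_allclose(mom.var_delta0, 0.01, atol=1e-4)
        np.testing.assert_allclose(mom.mean_delta1, 0.8, atol=1e-4)

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(3)
        Z, Y, P = _random_instance(rng, R=4, N=3, K=2)
        mom, _ = e_step(Y, Z, THETA, P)
        (m0, v0), (m1, v1), _ = dense_conditional_oracle(Y.Y, Z.Z, THETA, P)
        np.testing.assert_allclose(mom.mean_delta0, m0, atol=1e-8)
        np.testing.assert_allclose(mom.var_delta0, v0, atol=1e-8)
        np.testing.assert_allclose(mom.mean_delta1, m1, atol=1e-8)
        np.testing.assert_allclose(mom.var_delta1, v1, atol=1e-8)

    def test_matches_dense_oracle_with_missing(self):
        rng = np.random.default_rng(4)
        Z, Y, P = _random_instance(rng, R=5, N=4, K=2, missing=4)
        mom, _ = e_step(Y, Z, THETA, P)
        (m0, v0), (m1, v1), _ = dense_conditional_oracle(Y.Y, Z.Z, THETA, P)
        np.testing.assert_allclose(mom.mean_delta0, m0, atol=1e-8)
        np.testing.assert_allclose(mom.var_delta1, v1, atol=1e-8)

    def test_posterior_variance_never_exceeds_prior(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            Z, Y, P = _random_instance(rng, R=6, N=4, K=3, missing=2)
            mom, _ = e_step(Y, Z, THETA, P)
            assert (mom.var_delta0 <= THETA.sigma0_sq + 1e-12).all()
            assert (mom.var_delta1 <= THETA.sigma1_sq + 1e-12).all()
            assert (mom.var_delta0 >= 0).all() and (mom.var_delta1 >= 0).all()


class TestMStep:
    def test_plug_in_updates(self):
        Z, Y, P = _random_instance(np.random.default_rng(6))
        mom, stats = e_step(Y, Z, THETA, P)
        R = Z.n_regions
        stats.T1, stats.T3 = 0.3 * R, 0.09 * R
        theta, _ = m_step(stats, mom, Y, Z)
        assert theta.alpha0 == pytest.approx(0.3)
        assert theta.sigma0_sq == pytest.approx(0.0, abs=1e-10)

    def test_one_iteration_matches_formula_oracle(self):
        rng = np.random.default_rng(7)
        Z, Y, P = _random_instance(rng, R=4, N=3, K=2)
        (m0, v0), (m1, v1), _ = dense_conditional_oracle(Y.Y, Z.Z, THETA, P)
        mom, stats = e_step(Y, Z, THETA, P)
        theta, pi = m_step(stats, mom, Y, Z)
        R = Z.n_regions
        T1, T2 = m0.sum(), m1.sum()
        T3, T4 = (m0**2 + v0).sum(), (m1**2 + v1).sum()
        assert theta.alpha0 == pytest.approx(T1 / R, abs=1e-10)
        assert theta.alpha1 == pytest.approx(T2 / R, abs=1e-10)
        assert theta.sigma0_sq == pytest.approx(T3 / R - (T1 / R) ** 2, abs=1e-10)
        assert theta.sigma1_sq == pytest.approx(T4 / R - (T2 / R) ** 2, abs=1e-10)
        Zm = Z.Z.astype(float)
        X_t = (1 - Zm) * m0[:, None] + Zm * m1[:, None]
        resid = Y.Y - X_t @ pi.pi.T
        assert theta.tau_sq == pytest.approx(np.mean(resid**2), abs=1e-10)


class TestObservedLoglik:
    def test_univariate_closed_form(self):
        Z = make_region_state([[1]])
        Y = make_region_matrix([[0.7]])
        theta = ModelParams(0.2, 0.8, 0.0, 0.0, 0.01)
        P = np.array([[1.0]])
        expected = -0.5 * (np.log(2 * np.pi * 0.01) + (0.7 - 0.8) ** 2 / 0.01)
        assert observed_loglik(Y, Z, theta, P) == pytest.approx(expected)

    def test_matches_dense_oracle(self):
        rng = np.random.default_rng(8)
        Z, Y, P = _random_instance(rng, R=4, N=3, K=2)
        _, _, ll = dense_conditional_oracle(Y.Y, Z.Z, THETA, P)
        assert observed_loglik(Y, Z, THETA, P) == pytest.approx(ll, abs=1e-8)

    def test_all_missing_region_contributes_nothing(self):
        rng = np.random.default_rng(9)
        Z, Y, P = _random_instance(rng, R=4, N=3, K=2)
        base = observed_loglik(Y, Z, THETA, P)
        Zbig = make_region_state(np.vstack([Z.Z, [[1, 0]]]))
        Ybig = make_region_matrix(np.vstack([Y.Y, np.full((1, 3), np.nan)]))
        assert observed_loglik(Ybig, Zbig, THETA, P) == pytest.approx(base)


class TestFitModel:
    def test_noiseless_recovery(self, rng):
        Z = default_blood_z(30, cell_types=["a", "b", "c"])
        Zm = Z.Z.astype(float)
        X = (1 - Zm) * 0.1 + Zm * 0.9
        pi_true = rng.dirichlet(np.ones(3), 5)
        Y = make_region_matrix(X @ pi_true.T, regions=Z.regions)
        with pytest.warns(UserWarning, match="floor"):
            fit = fit_model(Y, Z)
        np.testing.assert_allclose(fit.pi.pi, pi_true, atol=1e-6)

    def test_deterministic(self):
        cfg = SimulationConfig(n_samples=4, n_sims=1, seed=21)
        ds = simulate_mixtures(cfg)
        a = fit_model(ds.Y["array"], cfg.Z)
        b = fit_model(ds.Y["array"], cfg.Z)
        np.testing.assert_array_equal(a.pi.pi, b.pi.pi)
        assert a.theta.as_dict() == b.theta.as_dict()
        assert a.loglik_trace == b.loglik_trace

    def test_simplex_constraints_hold(self):
        cfg = SimulationConfig(n_samples=6, n_sims=1, seed=22)
        ds = simulate_mixtures(cfg)
        fit = fit_model(ds.Y["sequencing"], cfg.Z)
        np.testing.assert_allclose(fit.pi.pi.sum(axis=1), 1.0, atol=1e-8)
        assert fit.pi.pi.min() >= -1e-10

    def test_cell_type_relabeling_permutes_estimates(self):
        cfg = SimulationConfig(n_samples=4, n_sims=1, seed=23)
        ds = simulate_mixtures(cfg)
        Z = cfg.Z
        perm = [3, 0, 5, 1, 4, 2]
        Zp = make_region_state(
            Z.Z[:, perm], cell_types=[Z.cell_types[j] for j in perm]
        )
        a = fit_model(ds.Y["array"], Z)
        b = fit_model(ds.Y["array"], Zp)
        np.testing.assert_allclose(a.pi.pi[:, perm], b.pi.pi, atol=1e-10)

    def test_nonconvergence_reported_not_raised(self):
        cfg = SimulationConfig(n_samples=4, n_sims=1, seed=24)
        ds = simulate_mixtures(cfg)
        fit = fit_model(ds.Y["array"], cfg.Z, max_iter=1)
        assert not fit.converged and fit.n_iter == 1

    def test_too_few_regions_errors(self):
        Z = make_region_state([[1, 0], [0, 1]])
        Y = make_region_matrix(np.full((2, 3), 0.5))
        with pytest.raises(ValidationError, match="more regions"):
            fit_model(Y, Z)

    def test_loglik_trace_finite(self):
        cfg = SimulationConfig(n_samples=4, n_sims=1, seed=25)
        ds = simulate_mixtures(cfg)
        fit = fit_model(ds.Y["array"], cfg.Z)
        assert np.isfinite(fit.loglik_trace).all()
        assert len(fit.loglik_trace) == fit.n_iter
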