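import math

import numpy as np
import pytest
from scipy import stats

from semgwas.model import (DefinitenessError, ExogenousCov, ModelSpec,
                           StructuralSingularityError, fit_ml,
                           implied_covariance, is_acyclic, nearest_psd,
                           param_significance, wishart_loglik)
from semgwas.synthetic import make_true_model, simulate_dataset

from conftest import measurement_spec_from_truth


def one_factor_one_trait():
    m = ModelSpec(latent_names=["F1"], trait_names=["T1"])
    m.Lambda[0, 0] = 1.0
    m.theta_eps[:] = 1.0
    m.theta_delta[:] = 1.0
    return m


class TestIsAcyclic:
    def test_empty_mask(self):
        assert is_acyclic(np.zeros((3, 3), dtype=bool))

    def test_two_cycle(self):
        mask = np.zeros((2, 2), dtype=bool)
        mask[0, 1] = mask[1, 0] = True
        assert not is_acyclic(mask)

    def test_random_dag_from_topological_construction(self, rng):
        # edges only from lower to higher index: acyclic by construction
        for _ in range(20):
            n = int(rng.integers(3, 8))
            mask = np.triu(rng.random((n, n)) < 0.5, k=1)
            assert is_acyclic(mask.T)

    def test_self_loop(self):
        mask = np.eye(2, dtype=bool)
        assert not is_acyclic(mask)


class TestImpliedCovariance:
    def test_single_factor_single_trait_variance(self):
        # loading 1, theta_eps=1, theta_delta=1 -> Var(trait) = 2
        m = one_factor_one_trait()
        exo = ExogenousCov([], np.empty((0, 0)))
        cov = implied_covariance(m, exo)
        assert cov.shape == (1, 1)
        assert cov[0, 0] == pytest.approx(2.0)

    def test_no_snp_model_independent_of_exo(self):
        tm = make_true_model(2, [2, 2], [1, 1], 0, seed=0)
        m = tm.spec.copy()
        m.Pi[:] = 0.0
        exo1 = ExogenousCov(tm.snp_names, np.eye(2))
        exo2 = ExogenousCov(tm.snp_names, np.array([[1.0, 0.7], [0.7, 1.0]]))
        nt = m.n_traits
        c1 = implied_covariance(m, exo1)[:nt, :nt]
        c2 = implied_covariance(m, exo2)[:nt, :nt]
        np.testing.assert_allclose(c1, c2)

    def test_matches_monte_carlo(self):
        # brute-force oracle: sample the generative equations directly
        tm = make_true_model(2, [2, 2], [2, 1], [1, 0, 0, 0],
                             b_edges=[(0, 1, 0.4)], seed=3)
        _, lat = simulate_dataset(tm, 200_000, seed=4, return_latent=True)
        obs = np.hstack([lat["trait_latent"], lat["snp_latent"]])
        S_mc = np.cov(obs, rowvar=False)
        Sigma = implied_covariance(
            tm.spec, ExogenousCov(tm.snp_names, np.eye(len(tm.snp_names))))
        rel = np.linalg.norm(S_mc - Sigma) / np.linalg.norm(Sigma)
        assert rel < 0.02

    def test_symmetry_and_psd(self):
        tm = make_true_model(3, [2, 2, 2], [1, 1, 1], 0,
                             b_edges=[(0, 1, 0.5), (1, 2, 0.3)], seed=5)
        exo = ExogenousCov(tm.snp_names, np.eye(3))
        cov = implied_covariance(tm.spec, exo)
        np.testing.assert_allclose(cov, cov.T)
        assert np.linalg.eigvalsh(cov).min() > -1e-10

    def test_factor_analysis_reduction(self):
        # B=0, Pi=0, K=0: trait block = Lambda Cov(eta) Lambda' + Theta_delta
        tm = make_true_model(2, [3, 3], 0, 0, seed=6)
        m = tm.spec
        exo = ExogenousCov([], np.empty((0, 0)))
        cov = implied_covariance(m, exo)
        expect = m.Lambda @ np.diag(m.theta_eps) @ m.Lambda.T + np.diag(m.theta_delta)
        np.testing.assert_allclose(cov, expect)

    def test_singular_structure_raises(self):
        m = ModelSpec(latent_names=["A", "B"], trait_names=["T1", "T2"])
        m.B[0, 1] = m.B[1, 0] = 1.0   # (I - B) singular
        with pytest.raises(StructuralSingularityError):
            implied_covariance(m, ExogenousCov([], np.empty((0, 0))))

    def test_dimension_mismatch_raises(self):
        tm = make_true_model(2, [2, 2], [1, 1], 0, seed=0)
        with pytest.raises(ValueError):
            implied_covariance(tm.spec, ExogenousCov(["x"], np.eye(1)))


class TestWishartLoglik:
    def test_identity_matches_closed_form(self):
        # independently coded Wishart log-pdf for X = (n-1) S, df = n-1, V = Sigma
        d, n = 2, 100
        S = Sigma = np.eye(d)
        df = n - 1
        X = df * S
        logZ = (df * d / 2 * math.log(2) + d * (d - 1) / 4 * math.log(math.pi)
                + sum(math.lgamma((df - i) / 2) for i in range(d))
                + df / 2 * math.log(np.linalg.det(Sigma)))
        closed = ((df - d - 1) / 2 * math.log(np.linalg.det(X))
                  - np.trace(np.linalg.inv(Sigma) @ X) / 2 - logZ)
        assert wishart_loglik(S, Sigma, n) == pytest.approx(closed, rel=1e-10)

    def test_inflated_sigma_tends_to_minus_inf(self):
        S = np.eye(2)
        vals = [wishart_loglik(S, c * np.eye(2), 100) for c in (1, 10, 1e3, 1e6)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] < vals[0] - 1e3

    def test_univariate_reduces_to_gamma(self):
        # d=1: (n-1)s2/sigma2 ~ chi2(n-1); compare densities via change of var
        n, s2, sig2 = 50, 1.7, 1.3
        got = wishart_loglik(np.array([[s2]]), np.array([[sig2]]), n)
        x = (n - 1) * s2
        expect = stats.gamma.logpdf(x, a=(n - 1) / 2, scale=2 * sig2)
        assert got == pytest.approx(expect, rel=1e-10)

    def test_non_pd_sigma_raises(self):
        with pytest.raises(DefinitenessError):
            wishart_loglik(np.eye(2), np.array([[1.0, 2.0], [2.0, 1.0]]), 50)

    def test_requires_n_greater_than_d(self):
        with pytest.raises(ValueError):
            wishart_loglik(np.eye(3), np.eye(3), 3)


class TestFitML:
    def test_zero_noise_recovery_single_loading(self):
        m = ModelSpec(latent_names=["F1"], trait_names=["T1", "T2"])
        m.Lambda[0, 0] = 1.0
        m.Lambda[1, 0] = 0.7
        m.theta_eps[:] = 1.0
        m.theta_delta[:] = 0.5
        exo = ExogenousCov([], np.empty((0, 0)))
        S = implied_covariance(m, exo)
        free = m.copy()
        free.Lambda_free[1, 0] = True
        free.Lambda[1, 0] = 1.0
        fit = fit_ml(free, S, 10_000)
        # zero-noise recovery up to the optimizer's gradient tolerance
        assert fit.model.Lambda[1, 0] == pytest.approx(0.7, abs=1e-3)

    def test_saturated_two_variable_model(self):
        # single factor, 2 traits, loading + both error variances free:
        # enough freedom to reproduce S exactly at the optimum
        m = ModelSpec(latent_names=["F1"], trait_names=["T1", "T2"])
        m.Lambda[0, 0] = 1.0
        m.Lambda_free[1, 0] = True
        m.Lambda[1, 0] = 1.0
        m.theta_eps[:] = 1.0
        m.theta_delta_free[:] = True
        S = np.array([[1.5, 0.6], [0.6, 1.2]])
        fit = fit_ml(m, S, 500)
        Sigma = implied_covariance(fit.model, ExogenousCov([], np.empty((0, 0))))
        # 3 free parameters, 3 distinct moments: saturated fit reproduces S
        np.testing.assert_allclose(Sigma, S, atol=5e-3)

    def test_loglik_improves_from_start(self, small_true_model, small_dataset):
        from semgwas.model import default_start, _objective

        spec = measurement_spec_from_truth(small_true_model)
        X = small_dataset.phenotypes.to_numpy()
        S = np.corrcoef(X, rowvar=False)
        fit = fit_ml(spec, S, 400)
        start_model = spec.copy()
        start_model.set_free(default_start(spec))
        exo = ExogenousCov([], np.empty((0, 0)))
        ll_start = wishart_loglik(S, implied_covariance(start_model, exo), 400)
        assert fit.loglik >= ll_start

    def test_parameter_recovery_rmse(self):
        tm = make_true_model(2, [3, 3], 0, 0, b_edges=[(0, 1, 0.5)], seed=11,
                             anchor=True)
        bundle = simulate_dataset(tm, 2000, seed=12)
        spec = measurement_spec_from_truth(tm)
        spec.B_free[1, 0] = True
        S = np.corrcoef(bundle.phenotypes.to_numpy(), rowvar=False)
        fit = fit_ml(spec, S, 2000)
        est = fit.model.Lambda[fit.model.Lambda_free]
        truth = tm.spec.Lambda[fit.model.Lambda_free]
        rmse = np.sqrt(np.mean((est - truth) ** 2))
        assert rmse < 0.05
        assert fit.model.B[1, 0] == pytest.approx(tm.spec.B[1, 0], abs=0.08)

    def test_identification_guard(self):
        m = ModelSpec(latent_names=["F1"], trait_names=["T1"])
        m.Lambda_free[0, 0] = True
        m.theta_eps_free[:] = True
        m.theta_delta_free[:] = True
        with pytest.raises(ValueError):
            fit_ml(m, np.eye(1), 100)


class TestParamSignificance:
    def test_z_quantile(self):
        info = np.array([[1.0]])          # se = 1
        p = param_significance(np.array([1.959964]), info)
        assert p[0] == pytest.approx(0.05, abs=1e-5)

    def test_zero_estimate(self):
        p = param_significance(np.array([0.0]), np.array([[4.0]]))
        assert p[0] == pytest.approx(1.0)

    def test_matches_normal_cdf_oracle(self):
        # est 0.5, se 0.1 -> z = 5 -> p = 2 (1 - Phi(5))
        info = np.array([[100.0]])        # var = 0.01
        p = param_significance(np.array([0.5]), info)
        assert p[0] == pytest.approx(2 * (1 - stats.norm.cdf(5.0)), rel=1e-8)

    def test_singular_information_flags_p_one(self):
        with pytest.warns(UserWarning):
            p = param_significance(np.array([1.0, 2.0]), np.zeros((2, 2)))
        np.testing.assert_allclose(p, 1.0)


class TestModelSpecContainer:
    def test_json_roundtrip(self, small_true_model):
        spec = small_true_model.spec
        spec2 = ModelSpec.from_json(spec.to_json())
        for m in ModelSpec.MATRICES:
            np.testing.assert_allclose(getattr(spec, m), getattr(spec2, m))
            np.testing.assert_array_equal(getattr(spec, m + "_free"),
                                          getattr(spec2, m + "_free"))
        assert spec.trait_kinds == spec2.trait_kinds

    def test_pack_set_free_roundtrip(self, small_true_model):
        spec = measurement_spec_from_truth(small_true_model)
        vec = spec.pack_free()
        spec.set_free(vec + 1.0)
        np.testing.assert_allclose(spec.pack_free(), vec + 1.0)

    def test_validate_rejects_two_free_cells_per_column(self):
        m = ModelSpec(latent_names=["F1", "F2"], trait_names=["T1", "T2"],
                      snp_factor_names=["s1"])
        m.Pi_free[:, 0] = True
        with pytest.raises(ValueError):
            m.validate()

    def test_validate_rejects_cyclic_b(self):
        m = ModelSpec(latent_names=["F1", "F2"], trait_names=["T1", "T2"])
        m.B[0, 1] = m.B[1, 0] = 0.5
        with pytest.raises(ValueError):
            m.validate()


def test_nearest_psd_repairs_indefinite_matrix():
    a = np.array([[1.0, 0.99, 0.0], [0.99, 1.0, 0.99], [0.0, 0.99, 1.0]])
    a[0, 2] = a[2, 0] = -0.99       # strongly indefinite
    fixed = nearest_psd(a)
    assert np.linalg.eigvalsh(fixed).min() >= 0
    already = np.eye(3)
    np.testing.assert_allclose(nearest_psd(already), already)
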