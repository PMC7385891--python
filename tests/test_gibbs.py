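import numpy as np
import pytest
from scipy import stats

from semgwas.gibbs import (GibbsConfig, draw_augmented, draw_coefficient_row,
                           draw_eta, draw_variances, effective_sample_size,
                           gelman_rubin, posterior_summary, run_chains,
                           sampled_masks, _extract)
from semgwas.model import ModelSpec
from semgwas.synthetic import make_true_model, simulate_dataset


class TestDrawAugmented:
    def test_support_constraint_binary_upper(self, rng):
        lo = np.zeros(10_000)
        hi = np.full(10_000, np.inf)
        draws = draw_augmented(lo, hi, rng)
        assert (draws > 0).all()

    def test_lower_half_mean(self, rng):
        # N(0,1) truncated to (-inf, 0]: mean = -sqrt(2/pi)
        lo = np.full(100_000, -np.inf)
        hi = np.zeros(100_000)
        draws = draw_augmented(lo, hi, rng)
        assert draws.mean() == pytest.approx(-np.sqrt(2 / np.pi), abs=0.01)
        assert (draws <= 0).all()

    def test_interval_containment(self, rng):
        lo = rng.uniform(-2, 0, 5000)
        hi = lo + rng.uniform(0.1, 2, 5000)
        draws = draw_augmented(lo, hi, rng)
        assert (draws > lo).all() and (draws <= hi + 1e-9).all()

    def test_truncated_moments(self, rng):
        lo, hi = -0.5, 1.0
        draws = draw_augmented(np.full(200_000, lo), np.full(200_000, hi), rng)
        ref = stats.truncnorm(lo, hi)
        assert draws.mean() == pytest.approx(ref.mean(), abs=0.01)
        assert draws.std() == pytest.approx(ref.std(), abs=0.01)


class TestDrawVariances:
    def test_prior_recovery_with_no_data(self, rng):
        draws = np.array([draw_variances(np.zeros(1), 0, 3.0, 2.0, rng)[0]
                          for _ in range(50_000)])
        assert draws.mean() == pytest.approx(2.0 / (3.0 - 1.0), abs=0.02)

    def test_posterior_moment_formula(self, rng):
        ssr, n, a0, b0 = 37.5, 40, 2.0, 1.0
        draws = np.array([draw_variances(np.array([ssr]), n, a0, b0, rng)[0]
                          for _ in range(100_000)])
        expect = (b0 + ssr / 2) / (a0 + n / 2 - 1)
        assert draws.mean() == pytest.approx(expect, rel=0.02)

    def test_strictly_positive(self, rng):
        draws = draw_variances(np.zeros(1000), 10, 2.0, 1.0, rng)
        assert (draws > 0).all()


class TestDrawCoefficientRow:
    def test_flat_prior_limit_matches_ols(self, rng):
        n, k = 400, 2
        X = rng.standard_normal((n, k))
        beta_true = np.array([0.7, -0.3])
        y = X @ beta_true + rng.standard_normal(n) * 0.5
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        draws = np.array([
            draw_coefficient_row(X, y, 0.25, np.zeros(k), 1e6, rng)
            for _ in range(20_000)])
        np.testing.assert_allclose(draws.mean(axis=0), ols, atol=0.01)

    def test_prior_dominance_limit(self, rng):
        X = rng.standard_normal((50, 1))
        y = rng.standard_normal(50)
        prior_mean = np.array([2.5])
        draws = np.array([
            draw_coefficient_row(X, y, 1.0, prior_mean, 1e-5, rng)[0]
            for _ in range(200)])
        np.testing.assert_allclose(draws, 2.5, atol=1e-3)


class TestDrawEta:
    def _single_factor_model(self):
        m = ModelSpec(latent_names=["F1"], trait_names=["T1", "T2"])
        m.Lambda[:, 0] = [1.0, 0.8]
        m.theta_eps[:] = 0.6
        m.theta_delta[:] = [0.3, 0.4]
        return m

    def test_conjugate_normal_oracle(self, rng):
        # closed-form posterior of eta given p for one sample
        m = self._single_factor_model()
        p = np.array([[0.9, -0.4]])
        prec = 1 / 0.6 + (1.0 ** 2 / 0.3 + 0.8 ** 2 / 0.4)
        mean = (1.0 * 0.9 / 0.3 + 0.8 * (-0.4) / 0.4) / prec
        draws = np.array([
            draw_eta(p, np.empty((1, 0)), m, rng)[0, 0]
            for _ in range(100_000)])
        assert draws.mean() == pytest.approx(mean, abs=0.01)
        assert draws.var() == pytest.approx(1 / prec, rel=0.03)

    def test_noiseless_limit_inverts_lambda(self, rng):
        m = ModelSpec(latent_names=["F1"], trait_names=["T1"])
        m.Lambda[0, 0] = 2.0
        m.theta_eps[:] = 1.0
        m.theta_delta[:] = 1e-10
        p = np.array([[1.4]])
        draws = draw_eta(np.tile(p, (100, 1)), np.empty((100, 0)), m, rng)
        np.testing.assert_allclose(draws, 1.4 / 2.0, atol=1e-4)

    def test_seeded_reproducibility(self):
        m = self._single_factor_model()
        p = np.random.default_rng(0).standard_normal((50, 2))
        d1 = draw_eta(p, np.empty((50, 0)), m, np.random.default_rng(9))
        d2 = draw_eta(p, np.empty((50, 0)), m, np.random.default_rng(9))
        np.testing.assert_array_equal(d1, d2)


class TestRunChains:
    def test_identical_seed_identical_draws(self, small_true_model,
                                            small_dataset):
        cfg = GibbsConfig(n_chains=2, length=60, burn_in=20)
        s1 = run_chains(small_true_model.spec.copy(), small_dataset, cfg, seed=5)
        s2 = run_chains(small_true_model.spec.copy(), small_dataset, cfg, seed=5)
        np.testing.assert_array_equal(s1.chains, s2.chains)

    def test_theta_draws_positive(self, small_true_model, small_dataset):
        cfg = GibbsConfig(n_chains=2, length=60, burn_in=10)
        s = run_chains(small_true_model.spec.copy(), small_dataset, cfg, seed=6)
        idx = [i for i, n in enumerate(s.param_names) if n.startswith("theta")]
        assert (s.chains[:, :, idx] > 0).all()

    def test_posterior_concentration_with_n(self, small_true_model):
        cfg = GibbsConfig(n_chains=2, length=400, burn_in=100)
        sds = []
        for n in (200, 2000):
            bundle = simulate_dataset(small_true_model, n, seed=3)
            s = run_chains(small_true_model.spec.copy(), bundle, cfg, seed=7)
            summ = posterior_summary(s)
            coef = [i for i, nm in enumerate(s.param_names)
                    if not nm.startswith("theta")]
            sds.append(summ["sd"].to_numpy()[coef].mean())
        assert sds[1] < sds[0]

    def test_geweke_joint_distribution(self, rng):
        # marginal-conditional vs successive-conditional simulation must agree
        # (no-SNP model: every conditional is exact and conjugate)
        n, iters = 15, 4000
        a0, b0, prior_sd, prior_mean = 4.0, 3.0, 0.5, 0.8

        def draw_prior(rng):
            lam = rng.normal(prior_mean, prior_sd)
            te = b0 / rng.gamma(a0, 1.0)
            td = b0 / rng.gamma(a0, 1.0, size=2)
            return lam, te, td

        def gen_data(lam, te, td, rng):
            eta = rng.normal(0, np.sqrt(te), n)
            p = np.column_stack([eta + rng.normal(0, np.sqrt(td[0]), n),
                                 lam * eta + rng.normal(0, np.sqrt(td[1]), n)])
            return eta, p

        # marginal-conditional: prior draws only
        mc = np.array([draw_prior(rng)[:2] for _ in range(iters)])

        # successive-conditional: Gibbs on (params, latent, data) jointly
        sc = np.empty((iters, 2))
        lam, te, td = draw_prior(rng)
        m = ModelSpec(latent_names=["F1"], trait_names=["T1", "T2"])
        for it in range(iters):
            eta, p = gen_data(lam, te, td, rng)
            m.Lambda[:, 0] = [1.0, lam]
            m.theta_eps[:] = te
            m.theta_delta[:] = td
            eta = draw_eta(p, np.empty((n, 0)), m, rng)[:, 0]
            te = draw_variances(np.array([(eta ** 2).sum()]), n, a0, b0, rng)[0]
            lam = draw_coefficient_row(eta[:, None], p[:, 1], td[1],
                                       np.array([prior_mean]), prior_sd, rng)[0]
            resid = np.column_stack([p[:, 0] - eta, p[:, 1] - lam * eta])
            td = draw_variances((resid ** 2).sum(axis=0), n, a0, b0, rng)
            sc[it] = [lam, te]

        for col, label in ((0, "lambda"), (1, "theta_eps")):
            q = np.linspace(0.1, 0.9, 9)
            qa = np.quantile(mc[:, col], q)
            qb = np.quantile(sc[500:, col], q)
            np.testing.assert_allclose(qa, qb, atol=0.12,
                                       err_msg=f"mismatch for {label}")


class TestDiagnostics:
    def test_rhat_iid_chains(self, rng):
        chains = rng.standard_normal((4, 2000, 3))
        r = gelman_rubin(chains)
        assert ((r > 0.99) & (r < 1.02)).all()

    def test_rhat_detects_separated_chains(self, rng):
        chains = np.stack([rng.normal(0, 1, (1000, 1)),
                           rng.normal(10, 1, (1000, 1))])
        assert gelman_rubin(chains)[0] > 1.05

    def test_rhat_affine_invariant(self, rng):
        chains = rng.standard_normal((3, 500, 1))
        r1 = gelman_rubin(chains)
        r2 = gelman_rubin(chains * 7.0 - 3.0)
        np.testing.assert_allclose(r1, r2, rtol=1e-10)

    def test_rhat_single_chain_raises(self, rng):
        with pytest.raises(ValueError):
            gelman_rubin(rng.standard_normal((1, 100, 2)))

    def test_ess_iid(self, rng):
        x = rng.standard_normal((1, 10_000, 1))
        ess = effective_sample_size(x)[0]
        assert ess == pytest.approx(10_000, rel=0.1)

    def test_ess_ar1_closed_form(self, rng):
        phi, L = 0.9, 200_000
        eps = rng.standard_normal(L)
        x = np.empty(L)
        x[0] = eps[0]
        for t in range(1, L):
            x[t] = phi * x[t - 1] + eps[t]
        ess = effective_sample_size(x[None, :, None])[0]
        expect = L * (1 - phi) / (1 + phi)
        assert ess == pytest.approx(expect, rel=0.2)

    def test_ess_bounded_by_total(self, rng):
        chains = rng.standard_normal((3, 500, 2))
        assert (effective_sample_size(chains) <= 1500 + 1e-9).all()

    def test_ess_constant_chain_zero(self):
        chains = np.ones((2, 100, 1))
        assert effective_sample_size(chains)[0] == 0


class TestPosteriorSummary:
    def _samples(self, chains, names=None):
        from semgwas.gibbs import PosteriorSamples

        names = names or [f"p{i}" for i in range(chains.shape[2])]
        return PosteriorSamples(param_names=names, chains=chains,
                                burn_in=0, length=chains.shape[1], seeds=[0])

    def test_constant_chains(self):
        chains = np.full((3, 50, 1), 2.5)
        summ = posterior_summary(self._samples(chains))
        assert summ["mean"].iloc[0] == 2.5
        assert summ["sd"].iloc[0] == 0.0

    def test_pooling_equals_concatenation(self, rng):
        chains = rng.standard_normal((4, 100, 2))
        summ = posterior_summary(self._samples(chains))
        flat = chains.reshape(-1, 2)
        np.testing.assert_allclose(summ["mean"], flat.mean(axis=0))
        np.testing.assert_allclose(summ["q05"],
                                   np.quantile(flat, 0.05, axis=0))

    def test_mean_matches_raw_average(self, rng):
        chains = rng.standard_normal((2, 300, 1))
        summ = posterior_summary(self._samples(chains))
        assert summ["mean"].iloc[0] == pytest.approx(chains.mean())


def test_sampled_masks_exclude_anchor_loadings(small_true_model):
    spec = small_true_model.spec
    masks = sampled_masks(spec)
    # anchored truth: Lambda anchors are exactly 1 and fixed
    anchors = (spec.Lambda == 1.0) & ~spec.Lambda_free
    assert not (masks["Lambda"] & anchors).any()
    assert masks["theta_eps"].all() and masks["theta_delta"].all()
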