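"""Sampler correctness tests: gradients, conjugacy, adaptation, pruning."""
import numpy as np
import pytest

from tacifa.model import PairedSeries, mean_curves
from tacifa.sampler import (
    SamplerConfig,
    TacifaSampler,
    adapt_step_size,
    psi_block_decomposition,
    run_mcmc,
)
from tacifa.synthdata import SimRecipe, generate_sim1


@pytest.fixture
def small_fit(rng):
    """A small sampler around simulated data, for gradient/conditional checks."""
    data, _ = generate_sim1(SimRecipe(p=4, T=20, seed=5, n_shared=2, n_ind=3))
    cfg = SamplerConfig(n_iter=10, n_burnin=5, K=6, r_init=3, r1_init=2, r2_init=2, seed=8)
    return TacifaSampler(data, cfg), data


def _fd_gradient(f, x, eps=1e-6):
    g = np.zeros_like(x)
    for i in range(x.size):
        xp, xm = x.copy(), x.copy()
        xp[i] += eps
        xm[i] -= eps
        g[i] = (f(xp) - f(xm)) / (2 * eps)
    return g


class TestHMCGradients:
    def test_kappa_gradient_matches_finite_differences(self, small_fit, rng):
        s, _ = small_fit
        for _ in range(3):
            q = s.kappa + 0.5 * rng.standard_normal(s.kappa.size)
            _, g = s.kappa_potential_grad(q)
            gfd = _fd_gradient(s.kappa_potential, q)
            assert np.max(np.abs(g - gfd) / (np.abs(gfd) + 1e-8)) < 1e-5

    def test_lambda_gradient_matches_finite_differences(self, small_fit, rng):
        """Validates the projector-derivative algebra for every column."""
        s, _ = small_fit
        s._lambda_caches()
        for j in range(s.r):
            q = s.Lambda[:, j] + 0.1 * rng.standard_normal(s.p)
            _, g = s.lambda_potential_grad(j, q)
            gfd = _fd_gradient(lambda x: s.lambda_potential(j, x), q)
            assert np.max(np.abs(g - gfd) / (np.abs(gfd) + 1e-8)) < 1e-5

    def test_potential_and_grad_agree_on_value(self, small_fit):
        s, _ = small_fit
        q = s.kappa.copy()
        assert s.kappa_potential(q) == pytest.approx(s.kappa_potential_grad(q)[0])
        s._lambda_caches()
        lam = s.Lambda[:, 0].copy()
        assert s.lambda_potential(0, lam) == pytest.approx(
            s.lambda_potential_grad(0, lam)[0])


class TestProjectorBlockIdentity:
    def test_block_decomposition_equals_projector(self, rng):
        from tacifa.model import projection

        for _ in range(20):
            p = int(rng.integers(4, 9))
            r = int(rng.integers(2, p))
            Lambda = rng.standard_normal((p, r))
            Psi = projection(Lambda)
            for j in range(r):
                assert np.allclose(psi_block_decomposition(Lambda, j), Psi, atol=1e-10)


class TestConjugateBlocks:
    def test_beta_conditional_matches_bayesian_regression(self, rng):
        """Single-feature, single-factor: the beta_shared full conditional
        equals the closed-form Gaussian linear-regression posterior."""
        from tacifa.model import FactorCoeffs, LoadingSet, ModelState, NoiseState
        from tacifa.splines import WarpSpec

        T, K = 30, 5
        t = np.arange(1, T + 1) / T
        lam = 1.7
        sigma2 = 0.8
        omega = 50.0
        X = rng.standard_normal((1, T))
        Y = rng.standard_normal((1, T))
        cfg = SamplerConfig(n_iter=4, n_burnin=2, K=K, r_init=1, r1_init=1, r2_init=1,
                            omega=omega, seed=0)
        bases = cfg.bases()
        state = ModelState(
            loadings=LoadingSet(np.array([[lam]]), np.zeros((1, 1)), np.zeros((1, 1)),
                                np.array([1.0]), np.array([1.0])),
            coeffs=FactorCoeffs(np.zeros((1, K)), np.zeros((1, K)), np.zeros((1, K))),
            warp=WarpSpec.identity(bases.warp),
            noise=NoiseState(np.array([sigma2]), np.array([sigma2])),
        )
        data = PairedSeries(X, Y, t)
        s = TacifaSampler(data, cfg, state=state)
        prec, lin = s.beta_shared_conditional()
        # oracle: ridge-style posterior of X', Y' regressed on lam * B(t)
        # (identity warp makes the Y design identical to the X design)
        B = bases.shared.design(t)
        D = np.vstack([lam * B, lam * B])
        resp = np.concatenate([X[0], Y[0]])
        prec_oracle = D.T @ D / sigma2 + np.eye(K) / omega
        mean_oracle = np.linalg.solve(prec_oracle, D.T @ resp / sigma2)
        assert np.allclose(prec, prec_oracle, atol=1e-8)
        assert np.allclose(np.linalg.solve(prec, lin), mean_oracle, atol=1e-8)

    def test_tiny_prior_variance_collapses_beta_to_zero(self, rng):
        data, _ = generate_sim1(SimRecipe(p=4, T=15, seed=2, n_shared=2, n_ind=2))
        cfg = SamplerConfig(n_iter=4, n_burnin=2, K=6, r_init=2, r1_init=2, r2_init=2,
                            omega=1e-12, seed=1)
        s = TacifaSampler(data, cfg)
        s.update_beta_shared()
        assert np.max(np.abs(s.beta)) < 1e-4

    def test_geweke_joint_vs_successive_conditional(self):
        """Getting-it-right check on the conjugate blocks at toy dimensions.

        Holding Lambda and kappa fixed, draws of (beta, Gamma, Xi, sigma)
        from prior->data simulation and from successive-conditional Gibbs
        cycling must share marginal moments.
        """
        p, T, K = 2, 10, 4
        n_cycles = 3000
        omega = 1.0
        t = np.arange(1, T + 1) / T
        cfg = SamplerConfig(n_iter=4, n_burnin=2, K=K, r_init=1, r1_init=1, r2_init=1,
                            omega=omega, sigma_shape=3.0, sigma_rate=3.0,
                            nu=3.0, delta_shape1=3.0, delta_shape2=3.0, seed=0)
        bases = cfg.bases()
        rng = np.random.default_rng(99)
        Lambda_fixed = np.array([[1.0], [0.5]])

        def draw_prior_state(s):
            s.Lambda = Lambda_fixed.copy()
            s._refresh_psi()
            s.phi1 = rng.gamma(cfg.nu, 1 / cfg.nu, (p, 1))
            s.delta1 = rng.gamma(cfg.delta_shape1, 1.0, 1)
            s.phi11 = rng.gamma(cfg.nu, 1 / cfg.nu, (p, 1))
            s.delta11 = rng.gamma(cfg.delta_shape1, 1.0, 1)
            s.phi12 = rng.gamma(cfg.nu, 1 / cfg.nu, (p, 1))
            s.delta12 = rng.gamma(cfg.delta_shape1, 1.0, 1)
            s.Gamma1 = rng.normal(0, 1, (p, 1)) / np.sqrt(s.phi11 * s.tau11)
            s.Gamma2 = rng.normal(0, 1, (p, 1)) / np.sqrt(s.phi12 * s.tau12)
            s.beta = rng.normal(0, np.sqrt(omega), (1, K))
            s.beta1 = rng.normal(0, np.sqrt(omega), (1, K))
            s.beta2 = rng.normal(0, np.sqrt(omega), (1, K))
            s.xi1 = rng.normal(0, np.sqrt(omega), 1)
            s.xi2 = rng.normal(0, np.sqrt(omega), 1)
            s.s1sq = 1 / rng.gamma(cfg.sigma_shape, 1 / cfg.sigma_rate, p)
            s.s2sq = 1 / rng.gamma(cfg.sigma_shape, 1 / cfg.sigma_rate, p)
            s._refresh_factors()

        def simulate_data(s):
            mu_X, mu_Y = mean_curves(s.snapshot(), bases, t)
            X = mu_X + rng.normal(0, np.sqrt(s.s1sq)[:, None], (p, T))
            Y = mu_Y + rng.normal(0, np.sqrt(s.s2sq)[:, None], (p, T))
            s.X, s.Y = X, Y

        dummy = PairedSeries(np.zeros((p, T)), np.zeros((p, T)), t)
        s = TacifaSampler(dummy, cfg, rng=rng)

        # marginal-conditional samples: fresh prior state + data each time
        mc = np.empty((n_cycles // 10, 2))
        for i in range(mc.shape[0]):
            draw_prior_state(s)
            mc[i] = [np.log(s.s1sq).mean(), s.beta[0, 0]]

        # successive-conditional: alternate Gibbs update and data refresh
        draw_prior_state(s)
        simulate_data(s)
        sc = np.empty((n_cycles, 2))
        for i in range(n_cycles):
            s.update_linear_blocks()
            s.update_sigma()
            s.update_shrinkage()
            s.Lambda = Lambda_fixed.copy()  # kept fixed in this check
            s._refresh_psi()
            simulate_data(s)
            sc[i] = [np.log(s.s1sq).mean(), s.beta[0, 0]]

        for col in range(2):
            a, b = mc[:, col], sc[::5, col]
            se = np.sqrt(a.var() / a.size + b.var() / b.size)
            z = (a.mean() - b.mean()) / se
            assert abs(z) < 5.0, f"Geweke z-score {z:.2f} for statistic {col}"


class TestAdaptation:
    @pytest.mark.parametrize("rate, expect", [
        (0.5, "down"), (0.7, "same"), (1.0, "up"), (0.1, "down"), (0.85, "up"),
    ])
    def test_step_size_rule(self, rate, expect):
        new = adapt_step_size(0.1, rate)
        if expect == "down":
            assert new < 0.1
        elif expect == "up":
            assert new > 0.1
        else:
            assert new == 0.1


class TestPruning:
    def test_zero_column_removed(self, small_fit):
        s, _ = small_fit
        s.Lambda[:, -1] = 0.0
        r_before = s.r
        s.prune(iteration=1)
        assert s.r == r_before - 1
        assert s.beta.shape[0] == s.r
        assert s.xi1.size == s.r and s.phi1.shape[1] == s.r and s.delta1.size == s.r
        assert s.settings.step_size_lambda.size == s.r

    def test_all_columns_above_threshold_unchanged(self, small_fit):
        s, _ = small_fit
        before = s.Lambda.copy()
        s.prune(iteration=1)
        assert np.array_equal(s.Lambda, before)

    def test_rank_never_below_one(self, small_fit):
        s, _ = small_fit
        s.Lambda[:] = 0.0
        s.Lambda[0, 1] = 1e-4  # still below threshold, but the largest
        s.prune(iteration=1)
        assert s.r == 1


class TestRunMcmc:
    def test_seed_reproducibility(self):
        data, _ = generate_sim1(SimRecipe(p=4, T=15, seed=3, n_shared=2, n_ind=2))
        cfg = SamplerConfig(n_iter=12, n_burnin=6, K=5, r_init=2, r1_init=2, r2_init=2,
                            seed=42)
        c1 = run_mcmc(data, cfg)
        c2 = run_mcmc(data, cfg)
        for s1, s2 in zip(c1.states, c2.states):
            assert np.array_equal(s1.loadings.Lambda, s2.loadings.Lambda)
            assert np.array_equal(s1.warp.kappa, s2.warp.kappa)
            assert np.array_equal(s1.noise.sigma1_sq, s2.noise.sigma1_sq)

    def test_zero_iteration_run(self):
        data, _ = generate_sim1(SimRecipe(p=3, T=10, seed=1, n_shared=2, n_ind=2))
        cfg = SamplerConfig(n_iter=0, n_burnin=0, K=5, r_init=2, r1_init=1, r2_init=1)
        chain = run_mcmc(data, cfg)
        assert len(chain) == 0

    def test_zero_step_size_leaves_state_unchanged(self, small_fit):
        s, _ = small_fit
        s.settings.step_size_kappa = 0.0
        before = s.kappa.copy()
        s.hmc_kappa()
        assert np.array_equal(s.kappa, before)

    def test_invalid_burnin_rejected(self):
        with pytest.raises(ValueError):
            SamplerConfig(n_iter=10, n_burnin=10)

    def test_chain_save_load_round_trip(self, tmp_path):
        from tacifa.sampler import Chain

        data, _ = generate_sim1(SimRecipe(p=4, T=15, seed=3, n_shared=2, n_ind=2))
        cfg = SamplerConfig(n_iter=8, n_burnin=4, K=5, r_init=2, r1_init=2,
                            r2_init=2, seed=42)
        chain = run_mcmc(data, cfg)
        chain.save(tmp_path / "chain")
        back = Chain.load(tmp_path / "chain")
        assert len(back) == len(chain)
        for s1, s2 in zip(chain.states, back.states):
            assert np.array_equal(s1.loadings.Lambda, s2.loadings.Lambda)
            assert np.array_equal(s1.warp.kappa, s2.warp.kappa)
        assert np.array_equal(back.rank_history, chain.rank_history)
        assert back.config.seed == chain.config.seed


class TestLambdaPriorLimit:
    def test_likelihood_free_limit_matches_prior(self, rng):
        """With enormous noise variances the Lambda HMC draws follow the
        N(0, phi^-1 tau^-1) prior marginally."""
        data, _ = generate_sim1(SimRecipe(p=3, T=10, seed=6, n_shared=2, n_ind=2))
        cfg = SamplerConfig(n_iter=4, n_burnin=2, K=5, r_init=2, r1_init=1, r2_init=1,
                            seed=11)
        s = TacifaSampler(data, cfg, rng=rng)
        s.s1sq = np.full(3, 1e12)
        s.s2sq = np.full(3, 1e12)
        s.phi1 = np.full((3, 2), 2.0)
        s.delta1 = np.array([1.5, 1.0])
        s.Lambda = rng.standard_normal((3, 2)) * 0.1
        s._refresh_psi()
        s.settings.step_size_lambda[:] = 0.3
        s._lambda_caches()
        draws = []
        for _ in range(800):
            s.hmc_lambda_column(0)
            draws.append(s.Lambda[:, 0].copy())
        draws = np.array(draws[100:])
        target_var = 1.0 / (2.0 * 1.5)  # phi = 2, tau_1 = delta_1 = 1.5
        assert draws.mean() == pytest.approx(0.0, abs=0.1)
        assert draws.var() == pytest.approx(target_var, rel=0.25)
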