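"""Projection, mean-curve, likelihood and similarity tests."""
import numpy as np
import pytest
from scipy import stats

from tacifa.model import (
    FactorCoeffs,
    LoadingSet,
    ModelBases,
    ModelState,
    NoiseState,
    PairedSeries,
    log_likelihood,
    mean_curves,
    projection,
    syn_similarity,
)
from tacifa.splines import WarpSpec

from conftest import random_state


class TestProjection:
    def test_coordinate_projection(self):
        Lambda = np.eye(6)[:, :2]
        Psi = projection(Lambda)
        expected = np.diag([0.0, 0.0, 1, 1, 1, 1])
        assert np.allclose(Psi, expected)

    def test_projector_algebra(self, rng):
        Lambda = rng.standard_normal((6, 2))
        Psi = projection(Lambda)
        assert np.allclose(Psi, Psi.T, atol=1e-10)
        assert np.allclose(Psi @ Psi, Psi, atol=1e-10)
        assert np.allclose(Psi @ Lambda, 0, atol=1e-10)

    def test_trace_equals_p_minus_r(self, rng):
        for _ in range(100):
            p = int(rng.integers(3, 10))
            r = int(rng.integers(1, p))
            Psi = projection(rng.standard_normal((p, r)))
            assert np.trace(Psi) == pytest.approx(p - r, abs=1e-8)

    def test_rank_deficient_warns(self):
        Lambda = np.ones((4, 2))  # duplicated columns
        with pytest.warns(RuntimeWarning):
            Psi = projection(Lambda)
        assert np.allclose(Psi @ Lambda, 0, atol=1e-8)


class TestMeanCurves:
    def test_identical_shared_parts_no_individual(self, rng):
        """With zero Gammas, identity warp and equal scales, mu_X == mu_Y."""
        state, bases = random_state(rng, identity_warp=True)
        L = state.loadings
        state = state.replace(loadings=LoadingSet(
            L.Lambda, np.zeros_like(L.Gamma1), np.zeros_like(L.Gamma2), L.Xi1, L.Xi1))
        t = np.linspace(0, 1, 40)
        mu_X, mu_Y = mean_curves(state, bases, t)
        assert np.allclose(mu_X, mu_Y, atol=1e-10)

    def test_zero_shared_coefficients(self, rng):
        state, bases = random_state(rng)
        c = state.coeffs
        state = state.replace(coeffs=FactorCoeffs(
            np.zeros_like(c.beta_shared), c.beta_ind1, c.beta_ind2))
        t = np.linspace(0, 1, 25)
        mu_X, _ = mean_curves(state, bases, t)
        L = state.loadings
        zeta1 = c.beta_ind1 @ bases.ind1.design(t).T
        assert np.allclose(mu_X, L.Psi @ (L.Gamma1 @ zeta1), atol=1e-12)

    def test_shared_and_individual_parts_orthogonal(self, rng):
        state, bases = random_state(rng, p=7, r=3)
        L = state.loadings
        t = np.linspace(0, 1, 30)
        eta = state.coeffs.beta_shared @ bases.shared.design(t).T
        shared = L.Lambda @ (L.Xi1[:, None] * eta)
        individual = L.Psi @ (L.Gamma1 @ (state.coeffs.beta_ind1 @ bases.ind1.design(t).T))
        cross = np.abs((shared * individual).sum(axis=0))
        assert cross.max() < 1e-8


class TestLogLikelihood:
    def test_zero_residual_unit_variance(self, rng):
        state, bases = random_state(rng, p=4)
        state = state.replace(noise=NoiseState(np.ones(4), np.ones(4)))
        t = np.linspace(0, 1, 10)
        mu_X, mu_Y = mean_curves(state, bases, t)
        data = PairedSeries(mu_X, mu_Y, t)
        p, T = 4, 10
        assert log_likelihood(state, data, bases) == pytest.approx(-p * T * np.log(2 * np.pi))

    def test_matches_entrywise_density_sum(self, rng):
        """Brute-force scipy.stats per-entry log-density oracle."""
        state, bases = random_state(rng, p=4)
        t = np.linspace(0, 1, 10)
        mu_X, mu_Y = mean_curves(state, bases, t)
        X = mu_X + rng.standard_normal(mu_X.shape)
        Y = mu_Y + rng.standard_normal(mu_Y.shape)
        data = PairedSeries(X, Y, t)
        oracle = 0.0
        for mu, obs, s2 in ((mu_X, X, state.noise.sigma1_sq), (mu_Y, Y, state.noise.sigma2_sq)):
            for l in range(4):
                oracle += stats.norm.logpdf(obs[l], mu[l], np.sqrt(s2[l])).sum()
        assert log_likelihood(state, data, bases) == pytest.approx(oracle, abs=1e-10)

    def test_variance_change_is_feature_separable(self, rng):
        state, bases = random_state(rng, p=4)
        t = np.linspace(0, 1, 12)
        mu_X, mu_Y = mean_curves(state, bases, t)
        X = mu_X + rng.standard_normal(mu_X.shape)
        data = PairedSeries(X, mu_Y, t)
        base = log_likelihood(state, data, bases)
        s2 = state.noise.sigma1_sq.copy()
        s2_new = s2.copy()
        s2_new[2] *= 2.0
        bumped = state.replace(noise=NoiseState(s2_new, state.noise.sigma2_sq))
        delta = log_likelihood(bumped, data, bases) - base
        resid_sq = ((X - mu_X)[2] ** 2).sum()
        expected = -0.5 * 12 * np.log(2.0) - 0.5 * resid_sq / s2_new[2] + 0.5 * resid_sq / s2[2]
        assert delta == pytest.approx(expected, abs=1e-10)

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            NoiseState(np.array([1.0, -0.5]), np.array([1.0, 1.0]))


def _constant_factor_state(sx_target: float, sy_target: float) -> tuple[ModelState, ModelBases]:
    """p=1 state whose shared-variance shares are exactly (sx, sy).

    With p=1 and r=1 the projector Psi is 0, so the individual terms
    vanish; constant coefficient rows make eta constant in t (partition
    of unity), so shares are (xi*eta)^2 / ((xi*eta)^2 + sigma^2).
    """
    bases = ModelBases.tied(5)
    a = np.sqrt(sx_target / (1 - sx_target))  # with sigma^2 = 1
    b = np.sqrt(sy_target / (1 - sy_target))
    state = ModelState(
        loadings=LoadingSet(np.array([[1.0]]), np.zeros((1, 1)), np.zeros((1, 1)),
                            np.array([a]), np.array([b])),
        coeffs=FactorCoeffs(np.ones((1, 5)), np.zeros((1, 5)), np.zeros((1, 5))),
        warp=WarpSpec(np.zeros(4)),
        noise=NoiseState(np.ones(1), np.ones(1)),
    )
    return state, bases


class TestSynSimilarity:
    def test_identical_series_gives_one(self, rng):
        state, bases = random_state(rng, identity_warp=True)
        L = state.loadings
        state = state.replace(
            loadings=LoadingSet(L.Lambda, L.Gamma1, L.Gamma1, L.Xi1, L.Xi1),
            coeffs=FactorCoeffs(state.coeffs.beta_shared, state.coeffs.beta_ind1,
                                state.coeffs.beta_ind1),
            noise=NoiseState(state.noise.sigma1_sq, state.noise.sigma1_sq),
        )
        t = np.linspace(0, 1, 30)
        assert syn_similarity(state, bases, t) == pytest.approx(1.0)

    def test_hand_computed_single_entry(self):
        """Shares 0.8 vs 0.3 at a single feature/time give Syn = 0.5."""
        state, bases = _constant_factor_state(0.8, 0.3)
        assert syn_similarity(state, bases, np.array([0.4])) == pytest.approx(0.5, abs=1e-9)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(25):
            state, bases = random_state(rng)
            syn = syn_similarity(state, bases, np.linspace(0, 1, 20))
            assert 0.0 <= syn <= 1.0

    def test_symmetric_under_role_swap_identity_warp(self, rng):
        state, bases = random_state(rng, identity_warp=True)
        L, c = state.loadings, state.coeffs
        swapped = state.replace(
            loadings=LoadingSet(L.Lambda, L.Gamma2, L.Gamma1, L.Xi2, L.Xi1),
            coeffs=FactorCoeffs(c.beta_shared, c.beta_ind2, c.beta_ind1),
            noise=NoiseState(state.noise.sigma2_sq, state.noise.sigma1_sq),
        )
        t = np.linspace(0, 1, 25)
        assert syn_similarity(state, bases, t) == pytest.approx(
            syn_similarity(swapped, bases, t), abs=1e-12)

    def test_sign_flip_rotation_invariance(self, rng):
        """Flipping a column's sign in Lambda and its factor row leaves Syn unchanged."""
        state, bases = random_state(rng, p=6, r=3)
        L, c = state.loadings, state.coeffs
        flip = np.array([1.0, -1.0, 1.0])
        flipped = state.replace(
            loadings=LoadingSet(L.Lambda * flip[None, :], L.Gamma1, L.Gamma2, L.Xi1, L.Xi2),
            coeffs=FactorCoeffs(c.beta_shared * flip[:, None], c.beta_ind1, c.beta_ind2),
        )
        t = np.linspace(0, 1, 20)
        assert syn_similarity(flipped, bases, t) == pytest.approx(
            syn_similarity(state, bases, t), abs=1e-10)


class TestPairedSeries:
    def test_shape_and_grid_validation(self):
        X = np.zeros((3, 5))
        with pytest.raises(ValueError):
            PairedSeries(X, np.zeros((3, 4)), np.linspace(0, 1, 5))
        with pytest.raises(ValueError):
            PairedSeries(X, X, np.linspace(0, 2, 5))
        with pytest.raises(ValueError):
            PairedSeries(X, X, np.ones(5) * 0.5)
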