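"""Model containers and likelihood machinery.

The observation model for a pair of p-dimensional series on a common time
grid t_1..t_T in [0, 1] is

    x_t = Psi Gamma1 zeta1(t) + Lambda Xi1 eta(t)     + eps1_t,
    y_t = Psi Gamma2 zeta2(t) + Lambda Xi2 eta(M(t))  + eps2_t,

where Lambda (p x r) spans the shared subspace, Psi = I - Lambda
(Lambda' Lambda)^{-1} Lambda' projects onto its orthogonal complement so
Gamma1, Gamma2 generate strictly individual-specific structure, Xi1, Xi2
are diagonal scales, the latent factor curves eta, zeta1, zeta2 are
B-spline expansions, M is the monotone warp, and the errors are Gaussian
with feature-specific diagonal covariances.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .splines import BasisSpec, WarpSpec, eval_warp

__all__ = [
    "PairedSeries",
    "LoadingSet",
    "FactorCoeffs",
    "NoiseState",
    "ModelBases",
    "ModelState",
    "projection",
    "mean_curves",
    "log_likelihood",
    "log_likelihood_from_means",
    "syn_similarity",
]


@dataclass(frozen=True)
class PairedSeries:
    """Two p x T data matrices observed on a shared time grid in [0, 1]."""

    X: np.ndarray
    Y: np.ndarray
    t: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        Y = np.asarray(self.Y, dtype=float)
        t = np.asarray(self.t, dtype=float)
        if X.ndim != 2 or Y.ndim != 2:
            raise ValueError("X and Y must be 2-D (features x time)")
        if X.shape != Y.shape:
            raise ValueError(f"X and Y must share shape; got {X.shape} vs {Y.shape}")
        if t.shape != (X.shape[1],):
            raise ValueError(f"time grid length {t.shape} != T={X.shape[1]}")
        if t.min() < 0 or t.max() > 1:
            raise ValueError("time grid must lie in [0, 1]")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
            raise ValueError("data must be finite (no NaN/inf)")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y)
        object.__setattr__(self, "t", t)

    @property
    def p(self) -> int:
        return self.X.shape[0]

    @property
    def T(self) -> int:
        return self.X.shape[1]

    def subset(self, columns: np.ndarray) -> "PairedSeries":
        """Restrict both series to a subset of time columns."""
        columns = np.sort(np.asarray(columns))
        return PairedSeries(self.X[:, columns], self.Y[:, columns], self.t[columns])


def projection(Lambda: np.ndarray) -> np.ndarray:
    """Orthogonal projector Psi = I - Lambda (Lambda'Lambda)^{-1} Lambda'.

    Symmetric, idempotent, annihilates the columns of Lambda, and has
    trace p - r for full-column-rank Lambda.  A rank-deficient Lambda
    (smallest singular value <= 1e-10) falls back to the pseudo-inverse
    with a warning, signalling a near-degenerate column during sampling.
    """
    Lambda = np.atleast_2d(np.asarray(Lambda, dtype=float))
    p = Lambda.shape[0]
    smin = np.linalg.svd(Lambda, compute_uv=False).min() if Lambda.size else 0.0
    if smin <= 1e-10:
        warnings.warn(
            "Lambda is (near) rank deficient; using pseudo-inverse projector",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.eye(p) - Lambda @ np.linalg.pinv(Lambda)
    G = Lambda.T @ Lambda
    return np.eye(p) - Lambda @ np.linalg.solve(G, Lambda.T)


@dataclass(frozen=True)
class LoadingSet:
    """Loading matrices and diagonal scales of the two series."""

    Lambda: np.ndarray  # p x r shared loadings
    Gamma1: np.ndarray  # p x r1 individual loadings, series 1
    Gamma2: np.ndarray  # p x r2 individual loadings, series 2
    Xi1: np.ndarray  # length-r diagonal of Xi1
    Xi2: np.ndarray  # length-r diagonal of Xi2

    def __post_init__(self) -> None:
        for name in ("Lambda", "Gamma1", "Gamma2"):
            object.__setattr__(self, name, np.atleast_2d(np.asarray(getattr(self, name), float)))
        for name in ("Xi1", "Xi2"):
            object.__setattr__(self, name, np.atleast_1d(np.asarray(getattr(self, name), float)))
        p, r = self.Lambda.shape
        if self.Gamma1.shape[0] != p or self.Gamma2.shape[0] != p:
            raise ValueError("Gamma1/Gamma2 must have the same number of rows as Lambda")
        if self.Xi1.shape != (r,) or self.Xi2.shape != (r,):
            raise ValueError("Xi1/Xi2 must be length-r diagonals")

    @property
    def p(self) -> int:
        return self.Lambda.shape[0]

    @property
    def r(self) -> int:
        return self.Lambda.shape[1]

    @property
    def r1(self) -> int:
        return self.Gamma1.shape[1]

    @property
    def r2(self) -> int:
        return self.Gamma2.shape[1]

    @property
    def Psi(self) -> np.ndarray:
        return projection(self.Lambda)


@dataclass(frozen=True)
class FactorCoeffs:
    """B-spline coefficient blocks of the latent factor curves."""

    beta_shared: np.ndarray  # r x K
    beta_ind1: np.ndarray  # r1 x K1
    beta_ind2: np.ndarray  # r2 x K2

    def __post_init__(self) -> None:
        for name in ("beta_shared", "beta_ind1", "beta_ind2"):
            object.__setattr__(self, name, np.atleast_2d(np.asarray(getattr(self, name), float)))


@dataclass(frozen=True)
class NoiseState:
    """Feature-specific error variances of the two series."""

    sigma1_sq: np.ndarray
    sigma2_sq: np.ndarray

    def __post_init__(self) -> None:
        for name in ("sigma1_sq", "sigma2_sq"):
            v = np.atleast_1d(np.asarray(getattr(self, name), float))
            if np.any(v <= 0):
                raise ValueError(f"{name} must be strictly positive")
            object.__setattr__(self, name, v)


@dataclass(frozen=True)
class ModelBases:
    """The four B-spline bases of the model (shared, individual x2, warp)."""

    shared: BasisSpec  # K bases for eta
    ind1: BasisSpec  # K1 bases for zeta1
    ind2: BasisSpec  # K2 bases for zeta2
    warp: BasisSpec  # J bases for M

    @staticmethod
    def tied(K: int, K1: int | None = None, K2: int | None = None, J: int | None = None,
             degree: int = 3) -> "ModelBases":
        return ModelBases(
            shared=BasisSpec(K, degree),
            ind1=BasisSpec(K1 or K, degree),
            ind2=BasisSpec(K2 or K, degree),
            warp=BasisSpec(J or K, degree),
        )


@dataclass(frozen=True)
class ModelState:
    """One complete set of model unknowns."""

    loadings: LoadingSet
    coeffs: FactorCoeffs
    warp: WarpSpec
    noise: NoiseState
    shrinkage: "object | None" = None  # ShrinkageState; optional outside the sampler

    def replace(self, **kw) -> "ModelState":
        return replace(self, **kw)


def factor_curves(state: ModelState, bases: ModelBases, t: np.ndarray):
    """Evaluate (eta(t), eta(M(t)), zeta1(t), zeta2(t)) on a grid."""
    Bt = bases.shared.design(t)
    M = eval_warp(state.warp, bases.warp, t)
    BM = bases.shared.design(M)
    eta = state.coeffs.beta_shared @ Bt.T
    eta_M = state.coeffs.beta_shared @ BM.T
    zeta1 = state.coeffs.beta_ind1 @ bases.ind1.design(t).T
    zeta2 = state.coeffs.beta_ind2 @ bases.ind2.design(t).T
    return eta, eta_M, zeta1, zeta2


def mean_curves(state: ModelState, bases: ModelBases, t: np.ndarray):
    """Model mean matrices (mu_X, mu_Y), each p x len(t).

    mu_X(t) = Psi Gamma1 zeta1(t) + Lambda Xi1 eta(t) and
    mu_Y(t) = Psi Gamma2 zeta2(t) + Lambda Xi2 eta(M(t)); the Y mean uses
    the nested composition eta o M.
    """
    L = state.loadings
    eta, eta_M, zeta1, zeta2 = factor_curves(state, bases, t)
    Psi = L.Psi
    mu_X = Psi @ (L.Gamma1 @ zeta1) + L.Lambda @ (L.Xi1[:, None] * eta)
    mu_Y = Psi @ (L.Gamma2 @ zeta2) + L.Lambda @ (L.Xi2[:, None] * eta_M)
    return mu_X, mu_Y


def log_likelihood_from_means(mu_X, mu_Y, noise: NoiseState, data: PairedSeries) -> float:
    """Gaussian log likelihood given precomputed mean matrices."""
    T = data.T
    ll = 0.0
    for mu, obs, s2 in ((mu_X, data.X, noise.sigma1_sq), (mu_Y, data.Y, noise.sigma2_sq)):
        resid = obs - mu
        ll -= 0.5 * T * np.sum(np.log(2.0 * np.pi * s2))
        ll -= 0.5 * np.sum(resid**2 / s2[:, None])
    return float(ll)


def log_likelihood(state: ModelState, data: PairedSeries, bases: ModelBases) -> float:
    """Joint Gaussian log likelihood of both series under the model."""
    mu_X, mu_Y = mean_curves(state, bases, data.t)
    return log_likelihood_from_means(mu_X, mu_Y, state.noise, data)


def shared_variance_shares(state: ModelState, bases: ModelBases, t: np.ndarray):
    """Per-feature, per-time relative shared-variance contributions.

    For feature l of series X this is

        (Lambda_l Xi1 eta(t))^2
        ------------------------------------------------------------
        (Psi_l Gamma1 zeta1(t))^2 + (Lambda_l Xi1 eta(t))^2 + sigma1l^2

    (and the warped analogue for Y), always in [0, 1).
    """
    L = state.loadings
    eta, eta_M, zeta1, zeta2 = factor_curves(state, bases, t)
    Psi = L.Psi
    shared_x = L.Lambda @ (L.Xi1[:, None] * eta)
    shared_y = L.Lambda @ (L.Xi2[:, None] * eta_M)
    ind_x = Psi @ (L.Gamma1 @ zeta1)
    ind_y = Psi @ (L.Gamma2 @ zeta2)
    sx = shared_x**2 / (ind_x**2 + shared_x**2 + state.noise.sigma1_sq[:, None])
    sy = shared_y**2 / (ind_y**2 + shared_y**2 + state.noise.sigma2_sq[:, None])
    return sx, sy


def syn_similarity(state: ModelState, bases: ModelBases, t: np.ndarray) -> float:
    """Syn similarity statistic in [0, 1].

    Syn = 1 - (1/(pT)) sum_l | sum_t (s_X[l,t] - s_Y[l,t]) | where s_X and
    s_Y are the relative shared-variance contributions of feature l at time
    t for each series.  Syn = 1 means the warped shared structure explains
    the same fraction of variance feature-by-feature in both series.
    """
    sx, sy = shared_variance_shares(state, bases, t)
    p, T = sx.shape
    return float(1.0 - np.abs((sx - sy).sum(axis=1)).sum() / (p * T))
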