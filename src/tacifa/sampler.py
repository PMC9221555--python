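"""Posterior computation: HMC-within-Gibbs with rank adaptation.

All conditionally linear-Gaussian blocks (factor coefficients, individual
loadings, diagonal scales) are drawn from their exact Gaussian full
conditionals; noise precisions and the multiplicative-gamma shrinkage
locals/globals from their Gamma conditionals.  The shared loading matrix
Lambda (column by column) and the warp parameters kappa are updated by
Hamiltonian Monte Carlo with analytic gradients, a fixed leapfrog length
of 30 and step sizes tuned during burn-in to keep acceptance rates in
[0.6, 0.8].  Columns whose entries all fall within a small threshold of
zero are pruned during burn-in, letting the shrinkage prior select the
number of factors.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import asdict as dataclass_asdict
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .model import (
    FactorCoeffs,
    LoadingSet,
    ModelBases,
    ModelState,
    NoiseState,
    PairedSeries,
    projection,
)
from .splines import WarpSpec, gamma_from_kappa

__all__ = [
    "ShrinkageState",
    "HMCSettings",
    "SamplerConfig",
    "Chain",
    "TacifaSampler",
    "run_mcmc",
    "select_basis_size",
    "gibbs_update_linear_blocks",
    "hmc_update_kappa",
    "hmc_update_lambda_column",
    "adapt_step_size",
    "prune_columns",
    "psi_block_decomposition",
]


# --------------------------------------------------------------------------
# configuration and state containers


@dataclass(frozen=True)
class ShrinkageState:
    """Multiplicative-gamma-process shrinkage parameters.

    Each loading matrix has entrywise local precisions phi and a column
    precision tau_k that is the running product of gamma-distributed
    multipliers delta_1..delta_k, so later columns are shrunk ever harder
    toward zero -- the mechanism behind automatic rank selection.
    """

    phi1: np.ndarray  # p x r, locals for Lambda
    phi11: np.ndarray  # p x r1, locals for Gamma1
    phi12: np.ndarray  # p x r2, locals for Gamma2
    delta1: np.ndarray  # length r
    delta11: np.ndarray  # length r1
    delta12: np.ndarray  # length r2

    @property
    def tau1(self) -> np.ndarray:
        return np.cumprod(self.delta1)

    @property
    def tau11(self) -> np.ndarray:
        return np.cumprod(self.delta11)

    @property
    def tau12(self) -> np.ndarray:
        return np.cumprod(self.delta12)


@dataclass
class HMCSettings:
    """Leapfrog settings and per-block step sizes."""

    leapfrog_steps: int = 30
    step_size_kappa: float = 0.01
    step_size_lambda: np.ndarray = field(default_factory=lambda: np.array([0.01]))
    target_accept_band: tuple[float, float] = (0.6, 0.8)
    adapt_interval: int = 100


@dataclass(frozen=True)
class SamplerConfig:
    """Everything needed to reproduce a run.

    Basis sizes K1, K2, J default to K (tied, as in the cross-validated
    fits).  Initial ranks default to p, a conservative upper bound from
    which pruning works downward.  ``omega`` is the prior *variance* of
    the unshrunk Gaussian blocks (Xi diagonals, warp parameters, factor
    coefficients).
    """

    n_iter: int = 6000
    n_burnin: int = 3000
    K: int = 10
    K1: int | None = None
    K2: int | None = None
    J: int | None = None
    r_init: int | None = None
    r1_init: int | None = None
    r2_init: int | None = None
    prune_threshold: float = 1e-3
    nu: float = 3.0  # local shrinkage Gamma(nu, nu)
    delta_shape1: float = 5.0  # MGP first-column shape
    delta_shape2: float = 5.0  # MGP later-column shape; larger = stronger shrinkage
    sigma_shape: float = 0.1  # noise precision Gamma(shape, rate)
    sigma_rate: float = 0.1
    omega: float = 100.0
    leapfrog_steps: int = 30
    adapt_interval: int = 100
    accept_band: tuple[float, float] = (0.6, 0.8)
    warm_start_warp: bool = True
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter < 0 or self.n_burnin < 0:
            raise ValueError("iteration counts must be non-negative")
        if self.n_iter > 0 and not self.n_burnin < self.n_iter:
            raise ValueError("need n_burnin < n_iter")
        if self.prune_threshold <= 0:
            raise ValueError("prune_threshold must be positive")

    def bases(self, degree: int = 3) -> ModelBases:
        return ModelBases.tied(self.K, self.K1, self.K2, self.J, degree)


@dataclass
class Chain:
    """Post burn-in draws plus sampling diagnostics."""

    states: list[ModelState]
    rank_history: np.ndarray  # n_iter x 3 columns (r, r1, r2)
    accept_history: dict[str, list[float]]  # per adaptation window
    prune_events: list[tuple[int, str, int]]  # (iteration, block, n_removed)
    config: SamplerConfig
    bases: ModelBases
    t: np.ndarray
    data: PairedSeries | None = None

    def __len__(self) -> int:
        return len(self.states)

    _FIELDS = ("Lambda", "Gamma1", "Gamma2", "Xi1", "Xi2", "beta_shared",
               "beta_ind1", "beta_ind2", "kappa", "sigma1_sq", "sigma2_sq")

    def save(self, path) -> None:
        """Columnar on-disk layout: one array per unknown per draw, plus a
        JSON manifest with the config, seed and pruning history."""
        import json
        from pathlib import Path

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        arrays: dict[str, np.ndarray] = {"rank_history": self.rank_history, "t": self.t}
        if self.data is not None:
            arrays["X"], arrays["Y"] = self.data.X, self.data.Y
        for i, s in enumerate(self.states):
            vals = (s.loadings.Lambda, s.loadings.Gamma1, s.loadings.Gamma2,
                    s.loadings.Xi1, s.loadings.Xi2, s.coeffs.beta_shared,
                    s.coeffs.beta_ind1, s.coeffs.beta_ind2, s.warp.kappa,
                    s.noise.sigma1_sq, s.noise.sigma2_sq)
            for name, v in zip(self._FIELDS, vals):
                arrays[f"{name}_{i}"] = v
        np.savez_compressed(path / "chain.npz", **arrays)
        manifest = {
            "n_states": len(self.states),
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in dataclass_asdict(self.config).items()},
            "seed": self.config.seed,
            "accept_history": self.accept_history,
            "prune_events": [list(e) for e in self.prune_events],
            "has_data": self.data is not None,
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @staticmethod
    def load(path) -> "Chain":
        import json
        from pathlib import Path

        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        npz = np.load(path / "chain.npz")
        cfg_dict = dict(manifest["config"])
        cfg_dict["accept_band"] = tuple(cfg_dict["accept_band"])
        config = SamplerConfig(**cfg_dict)
        states = []
        for i in range(manifest["n_states"]):
            v = {name: npz[f"{name}_{i}"] for name in Chain._FIELDS}
            states.append(ModelState(
                loadings=LoadingSet(v["Lambda"], v["Gamma1"], v["Gamma2"],
                                    v["Xi1"], v["Xi2"]),
                coeffs=FactorCoeffs(v["beta_shared"], v["beta_ind1"], v["beta_ind2"]),
                warp=WarpSpec(v["kappa"]),
                noise=NoiseState(v["sigma1_sq"], v["sigma2_sq"]),
            ))
        data = None
        if manifest.get("has_data"):
            data = PairedSeries(npz["X"], npz["Y"], npz["t"])
        return Chain(
            states=states,
            rank_history=npz["rank_history"],
            accept_history=manifest["accept_history"],
            prune_events=[tuple(e) for e in manifest["prune_events"]],
            config=config,
            bases=config.bases(),
            t=npz["t"],
            data=data,
        )


# --------------------------------------------------------------------------
# small numerical helpers


def _draw_gaussian_prec(rng: np.random.Generator, prec: np.ndarray, lin: np.ndarray) -> np.ndarray:
    """Draw from N(prec^{-1} lin, prec^{-1}) via Cholesky of the precision."""
    L = np.linalg.cholesky(prec)
    mean = cho_solve((L, True), lin)
    z = rng.standard_normal(lin.shape[0])
    return mean + solve_triangular(L, z, trans="T", lower=True)


def adapt_step_size(step: float, rate: float, band: tuple[float, float] = (0.6, 0.8)) -> float:
    """Windowed multiplicative step-size rule.

    Below the band the step shrinks (x0.8, or x0.5 when acceptance has
    collapsed below 0.2); above it grows (x1.25, or x2 when acceptance is
    essentially 1); inside the band it is left alone.
    """
    lo, hi = band
    if rate < lo:
        return step * (0.5 if rate < 0.2 else 0.8)
    if rate > hi:
        return step * (2.0 if rate > 0.95 else 1.25)
    return step


def psi_block_decomposition(Lambda: np.ndarray, j: int) -> np.ndarray:
    """Psi written as (1-P1)(1-P2)(1-P1) isolating column j.

    P1 projects onto the span of the other columns and P2 onto the part
    of column j orthogonal to them; the product reproduces the full
    projector I - Lambda (Lambda'Lambda)^{-1} Lambda'.
    """
    p = Lambda.shape[0]
    rest = np.delete(Lambda, j, axis=1)
    col = Lambda[:, j : j + 1]
    if rest.shape[1]:
        P1 = rest @ np.linalg.solve(rest.T @ rest, rest.T)
    else:
        P1 = np.zeros((p, p))
    Q1 = np.eye(p) - P1
    denom = (col.T @ Q1 @ col).item()
    P2 = (col @ col.T) / denom
    return Q1 @ (np.eye(p) - P2) @ Q1


# --------------------------------------------------------------------------
# the sampler


class TacifaSampler:
    """Mutable sampling engine behind :func:`run_mcmc`.

    Holds the current state as plain arrays plus cached design matrices;
    exposes the individual update blocks so they can be exercised (and
    their gradients finite-difference checked) in isolation.
    """

    def __init__(
        self,
        data: PairedSeries,
        config: SamplerConfig,
        rng: np.random.Generator | None = None,
        state: ModelState | None = None,
    ) -> None:
        self.data = data
        self.config = config
        self.rng = rng if rng is not None else np.random.default_rng(config.seed)
        self.bases = config.bases()
        self.X, self.Y, self.t = data.X, data.Y, data.t
        self.p, self.T = data.p, data.T

        # fixed design matrices
        self.Bt = self.bases.shared.design(self.t)  # T x K
        self.B1t = self.bases.ind1.design(self.t)  # T x K1
        self.B2t = self.bases.ind2.design(self.t)  # T x K2
        self.Bw = self.bases.warp.design(self.t)  # T x J
        # suffix sums sum_{l>=j} B_l(t) for j = 2..J (kappa indices)
        Sw = np.cumsum(self.Bw[:, ::-1], axis=1)[:, ::-1]
        self.Sw = Sw[:, 1:]  # T x (J-1)

        fresh = state is None
        if fresh:
            self._default_init()
        else:
            self._init_from_state(state)
        self._refresh_psi()
        self._refresh_warp()
        self._refresh_factors()
        if fresh and config.warm_start_warp:
            self._warm_start_warp()

        self.settings = HMCSettings(
            leapfrog_steps=config.leapfrog_steps,
            step_size_kappa=0.0,
            step_size_lambda=np.zeros(self.r),
            target_accept_band=config.accept_band,
            adapt_interval=config.adapt_interval,
        )
        self._init_step_sizes()
        self._reset_accept_counters()
        self.accept_history: dict[str, list[float]] = {"kappa": [], "lambda": []}
        self.prune_events: list[tuple[int, str, int]] = []
        self._in_burnin = True

    # -- initialization ----------------------------------------------------

    @property
    def r(self) -> int:
        return self.Lambda.shape[1]

    @property
    def r1(self) -> int:
        return self.Gamma1.shape[1]

    @property
    def r2(self) -> int:
        return self.Gamma2.shape[1]

    def _default_init(self) -> None:
        cfg, rng = self.config, self.rng
        p, T = self.p, self.T
        r = cfg.r_init or p
        r1 = cfg.r1_init or p
        r2 = cfg.r2_init or p
        K, K1, K2 = self.Bt.shape[1], self.B1t.shape[1], self.B2t.shape[1]
        J = self.Bw.shape[1]

        # Shared loadings from an SVD of the first series: X ~ U S V', so
        # Lambda = U S reproduces X with unit-norm factor rows V'.  This
        # starts the chain near the dominant subspace; surplus columns
        # carry only noise-level energy and are shrunk away by the prior.
        U, s, Vt = np.linalg.svd(self.X, full_matrices=False)
        k = min(r, min(p, T))
        # Only components whose singular values clear a noise floor carry
        # identifiable structure; the rest of the conservative r = p columns
        # start at prior scale so the shrinkage prior can retire them
        # immediately instead of first having to squash noise-level energy.
        med = np.median(s[:k]) if k else 0.0
        informative = (s[:k] > 1.25 * med) & (s[:k] > 1e-8 * max(s[0] if k else 0.0, 1.0))
        self.Lambda = rng.normal(0.0, 0.01, (p, r))
        self.Lambda[:, :k][:, informative] = (U[:, :k] * s[:k])[:, informative]
        self.xi1 = np.ones(r)
        self.xi2 = np.ones(r)

        ridge = self.Bt.T @ self.Bt + 1e-6 * np.eye(K)
        self.beta = np.zeros((r, K))
        fit = np.linalg.solve(ridge, self.Bt.T @ Vt[:k].T).T
        self.beta[:k][informative] = fit[informative]

        self.Gamma1 = rng.normal(0.0, 0.1, (p, r1))
        self.Gamma2 = rng.normal(0.0, 0.1, (p, r2))
        self.beta1 = np.zeros((r1, K1))
        self.beta2 = np.zeros((r2, K2))

        # A shared factor must carry signal in both series.  Components of
        # the X-decomposition with (essentially) no energy in Y are
        # first-series-specific: start them in the individual space, not
        # in Lambda, so the sampler does not have to migrate them across
        # the orthogonality constraint later.
        ridge1 = self.B1t.T @ self.B1t + 1e-6 * np.eye(K1)
        slot = 0
        for kcol in range(k):
            if not informative[kcol]:
                continue
            u = self.Lambda[:, kcol]
            nrm = np.linalg.norm(u)
            if nrm < 1e-12:
                continue
            u = u / nrm
            ex = np.var(u @ self.X)
            ey = np.var(u @ self.Y)
            if ey < 0.05 * ex and slot < r1:
                self.Gamma1[:, slot] = self.Lambda[:, kcol]
                self.beta1[slot] = np.linalg.solve(ridge1, self.B1t.T @ (u @ self.X)) / nrm
                slot += 1
                self.Lambda[:, kcol] = rng.normal(0.0, 0.01, p)
                self.beta[kcol] = 0.0

        self.kappa = WarpSpec.identity(self.bases.warp).kappa.copy()

        self.phi1 = np.ones((p, r))
        self.phi11 = np.ones((p, r1))
        self.phi12 = np.ones((p, r2))
        self.delta1 = np.ones(r)
        self.delta11 = np.ones(r1)
        self.delta12 = np.ones(r2)

        # initial noise floors are relative to the overall data scale so a
        # constant (e.g. exactly-zero) feature cannot get a near-infinite
        # weight before the first conjugate variance update
        resid1 = self.X - self.Lambda @ (self.beta @ self.Bt.T)
        v1 = resid1.var(axis=1)
        v2 = self.Y.var(axis=1)
        self.s1sq = np.maximum(v1, 1e-4 * v1.mean() + 1e-12)
        self.s2sq = np.maximum(v2, 1e-4 * v2.mean() + 1e-12)

    def _init_from_state(self, state: ModelState) -> None:
        L, c = state.loadings, state.coeffs
        self.Lambda = L.Lambda.copy()
        self.Gamma1 = L.Gamma1.copy()
        self.Gamma2 = L.Gamma2.copy()
        self.xi1 = L.Xi1.copy()
        self.xi2 = L.Xi2.copy()
        self.beta = c.beta_shared.copy()
        self.beta1 = c.beta_ind1.copy()
        self.beta2 = c.beta_ind2.copy()
        self.kappa = state.warp.kappa.copy()
        self.s1sq = state.noise.sigma1_sq.copy()
        self.s2sq = state.noise.sigma2_sq.copy()
        sh = state.shrinkage
        if sh is not None:
            self.phi1, self.phi11, self.phi12 = sh.phi1.copy(), sh.phi11.copy(), sh.phi12.copy()
            self.delta1, self.delta11, self.delta12 = (
                sh.delta1.copy(), sh.delta11.copy(), sh.delta12.copy())
        else:
            self.phi1 = np.ones_like(self.Lambda)
            self.phi11 = np.ones_like(self.Gamma1)
            self.phi12 = np.ones_like(self.Gamma2)
            self.delta1 = np.ones(self.Lambda.shape[1])
            self.delta11 = np.ones(self.Gamma1.shape[1])
            self.delta12 = np.ones(self.Gamma2.shape[1])

    def _warm_start_warp(self) -> None:
        """Deterministic warm start of the warp parameters.

        A short quasi-Newton minimization of the warp potential at the
        initial state.  At initialization the individual space is inert,
        so the second series' misfit is carried entirely by the warped
        shared curves and the warp gradient is maximally informative;
        starting the chain near that optimum keeps the warp from being
        crowded out by the (conjugate, fast-adapting) individual blocks.
        """
        from scipy.optimize import minimize

        res = minimize(
            self.kappa_potential_grad,
            self.kappa,
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 80},
        )
        if np.all(np.isfinite(res.x)):
            self.kappa = res.x
            self._refresh_warp()

    # -- cache refreshes ---------------------------------------------------

    def _refresh_psi(self) -> None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            self.Psi = projection(self.Lambda)

    def _refresh_warp(self) -> None:
        gamma = gamma_from_kappa(self.kappa)
        self.M = np.clip(self.Bw @ gamma, 0.0, 1.0)
        self.BM = self.bases.shared.design(self.M)
        self.eta_M = self.beta @ self.BM.T

    def _refresh_factors(self) -> None:
        self.eta = self.beta @ self.Bt.T
        self.eta_M = self.beta @ self.BM.T
        self.zeta1 = self.beta1 @ self.B1t.T
        self.zeta2 = self.beta2 @ self.B2t.T

    @property
    def tau1(self) -> np.ndarray:
        return np.cumprod(self.delta1)

    @property
    def tau11(self) -> np.ndarray:
        return np.cumprod(self.delta11)

    @property
    def tau12(self) -> np.ndarray:
        return np.cumprod(self.delta12)

    def snapshot(self) -> ModelState:
        """Freeze the current state into an immutable ModelState."""
        return ModelState(
            loadings=LoadingSet(self.Lambda.copy(), self.Gamma1.copy(), self.Gamma2.copy(),
                                self.xi1.copy(), self.xi2.copy()),
            coeffs=FactorCoeffs(self.beta.copy(), self.beta1.copy(), self.beta2.copy()),
            warp=WarpSpec(self.kappa.copy()),
            noise=NoiseState(self.s1sq.copy(), self.s2sq.copy()),
            shrinkage=ShrinkageState(self.phi1.copy(), self.phi11.copy(), self.phi12.copy(),
                                     self.delta1.copy(), self.delta11.copy(), self.delta12.copy()),
        )

    # -- conjugate Gibbs blocks -------------------------------------------

    def beta_shared_conditional(self):
        """Precision matrix and linear term of vec_F(beta_shared)."""
        w1 = 1.0 / self.s1sq
        w2 = 1.0 / self.s2sq
        A1 = self.Lambda * self.xi1[None, :]
        A2 = self.Lambda * self.xi2[None, :]
        Xt = self.X - self.Psi @ (self.Gamma1 @ self.zeta1)
        Yt = self.Y - self.Psi @ (self.Gamma2 @ self.zeta2)
        K = self.Bt.shape[1]
        prec = (
            np.kron(self.Bt.T @ self.Bt, A1.T @ (w1[:, None] * A1))
            + np.kron(self.BM.T @ self.BM, A2.T @ (w2[:, None] * A2))
        )
        prec[np.diag_indices_from(prec)] += 1.0 / self.config.omega
        lin = (A1.T @ (w1[:, None] * Xt) @ self.Bt).ravel(order="F") + (
            A2.T @ (w2[:, None] * Yt) @ self.BM
        ).ravel(order="F")
        return prec, lin

    def update_beta_shared(self) -> None:
        prec, lin = self.beta_shared_conditional()
        draw = _draw_gaussian_prec(self.rng, prec, lin)
        self.beta = draw.reshape(self.r, -1, order="F")
        self.eta = self.beta @ self.Bt.T
        self.eta_M = self.beta @ self.BM.T

    def _beta_ind_conditional(self, which: int):
        if which == 1:
            A = self.Psi @ self.Gamma1
            B = self.B1t
            resid = self.X - self.Lambda @ (self.xi1[:, None] * self.eta)
            w = 1.0 / self.s1sq
        else:
            A = self.Psi @ self.Gamma2
            B = self.B2t
            resid = self.Y - self.Lambda @ (self.xi2[:, None] * self.eta_M)
            w = 1.0 / self.s2sq
        prec = np.kron(B.T @ B, A.T @ (w[:, None] * A))
        prec[np.diag_indices_from(prec)] += 1.0 / self.config.omega
        lin = (A.T @ (w[:, None] * resid) @ B).ravel(order="F")
        return prec, lin

    def update_beta_ind(self, which: int) -> None:
        prec, lin = self._beta_ind_conditional(which)
        draw = _draw_gaussian_prec(self.rng, prec, lin)
        if which == 1:
            self.beta1 = draw.reshape(self.r1, -1, order="F")
            self.zeta1 = self.beta1 @ self.B1t.T
        else:
            self.beta2 = draw.reshape(self.r2, -1, order="F")
            self.zeta2 = self.beta2 @ self.B2t.T

    def update_gamma(self, which: int) -> None:
        """Column-wise Gaussian full conditionals for Gamma1 or Gamma2."""
        if which == 1:
            Gamma, zeta, phi, tau = self.Gamma1, self.zeta1, self.phi11, self.tau11
            resid0 = self.X - self.Lambda @ (self.xi1[:, None] * self.eta)
            w = 1.0 / self.s1sq
        else:
            Gamma, zeta, phi, tau = self.Gamma2, self.zeta2, self.phi12, self.tau12
            resid0 = self.Y - self.Lambda @ (self.xi2[:, None] * self.eta_M)
            w = 1.0 / self.s2sq
        Psi = self.Psi
        PsiW = Psi.T * w[None, :]  # Psi' W
        PsiWPsi = PsiW @ Psi
        PU = Psi @ (Gamma @ zeta)
        for k in range(Gamma.shape[1]):
            zk = zeta[k]
            PU -= np.outer(Psi @ Gamma[:, k], zk)
            Rk = resid0 - PU
            prec = (zk @ zk) * PsiWPsi
            prec[np.diag_indices_from(prec)] += phi[:, k] * tau[k]
            lin = PsiW @ Rk @ zk
            Gamma[:, k] = _draw_gaussian_prec(self.rng, prec, lin)
            PU += np.outer(Psi @ Gamma[:, k], zk)

    def update_xi(self, which: int) -> None:
        """Joint Gaussian full conditional of a diagonal scale Xi."""
        if which == 1:
            H = self.eta
            resid = self.X - self.Psi @ (self.Gamma1 @ self.zeta1)
            w = 1.0 / self.s1sq
        else:
            H = self.eta_M
            resid = self.Y - self.Psi @ (self.Gamma2 @ self.zeta2)
            w = 1.0 / self.s2sq
        LW = self.Lambda.T @ (w[:, None] * self.Lambda)  # r x r
        prec = LW * (H @ H.T)
        prec[np.diag_indices_from(prec)] += 1.0 / self.config.omega
        lin = (((w[:, None] * self.Lambda).T @ resid) * H).sum(axis=1)
        draw = _draw_gaussian_prec(self.rng, prec, lin)
        if which == 1:
            self.xi1 = draw
        else:
            self.xi2 = draw

    def update_linear_blocks(self) -> None:
        self.update_beta_shared()
        # While r = p the projector is null and the individual space has no
        # likelihood involvement; its conditionals degenerate to the prior.
        # Skipping the draws (a valid partial sweep) preserves the
        # data-informed initialization of Gamma until pruning frees Psi.
        if np.trace(self.Psi) > 1e-8:
            self.update_beta_ind(1)
            self.update_beta_ind(2)
            self.update_gamma(1)
            self.update_gamma(2)
        self.update_xi(1)
        self.update_xi(2)

    def residuals(self):
        R1 = (self.X - self.Psi @ (self.Gamma1 @ self.zeta1)
              - self.Lambda @ (self.xi1[:, None] * self.eta))
        R2 = (self.Y - self.Psi @ (self.Gamma2 @ self.zeta2)
              - self.Lambda @ (self.xi2[:, None] * self.eta_M))
        return R1, R2

    def update_sigma(self) -> None:
        cfg = self.config
        R1, R2 = self.residuals()
        shape = cfg.sigma_shape + 0.5 * self.T
        rate1 = cfg.sigma_rate + 0.5 * (R1**2).sum(axis=1)
        rate2 = cfg.sigma_rate + 0.5 * (R2**2).sum(axis=1)
        self.s1sq = 1.0 / self.rng.gamma(shape, 1.0 / rate1)
        self.s2sq = 1.0 / self.rng.gamma(shape, 1.0 / rate2)

    def _update_mgp_block(self, mat, phi, delta):
        """Shared machinery for one multiplicative-gamma shrinkage block."""
        cfg, rng = self.config, self.rng
        p, r = mat.shape
        tau = np.cumprod(delta)
        phi[:] = rng.gamma(cfg.nu + 0.5, 1.0 / (cfg.nu + 0.5 * tau[None, :] * mat**2))
        col_ss = (phi * mat**2).sum(axis=0)  # sum_l phi_lk M_lk^2 per column
        for h in range(r):
            tau = np.cumprod(delta)
            tau_minus = tau[h:] / delta[h]
            shape = (cfg.delta_shape1 if h == 0 else cfg.delta_shape2) + 0.5 * p * (r - h)
            rate = 1.0 + 0.5 * (tau_minus * col_ss[h:]).sum()
            delta[h] = rng.gamma(shape, 1.0 / rate)

    def update_shrinkage(self) -> None:
        self._update_mgp_block(self.Lambda, self.phi1, self.delta1)
        self._update_mgp_block(self.Gamma1, self.phi11, self.delta11)
        self._update_mgp_block(self.Gamma2, self.phi12, self.delta12)

    # -- HMC: warp parameters ----------------------------------------------

    def kappa_potential(self, kappa: np.ndarray) -> float:
        gamma = gamma_from_kappa(kappa)
        M = np.clip(self.Bw @ gamma, 0.0, 1.0)
        eta_M = self.beta @ self.bases.shared.design(M).T
        R = (self.Y - self.Psi @ (self.Gamma2 @ self.zeta2)
             - self.Lambda @ (self.xi2[:, None] * eta_M))
        w2 = 1.0 / self.s2sq
        return float(0.5 * (w2[:, None] * R**2).sum() + 0.5 * (kappa**2).sum() / self.config.omega)

    def kappa_potential_grad(self, kappa: np.ndarray):
        """Potential and gradient for the warp-parameter HMC update.

        The gradient runs the chain rule through the warped factor curves:
        dU/dkappa_j = -sum_t d_t w_j [S_j(t) - M(t)] + kappa_j / omega with
        d_t the weighted residual contracted with Lambda Xi2 eta'(M(t)),
        w the softmax weights and S_j the suffix sum of warp bases.
        """
        shifted = kappa - kappa.max()
        wts = np.exp(shifted)
        wts /= wts.sum()
        cum = np.cumsum(wts)
        cum /= cum[-1]
        gamma = np.concatenate([[0.0], cum])
        gamma[-1] = 1.0
        M = np.clip(self.Bw @ gamma, 0.0, 1.0)
        BM = self.bases.shared.design(M)
        dBM = self.bases.shared.design_derivative(M)
        eta_M = self.beta @ BM.T
        deta_M = self.beta @ dBM.T
        A2 = self.Lambda * self.xi2[None, :]
        R = self.Y - self.Psi @ (self.Gamma2 @ self.zeta2) - A2 @ eta_M
        w2 = 1.0 / self.s2sq
        U = 0.5 * (w2[:, None] * R**2).sum() + 0.5 * (kappa**2).sum() / self.config.omega
        d_t = ((w2[:, None] * R) * (A2 @ deta_M)).sum(axis=0)  # length T
        # dM(t)/dkappa_j = w_j (S_j(t) - M(t))
        grad = -(d_t[:, None] * (self.Sw - M[:, None]) * wts[None, :]).sum(axis=0)
        grad += kappa / self.config.omega
        return float(U), grad

    def hmc_kappa(self) -> bool:
        eps = self.settings.step_size_kappa
        nstep = self.settings.leapfrog_steps
        q0 = self.kappa.copy()
        U0, g = self.kappa_potential_grad(q0)
        if eps == 0.0:
            self._accept["kappa"][1] += 1
            self._accept["kappa"][0] += 1
            return True
        mom = self.rng.standard_normal(q0.size)
        H0 = U0 + 0.5 * mom @ mom
        q = q0.copy()
        ok = True
        with np.errstate(over="ignore", invalid="ignore"):
            for _ in range(nstep):
                mom = mom - 0.5 * eps * g
                q = q + eps * mom
                U, g = self.kappa_potential_grad(q)
                if not (np.isfinite(U) and np.all(np.isfinite(g))):
                    ok = False
                    break
                mom = mom - 0.5 * eps * g
        if not ok:
            if self._in_burnin:  # divergent trajectory: emergency brake
                self.settings.step_size_kappa *= 0.5
            else:
                warnings.warn("non-finite warp HMC trajectory; rejecting", RuntimeWarning)
        accept = False
        if ok:
            H1 = U + 0.5 * mom @ mom
            accept = math.log(self.rng.uniform()) < H0 - H1
        if accept:
            self.kappa = q
            self._refresh_warp()
        self._accept["kappa"][1] += 1
        self._accept["kappa"][0] += int(accept)
        return accept

    # -- HMC: shared loading columns ----------------------------------------

    def lambda_potential(self, j: int, lam: np.ndarray) -> float:
        Lam = self.Lambda.copy()
        Lam[:, j] = lam
        Psi = np.eye(self.p) - Lam @ np.linalg.solve(Lam.T @ Lam, Lam.T)
        R1 = self.X - Psi @ self._Z1U - Lam @ (self.xi1[:, None] * self.eta)
        R2 = self.Y - Psi @ self._Z2U - Lam @ (self.xi2[:, None] * self.eta_M)
        w1, w2 = 1.0 / self.s1sq, 1.0 / self.s2sq
        prior_prec = self.phi1[:, j] * self.tau1[j]
        return float(
            0.5 * (w1[:, None] * R1**2).sum()
            + 0.5 * (w2[:, None] * R2**2).sum()
            + 0.5 * (prior_prec * lam**2).sum()
        )

    def lambda_potential_grad(self, j: int, lam: np.ndarray):
        """Potential and analytic gradient for one Lambda column.

        Differentiates both the direct shared-mean dependence and the
        dependence through the projector Psi (via dPsi = -(Psi e_k a_j' +
        a_j e_k' Psi) for a_j the j-th column of Lambda (Lambda'Lambda)^{-1}).
        """
        Lam = self.Lambda.copy()
        Lam[:, j] = lam
        G = Lam.T @ Lam
        try:
            cho = cho_factor(G)
            LamGinv = cho_solve(cho, Lam.T).T  # p x r: Lambda (Lambda'Lambda)^{-1}
        except np.linalg.LinAlgError:
            LamGinv = (np.linalg.pinv(G) @ Lam.T).T
        Psi = np.eye(self.p) - LamGinv @ Lam.T
        a = LamGinv[:, j]
        w1, w2 = 1.0 / self.s1sq, 1.0 / self.s2sq
        R1 = self.X - Psi @ self._Z1U - Lam @ (self.xi1[:, None] * self.eta)
        R2 = self.Y - Psi @ self._Z2U - Lam @ (self.xi2[:, None] * self.eta_M)
        G1 = w1[:, None] * R1
        G2 = w2[:, None] * R2
        prior_prec = self.phi1[:, j] * self.tau1[j]
        U = float(0.5 * (G1 * R1).sum() + 0.5 * (G2 * R2).sum()
                  + 0.5 * (prior_prec * lam**2).sum())
        S = G1 @ self._Z1U.T + G2 @ self._Z2U.T
        grad = (
            -self.xi1[j] * (G1 @ self.eta[j])
            - self.xi2[j] * (G2 @ self.eta_M[j])
            + Psi @ ((S + S.T) @ a)
            + prior_prec * lam
        )
        return U, grad

    def _lambda_caches(self) -> None:
        self._Z1U = self.Gamma1 @ self.zeta1
        self._Z2U = self.Gamma2 @ self.zeta2

    def _lambda_scale(self, j: int) -> np.ndarray:
        """Per-entry preconditioning scale for the column-j HMC update.

        The inverse square root of (prior precision + direct likelihood
        curvature); as the shrinkage prior tightens a column, the scale
        contracts with it so the leapfrog keeps mixing at every
        magnitude instead of stalling on near-pruned columns.
        """
        prior_prec = self.phi1[:, j] * self.tau1[j]
        curv = (self.xi1[j] ** 2 * (self.eta[j] ** 2).sum()) / self.s1sq + (
            self.xi2[j] ** 2 * (self.eta_M[j] ** 2).sum()
        ) / self.s2sq
        # Gauss-Newton diagonal of the projector path: the mean moves by
        # -(Psi e_k a' + a e_k' Psi) U per unit of lambda_kj, with a the
        # j-th column of Lambda (Lambda'Lambda)^{-1}
        G = self.Lambda.T @ self.Lambda
        try:
            a = self.Lambda @ np.linalg.solve(G, np.eye(self.r)[:, j])
        except np.linalg.LinAlgError:
            a = self.Lambda @ np.linalg.pinv(G)[:, j]
        Psi2 = self.Psi**2
        for U, w in ((self._Z1U, 1.0 / self.s1sq), (self._Z2U, 1.0 / self.s2sq)):
            PU = self.Psi @ U
            u = a @ U  # length T
            curv = curv + (u @ u) * (w @ Psi2)
            curv = curv + 2.0 * (self.Psi.T @ (w * a)) * (PU @ u)
            curv = curv + (w @ a**2) * (PU**2).sum(axis=1)
        return 1.0 / np.sqrt(np.maximum(prior_prec + curv, 0.0) + 1e-12)

    def hmc_lambda_column(self, j: int) -> bool:
        rest = np.delete(self.Lambda, j, axis=1)
        if rest.shape[1]:
            if np.linalg.svd(rest, compute_uv=False).min() <= 1e-10:
                warnings.warn(
                    f"Lambda without column {j} is rank deficient; skipping update",
                    RuntimeWarning,
                )
                return False
        eps = float(self.settings.step_size_lambda[j])
        nstep = self.settings.leapfrog_steps
        q0 = self.Lambda[:, j].copy()
        U0, g = self.lambda_potential_grad(j, q0)
        if eps == 0.0:
            self._accept_lambda[j] += (1, 1)
            return True
        sc = self._lambda_scale(j)  # fixed during the trajectory
        mom = self.rng.standard_normal(self.p)
        H0 = U0 + 0.5 * mom @ mom
        q = q0.copy()
        ok = True
        with np.errstate(over="ignore", invalid="ignore"):
            for _ in range(nstep):
                mom = mom - 0.5 * eps * sc * g
                q = q + eps * sc * mom
                U, g = self.lambda_potential_grad(j, q)
                if not (np.isfinite(U) and np.all(np.isfinite(g))):
                    ok = False
                    break
                mom = mom - 0.5 * eps * sc * g
        if not ok and self._in_burnin:
            self.settings.step_size_lambda[j] *= 0.5
        accept = False
        if ok:
            H1 = U + 0.5 * mom @ mom
            accept = math.log(self.rng.uniform()) < H0 - H1
        if accept:
            self.Lambda[:, j] = q
            self._refresh_psi()
        self._accept_lambda[j] += (int(accept), 1)
        return accept

    def hmc_lambda_all(self) -> None:
        self._lambda_caches()
        for j in range(self.r):
            self.hmc_lambda_column(j)

    def rescale_columns(self, sd: float = 0.7) -> None:
        """Likelihood-invariant scale move on each (Lambda_j, Xi1_j, Xi2_j).

        The model only identifies the product Lambda_j Xi_j, so a column
        can sit far from its prior scale while the product is pinned by
        the data.  Proposing lambda -> c lambda, xi -> xi / c (Jacobian
        c^(p-2)) and accepting on the prior ratio lets shrunk columns
        slide down to the scale where pruning recognizes them, without
        changing any fitted mean.
        """
        omega = self.config.omega
        tau = self.tau1
        for j in range(self.r):
            c = math.exp(sd * self.rng.standard_normal())
            lam = self.Lambda[:, j]
            quad = (self.phi1[:, j] * lam**2).sum() * tau[j]
            xi_sq = self.xi1[j] ** 2 + self.xi2[j] ** 2
            log_r = (
                -0.5 * quad * (c**2 - 1.0)
                - 0.5 * xi_sq * (1.0 / c**2 - 1.0) / omega
                + (self.p - 2) * math.log(c)
            )
            if math.log(self.rng.uniform()) < log_r:
                self.Lambda[:, j] = lam * c
                self.xi1[j] /= c
                self.xi2[j] /= c
        self._refresh_psi()

    # -- step sizes ----------------------------------------------------------

    def _reset_accept_counters(self) -> None:
        self._accept = {"kappa": [0, 0]}
        self._accept_lambda = np.zeros((self.r, 2))

    def _find_step_size(self, pot_grad, q0: np.ndarray, eps: float = 0.1,
                        scale: np.ndarray | float = 1.0) -> float:
        """Crude bracketing of a step size with one-step acceptance in (0.5, 0.95)."""
        U0, g0 = pot_grad(q0)
        for _ in range(60):
            mom = -0.5 * eps * scale * g0  # one-step probe from zero initial momentum
            q = q0 + eps * scale * mom
            with np.errstate(over="ignore", invalid="ignore"):
                U1, _ = pot_grad(q)
            if np.isfinite(U1):
                H1 = U1 + 0.5 * mom @ mom
                a = math.exp(min(0.0, U0 - H1))
            else:
                a = 0.0
            if a < 0.5:
                eps *= 0.5
            elif a > 0.95:
                eps *= 2.0
            else:
                break
        # a single probe step understates the error accumulated over a full
        # trajectory; start conservatively and let windowed adaptation raise it
        return max(0.3 * eps, 1e-12)

    def _init_step_sizes(self) -> None:
        self._lambda_caches()
        self.settings.step_size_kappa = self._find_step_size(
            self.kappa_potential_grad, self.kappa
        )
        steps = np.empty(self.r)
        for j in range(self.r):
            steps[j] = self._find_step_size(
                lambda q, jj=j: self.lambda_potential_grad(jj, q),
                self.Lambda[:, j].copy(),
                eps=0.5,
                scale=self._lambda_scale(j),
            )
        self.settings.step_size_lambda = steps

    def adapt(self) -> None:
        band = self.settings.target_accept_band
        acc, tot = self._accept["kappa"]
        if tot:
            rate = acc / tot
            self.accept_history["kappa"].append(rate)
            self.settings.step_size_kappa = adapt_step_size(
                self.settings.step_size_kappa, rate, band
            )
        if self._accept_lambda[:, 1].sum():
            rates = self._accept_lambda[:, 0] / np.maximum(self._accept_lambda[:, 1], 1)
            self.accept_history["lambda"].append(float(rates.mean()))
            self.settings.step_size_lambda = np.array(
                [adapt_step_size(s, rate, band)
                 for s, rate in zip(self.settings.step_size_lambda, rates)]
            )
        self._reset_accept_counters()

    # -- pruning ---------------------------------------------------------------

    def _prunable(self, mat: np.ndarray) -> np.ndarray:
        """Indices of columns with every entry within the prune threshold."""
        small = np.abs(mat).max(axis=0) < self.config.prune_threshold
        if small.all():  # never drop below rank 1: keep the largest column
            small[np.abs(mat).max(axis=0).argmax()] = False
        return np.flatnonzero(small)

    def prune(self, iteration: int) -> None:
        drop = self._prunable(self.Lambda)
        if drop.size:
            keep = np.setdiff1d(np.arange(self.r), drop)
            self.Lambda = self.Lambda[:, keep]
            self.xi1 = self.xi1[keep]
            self.xi2 = self.xi2[keep]
            self.beta = self.beta[keep]
            self.phi1 = self.phi1[:, keep]
            self.delta1 = self.delta1[keep]
            self.settings.step_size_lambda = self.settings.step_size_lambda[keep]
            self._accept_lambda = self._accept_lambda[keep]
            self._refresh_psi()
            self.eta = self.beta @ self.Bt.T
            self.eta_M = self.beta @ self.BM.T
            self.prune_events.append((iteration, "Lambda", drop.size))
        drop = self._prunable(self.Gamma1)
        if drop.size:
            keep = np.setdiff1d(np.arange(self.r1), drop)
            self.Gamma1 = self.Gamma1[:, keep]
            self.beta1 = self.beta1[keep]
            self.phi11 = self.phi11[:, keep]
            self.delta11 = self.delta11[keep]
            self.zeta1 = self.beta1 @ self.B1t.T
            self.prune_events.append((iteration, "Gamma1", drop.size))
        drop = self._prunable(self.Gamma2)
        if drop.size:
            keep = np.setdiff1d(np.arange(self.r2), drop)
            self.Gamma2 = self.Gamma2[:, keep]
            self.beta2 = self.beta2[keep]
            self.phi12 = self.phi12[:, keep]
            self.delta12 = self.delta12[keep]
            self.zeta2 = self.beta2 @ self.B2t.T
            self.prune_events.append((iteration, "Gamma2", drop.size))

    # -- main loop ---------------------------------------------------------------

    def _check_finite(self, iteration: int) -> None:
        for name in ("Lambda", "Gamma1", "Gamma2", "beta", "kappa", "s1sq", "s2sq"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                raise RuntimeError(
                    f"sampler diverged at iteration {iteration}: non-finite {name}; "
                    f"ranks=({self.r},{self.r1},{self.r2}), "
                    f"steps=(kappa={self.settings.step_size_kappa:.3g})"
                )

    def run(self) -> Chain:
        cfg = self.config
        states: list[ModelState] = []
        ranks = np.zeros((cfg.n_iter, 3), dtype=int)
        for it in range(1, cfg.n_iter + 1):
            self._in_burnin = it <= cfg.n_burnin
            self.update_linear_blocks()
            self.update_sigma()
            self.update_shrinkage()
            self.hmc_lambda_all()
            self.rescale_columns()
            self.hmc_kappa()
            if it <= cfg.n_burnin and it % cfg.adapt_interval == 0:
                self.adapt()
            if it <= cfg.n_burnin and self.rng.uniform() < math.exp(-1.0 - 5e-4 * it):
                self.prune(it)
            ranks[it - 1] = (self.r, self.r1, self.r2)
            self._check_finite(it)
            if it > cfg.n_burnin and (it - cfg.n_burnin) % cfg.thin == 0:
                states.append(self.snapshot())
        return Chain(
            states=states,
            rank_history=ranks,
            accept_history=self.accept_history,
            prune_events=self.prune_events,
            config=cfg,
            bases=self.bases,
            t=self.t.copy(),
            data=self.data,
        )


# --------------------------------------------------------------------------
# functional surface


def run_mcmc(data: PairedSeries, config: SamplerConfig) -> Chain:
    """Fit the model by MCMC; reproducible given ``config.seed``."""
    sampler = TacifaSampler(data, config)
    return sampler.run()


def gibbs_update_linear_blocks(
    state: ModelState, data: PairedSeries, config: SamplerConfig,
    rng: np.random.Generator | None = None,
) -> ModelState:
    """One sweep of the conjugate Gaussian block updates."""
    s = TacifaSampler(data, config, rng=rng, state=state)
    s.update_linear_blocks()
    return s.snapshot()


def hmc_update_kappa(
    state: ModelState, data: PairedSeries, config: SamplerConfig,
    rng: np.random.Generator | None = None, step_size: float | None = None,
) -> ModelState:
    """One Metropolis-corrected leapfrog update of the warp parameters."""
    s = TacifaSampler(data, config, rng=rng, state=state)
    if step_size is not None:
        s.settings.step_size_kappa = step_size
    s.hmc_kappa()
    return s.snapshot()


def hmc_update_lambda_column(
    state: ModelState, data: PairedSeries, j: int, config: SamplerConfig,
    rng: np.random.Generator | None = None, step_size: float | None = None,
) -> ModelState:
    """One Metropolis-corrected leapfrog update of column j of Lambda."""
    s = TacifaSampler(data, config, rng=rng, state=state)
    if step_size is not None:
        s.settings.step_size_lambda[j] = step_size
    s._lambda_caches()
    s.hmc_lambda_column(j)
    return s.snapshot()


def prune_columns(state: ModelState, config: SamplerConfig, data: PairedSeries,
                  iteration: int = 0) -> ModelState:
    """Remove effectively-zero loading columns (never below rank 1)."""
    s = TacifaSampler(data, config, state=state)
    s.prune(iteration)
    return s.snapshot()


def select_basis_size(
    data: PairedSeries,
    candidates: list[int],
    config: SamplerConfig,
    holdout_fraction: float = 0.1,
) -> int:
    """Pick the spline basis size by held-out prediction error.

    All four basis sizes are tied (K1 = K2 = J = K); for each candidate
    the model is fitted to a random 90% of the time columns and scored by
    the total posterior-predictive MSE at the held-out columns.
    """
    from .postprocess import predict_heldout
    from .synthdata import heldout_split

    if not candidates:
        raise ValueError("candidates must be non-empty")
    if len(candidates) == 1:
        return candidates[0]
    train, test = heldout_split(data.T, holdout_fraction, seed=config.seed)
    train_data = data.subset(train)
    best_k, best_mse = None, np.inf
    for K in candidates:
        cfg = replace(config, K=K, K1=None, K2=None, J=None)
        chain = run_mcmc(train_data, cfg)
        pred = predict_heldout(chain, data.t[test])
        mse = pred.mse(data.X[:, test], which="X") + pred.mse(data.Y[:, test], which="Y")
        if mse < best_mse:
            best_k, best_mse = K, mse
    return best_k
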