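"""Identifiability post-processing and posterior summaries.

Factor loadings are only identified up to an orthogonal right rotation:
(Lambda1, eta) and (Lambda1 R, R' eta) give the same likelihood.  To make
the raw chain interpretable, each draw is rotated toward its (already
aligned) predecessor by solving the orthogonal Procrustes problem, after
an initial SVD transform that orders the first draw's columns by how much
of the data they explain.  The shared-space pair (Lambda Xi1, Lambda Xi2)
receives a single common rotation, with the shared factor coefficients
counter-rotated, so no draw's likelihood changes; each projected
individual block gets its own rotation with its factor block
counter-rotated likewise.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import (
    ModelBases,
    NoiseState,
    PairedSeries,
    log_likelihood_from_means,
    mean_curves,
)
from .sampler import Chain
from .splines import eval_warp

__all__ = [
    "AlignedChain",
    "procrustes_rotation",
    "align_chain",
    "sp_importance",
    "important_factor_count",
    "important_shared_factors",
    "syn_from_chain",
    "PredictiveSummary",
    "predict_heldout",
    "WarpSummary",
    "warp_summary",
]


def procrustes_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Orthonormal R minimizing ||A - B R||_F.

    R = U V' where U S V' is the SVD of B'A.  A zero cross-product leaves
    the optimum undefined; the identity is returned with a warning.
    """
    A = np.atleast_2d(A)
    B = np.atleast_2d(B)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    C = B.T @ A
    if not np.any(np.abs(C) > 1e-300):
        warnings.warn("zero cross-product; Procrustes optimum undefined, returning identity",
                      RuntimeWarning)
        return np.eye(A.shape[1])
    U, _, Vt = np.linalg.svd(C)
    return U @ Vt


@dataclass
class AlignedChain:
    """Procrustes-aligned loading draws and counter-rotated factor blocks."""

    lambda1: np.ndarray  # m x p x r draws of Lambda Xi1, aligned
    lambda2: np.ndarray  # m x p x r draws of Lambda Xi2, aligned
    psigamma1: np.ndarray  # m x p x r1 draws of Psi Gamma1, aligned
    psigamma2: np.ndarray  # m x p x r2 draws of Psi Gamma2, aligned
    beta_shared: np.ndarray  # m x r x K, counter-rotated
    beta_ind1: np.ndarray  # m x r1 x K1
    beta_ind2: np.ndarray  # m x r2 x K2
    rotations_shared: np.ndarray  # m x r x r per-draw cumulative rotations
    rotations_ind1: np.ndarray
    rotations_ind2: np.ndarray
    kept: np.ndarray  # indices into chain.states that were aligned
    chain: Chain

    def __len__(self) -> int:
        return self.lambda1.shape[0]


def _sequential_align(blocks: np.ndarray, coeffs: np.ndarray, R0: np.ndarray | None = None):
    """Align draws of stacked loading blocks to their predecessors.

    ``blocks`` is (m, q, r) (q may be 2p for a stacked pair), ``coeffs``
    the matching (m, r, K) factor coefficients.  Returns aligned copies
    plus the per-draw rotations applied.
    """
    m, _, r = blocks.shape
    out = blocks.copy()
    cout = coeffs.copy()
    rots = np.tile(np.eye(r), (m, 1, 1))
    if R0 is not None:
        out[0] = out[0] @ R0
        cout[0] = R0.T @ cout[0]
        rots[0] = R0
    for i in range(1, m):
        R = procrustes_rotation(out[i - 1], blocks[i])
        out[i] = blocks[i] @ R
        cout[i] = R.T @ coeffs[i]
        rots[i] = R
    return out, cout, rots


def align_chain(chain: Chain) -> AlignedChain:
    """Sequentially Procrustes-align the post burn-in loading draws.

    Draws whose ranks differ from the terminal (modal) ranks are dropped
    with a message.  The first draw of the shared block is pre-rotated by
    the SVD of the residual cross-product (x_t - Psi Gamma1 zeta1(t))'
    Lambda1 so that higher-order columns are lower in significance.
    """
    if len(chain) < 1:
        raise ValueError("empty chain")
    ranks = np.array([
        (s.loadings.r, s.loadings.r1, s.loadings.r2) for s in chain.states
    ])
    terminal = ranks[-1]
    keep = np.flatnonzero((ranks == terminal).all(axis=1))
    if keep.size < len(chain):
        warnings.warn(
            f"discarding {len(chain) - keep.size} draws whose ranks differ from "
            f"terminal (r, r1, r2) = {tuple(terminal)}"
        )
    states = [chain.states[i] for i in keep]

    lam1 = np.stack([s.loadings.Lambda * s.loadings.Xi1[None, :] for s in states])
    lam2 = np.stack([s.loadings.Lambda * s.loadings.Xi2[None, :] for s in states])
    pg1 = np.stack([s.loadings.Psi @ s.loadings.Gamma1 for s in states])
    pg2 = np.stack([s.loadings.Psi @ s.loadings.Gamma2 for s in states])
    bsh = np.stack([s.coeffs.beta_shared for s in states])
    b1 = np.stack([s.coeffs.beta_ind1 for s in states])
    b2 = np.stack([s.coeffs.beta_ind2 for s in states])

    # initial SVD transform of the first shared-loading draw
    R0 = None
    if chain.data is not None:
        s0 = states[0]
        bases, t = chain.bases, chain.t
        zeta1 = s0.coeffs.beta_ind1 @ bases.ind1.design(t).T
        resid = chain.data.X - s0.loadings.Psi @ (s0.loadings.Gamma1 @ zeta1)
        _, _, U2t = np.linalg.svd(resid.T @ lam1[0], full_matrices=False)
        R0 = U2t.T

    stacked = np.concatenate([lam1, lam2], axis=1)  # common rotation for the pair
    stacked_aligned, bsh_a, rots = _sequential_align(stacked, bsh, R0)
    p = lam1.shape[1]
    pg1_a, b1_a, rots1 = _sequential_align(pg1, b1)
    pg2_a, b2_a, rots2 = _sequential_align(pg2, b2)

    return AlignedChain(
        lambda1=stacked_aligned[:, :p, :],
        lambda2=stacked_aligned[:, p:, :],
        psigamma1=pg1_a,
        psigamma2=pg2_a,
        beta_shared=bsh_a,
        beta_ind1=b1_a,
        beta_ind2=b2_a,
        rotations_shared=rots,
        rotations_ind1=rots1,
        rotations_ind2=rots2,
        kept=keep,
        chain=chain,
    )


def sp_importance(draws: np.ndarray) -> np.ndarray:
    """Entrywise sign-stability score SP = |0.5 - P(entry > 0)| / 0.5.

    1 means the aligned posterior mass is entirely one-signed (an
    important loading entry), 0 means perfectly sign-balanced.
    """
    draws = np.asarray(draws)
    if draws.shape[0] < 2:
        raise ValueError("need at least 2 draws")
    p_pos = (draws > 0).mean(axis=0)
    return np.abs(0.5 - p_pos) / 0.5


def important_factor_count(sp_table: np.ndarray, threshold: float = 0.9) -> int:
    """Number of loading columns containing at least one entry with SP
    at or above ``threshold`` (default 0.9)."""
    return int((np.asarray(sp_table).max(axis=0) >= threshold).sum())


def important_shared_factors(aligned: AlignedChain, threshold: float = 0.9) -> int:
    """Count of important shared-space factors.

    A column counts as important when its maximum entrywise SP reaches
    the threshold in the aligned chain *and* in the raw (unaligned)
    chain.  Alignment resolves rotational ambiguity, but for columns the
    shrinkage prior has collapsed to noise the Procrustes step imposes
    spurious sign coherence; requiring sign stability of the raw draws as
    well screens those out while leaving genuinely sign-determined
    factors (which barely rotate once identified) untouched.
    """
    raw = np.stack([
        aligned.chain.states[i].loadings.Lambda
        * aligned.chain.states[i].loadings.Xi1[None, :]
        for i in aligned.kept
    ])
    sp_aligned = sp_importance(aligned.lambda1).max(axis=0)
    sp_raw = sp_importance(raw).max(axis=0)
    return int((np.minimum(sp_aligned, sp_raw) >= threshold).sum())


@dataclass
class PredictiveSummary:
    """Pointwise posterior-predictive means and 95% bands at test times."""

    t: np.ndarray
    mean_X: np.ndarray  # p x len(t) predictive means
    mean_Y: np.ndarray
    lower_X: np.ndarray  # 2.5% predictive quantiles
    upper_X: np.ndarray  # 97.5%
    lower_Y: np.ndarray
    upper_Y: np.ndarray

    def _pick(self, which: str):
        if which == "X":
            return self.mean_X, self.lower_X, self.upper_X
        if which == "Y":
            return self.mean_Y, self.lower_Y, self.upper_Y
        raise ValueError("which must be 'X' or 'Y'")

    def mse(self, truth: np.ndarray, which: str) -> float:
        """Mean squared error of the predictive mean against held-out data."""
        mean, _, _ = self._pick(which)
        return float(np.mean((np.asarray(truth) - mean) ** 2))

    def coverage(self, truth: np.ndarray, which: str) -> float:
        """Fraction of held-out entries inside the 95% predictive band."""
        _, lo, hi = self._pick(which)
        truth = np.asarray(truth)
        return float(np.mean((truth >= lo) & (truth <= hi)))


def predict_heldout(chain: Chain, t_test: np.ndarray,
                    rng: np.random.Generator | None = None) -> PredictiveSummary:
    """Posterior-predictive summary at held-out time points.

    For each retained draw, the model mean is evaluated at ``t_test`` (the
    spline bases extend naturally to unobserved times) and observation
    noise is added to form one predictive sample; pointwise means and
    2.5/97.5% quantiles are returned.
    """
    t_test = np.atleast_1d(np.asarray(t_test, float))
    if t_test.size and (t_test.min() < 0 or t_test.max() > 1):
        raise ValueError("t_test must lie in [0, 1]")
    if len(chain) == 0:
        raise ValueError("empty chain")
    rng = rng if rng is not None else np.random.default_rng(chain.config.seed + 1)
    p = chain.states[0].loadings.p
    m = len(chain)
    mx = np.empty((m, p, t_test.size))
    my = np.empty_like(mx)
    px = np.empty_like(mx)
    py = np.empty_like(mx)
    for i, state in enumerate(chain.states):
        mu_X, mu_Y = mean_curves(state, chain.bases, t_test)
        mx[i], my[i] = mu_X, mu_Y
        px[i] = mu_X + rng.standard_normal(mu_X.shape) * np.sqrt(state.noise.sigma1_sq)[:, None]
        py[i] = mu_Y + rng.standard_normal(mu_Y.shape) * np.sqrt(state.noise.sigma2_sq)[:, None]
    loX, hiX = np.quantile(px, [0.025, 0.975], axis=0)
    loY, hiY = np.quantile(py, [0.025, 0.975], axis=0)
    return PredictiveSummary(
        t=t_test,
        mean_X=mx.mean(axis=0), mean_Y=my.mean(axis=0),
        lower_X=loX, upper_X=hiX, lower_Y=loY, upper_Y=hiY,
    )


@dataclass
class WarpSummary:
    """Posterior mean and 95% pointwise band of the warping function."""

    grid: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray

    def band_contains(self, truth: np.ndarray) -> np.ndarray:
        truth = np.asarray(truth)
        return (truth >= self.lower) & (truth <= self.upper)


def plot_warp_summary(summary: WarpSummary, path, truth=None) -> None:
    """Write a warp-posterior figure (mean, 95% band, identity line)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.fill_between(summary.grid, summary.lower, summary.upper,
                    color="red", alpha=0.25, label="95% band")
    ax.plot(summary.grid, summary.mean, color="green", label="posterior mean")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="no lag")
    if truth is not None:
        ax.plot(summary.grid, truth, color="black", lw=1.2, label="truth")
    ax.set_xlabel("t")
    ax.set_ylabel("M(t)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def warp_summary(chain: Chain, grid: np.ndarray) -> WarpSummary:
    """Pointwise posterior mean and 95% band of M(t) over a grid.

    The boundary constraints M(0) = 0 and M(1) = 1 hold for every draw,
    so the bands are degenerate at the endpoints.
    """
    if len(chain) < 2:
        raise ValueError("need at least 2 draws")
    grid = np.atleast_1d(np.asarray(grid, float))
    draws = np.stack([
        eval_warp(state.warp, chain.bases.warp, grid) for state in chain.states
    ])
    lo, hi = np.quantile(draws, [0.025, 0.975], axis=0)
    return WarpSummary(grid=grid, mean=draws.mean(axis=0), lower=lo, upper=hi)


def syn_from_chain(chain: Chain, how: str = "average") -> float:
    """Syn similarity summarized over a fitted chain.

    ``average`` (default) averages the per-draw Syn values — each draw's
    Syn is invariant to the rotational non-identifiability of the
    loadings, so this needs no alignment.  ``mean_state`` instead
    evaluates the statistic at the entrywise posterior mean of the raw
    parameters; it is cheaper but biased toward zero shared contribution
    whenever the chain mixes across rotations or sign flips.
    """
    from .model import FactorCoeffs, LoadingSet, NoiseState, syn_similarity
    from .splines import WarpSpec

    if len(chain) == 0:
        raise ValueError("empty chain")
    ranks = np.array([(s.loadings.r, s.loadings.r1, s.loadings.r2) for s in chain.states])
    keep = [chain.states[i] for i in np.flatnonzero((ranks == ranks[-1]).all(axis=1))]
    if how == "average":
        return float(np.mean([syn_similarity(s, chain.bases, chain.t) for s in keep]))
    if how != "mean_state":
        raise ValueError("how must be 'mean_state' or 'average'")

    def avg(get):
        return np.mean([get(s) for s in keep], axis=0)

    mean_state = keep[-1].replace(
        loadings=LoadingSet(
            avg(lambda s: s.loadings.Lambda), avg(lambda s: s.loadings.Gamma1),
            avg(lambda s: s.loadings.Gamma2), avg(lambda s: s.loadings.Xi1),
            avg(lambda s: s.loadings.Xi2),
        ),
        coeffs=FactorCoeffs(
            avg(lambda s: s.coeffs.beta_shared), avg(lambda s: s.coeffs.beta_ind1),
            avg(lambda s: s.coeffs.beta_ind2),
        ),
        warp=WarpSpec(avg(lambda s: s.warp.kappa)),
        noise=NoiseState(avg(lambda s: s.noise.sigma1_sq), avg(lambda s: s.noise.sigma2_sq)),
    )
    return float(syn_similarity(mean_state, chain.bases, chain.t))


def aligned_log_likelihoods(aligned: AlignedChain, data: PairedSeries) -> np.ndarray:
    """Log likelihood of each aligned draw, computed from the rotated parts.

    Alignment rotates loadings and counter-rotates factors, so these must
    equal the corresponding raw-draw likelihoods exactly.
    """
    chain = aligned.chain
    bases, t = chain.bases, chain.t
    B1 = bases.ind1.design(t).T
    B2 = bases.ind2.design(t).T
    Bt = bases.shared.design(t).T
    out = np.empty(len(aligned))
    for i in range(len(aligned)):
        state = chain.states[aligned.kept[i]]
        M = eval_warp(state.warp, bases.warp, t)
        BM = bases.shared.design(np.clip(M, 0, 1)).T
        mu_X = aligned.psigamma1[i] @ (aligned.beta_ind1[i] @ B1) + \
            aligned.lambda1[i] @ (aligned.beta_shared[i] @ Bt)
        mu_Y = aligned.psigamma2[i] @ (aligned.beta_ind2[i] @ B2) + \
            aligned.lambda2[i] @ (aligned.beta_shared[i] @ BM)
        out[i] = log_likelihood_from_means(mu_X, mu_Y, state.noise, data)
    return out
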