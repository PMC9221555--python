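"""Synthetic paired-series generators used in the evaluation studies.

Two designs are provided.  The first draws data from the factor model
itself: a 15-feature pair with a rank-3 block-diagonal shared loading
matrix, smooth polynomial shared factors, sinusoidal individual factors
and unit observation noise, with the second series warped in time by
M0(t) = t^0.5 (or a "turning" warp that changes lead/lag direction).
The second design is geometric and deliberately model-free: each series
is the set of Cartesian coordinates of 12 equidistant landmarks on an
ellipse whose axes change over time while the enclosed area stays fixed,
the second series running on the warped clock.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .model import PairedSeries, projection

__all__ = [
    "SimRecipe",
    "OrthoPoly",
    "warp_sqrt",
    "warp_turning",
    "generate_sim1",
    "generate_sim1_variant",
    "generate_sim2",
    "heldout_split",
]


def warp_sqrt(t: np.ndarray) -> np.ndarray:
    """Monotone warp M0(t) = t^0.5 (second series always lags)."""
    return np.sqrt(t)


def warp_turning(t: np.ndarray) -> np.ndarray:
    """Warp M0(t) = {(0.33 sin 2 pi t)^2 + t^2}^0.5; lead/lag changes sign."""
    return np.sqrt((0.33 * np.sin(2 * np.pi * t)) ** 2 + t**2)


@dataclass(frozen=True)
class SimRecipe:
    """Conditions of one simulation run.

    ``noise_sd`` is the observation noise standard deviation per entry
    (0 is allowed for the noise-free geometric design).
    """

    name: str = "sim1"
    p: int = 15
    T: int = 500
    warp: Callable[[np.ndarray], np.ndarray] = warp_sqrt
    noise_sd: float = 1.0
    seed: int = 0
    n_shared: int = 3  # rank of the true shared loading matrix
    n_ind: int = 10  # number of individual-specific factors

    def __post_init__(self) -> None:
        if self.T < 2:
            raise ValueError("T must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def grid(self) -> np.ndarray:
        """Time grid 1/T, 2/T, ..., 1."""
        return np.arange(1, self.T + 1) / self.T


class OrthoPoly:
    """Orthonormal polynomial basis on a grid, evaluable at new points.

    Mirrors R's ``poly``: QR-orthonormalize (1, t, ..., t^degree) over the
    grid, drop the constant, keep the monomial-to-orthogonal transform so
    the same polynomials can be evaluated at warped time points.
    """

    def __init__(self, grid: np.ndarray, degree: int) -> None:
        self.degree = degree
        V = np.vander(np.asarray(grid, float), degree + 1, increasing=True)
        Q, R = np.linalg.qr(V)
        sign = np.sign(np.diag(R))
        sign[sign == 0] = 1.0
        self._Rinv = np.linalg.inv(R * sign[:, None])

    def __call__(self, s: np.ndarray) -> np.ndarray:
        """Evaluate the degree polynomials at ``s``: shape (len(s), degree)."""
        V = np.vander(np.asarray(s, float), self.degree + 1, increasing=True)
        return (V @ self._Rinv)[:, 1:]


@dataclass(frozen=True)
class SimTruth:
    """Ground truth stored for recovery scoring."""

    Lambda: np.ndarray
    Gamma1: np.ndarray
    Gamma2: np.ndarray
    Psi: np.ndarray
    mean_X: np.ndarray
    mean_Y: np.ndarray
    warp: Callable[[np.ndarray], np.ndarray]
    noise_sd: float
    eta: OrthoPoly | None = None


def _block_diag_loadings(p: int, r: int, rng: np.random.Generator) -> np.ndarray:
    """Block-diagonal p x r loading matrix, nonzero entries ~ N(15, 0.1^2)."""
    Lambda = np.zeros((p, r))
    bounds = np.linspace(0, p, r + 1).round().astype(int)
    for k in range(r):
        rows = slice(bounds[k], bounds[k + 1])
        Lambda[rows, k] = rng.normal(15.0, 0.1, bounds[k + 1] - bounds[k])
    return Lambda


_ZETA_FAMILIES = {
    "sin": lambda k, t: np.sin(k * t),
    "linear": lambda k, t: k * t,
    "quadratic": lambda k, t: (k * t) ** 2,
}


def generate_sim1_variant(recipe: SimRecipe, zeta_family: str = "sin"):
    """Factor-model design with a configurable first-series factor family.

    Returns ``(PairedSeries, SimTruth)``.  The second series' individual
    factors are always cos(kt); the first series' are sin(kt), kt or
    (kt)^2 -- the further the family from the sinusoid the less alike
    the two series and the lower the expected similarity.
    """
    if zeta_family not in _ZETA_FAMILIES:
        raise ValueError(
            f"unknown zeta family {zeta_family!r}; choose from {sorted(_ZETA_FAMILIES)}"
        )
    rng = np.random.default_rng(recipe.seed)
    t = recipe.grid
    p, T, r, r_ind = recipe.p, recipe.T, recipe.n_shared, recipe.n_ind

    Lambda = _block_diag_loadings(p, r, rng)
    Gamma1 = rng.normal(0.0, 0.1, (p, r_ind))
    Gamma2 = rng.normal(0.0, 0.1, (p, r_ind))
    Psi = projection(Lambda)

    ks = np.arange(1, r_ind + 1)[:, None]
    zeta1 = _ZETA_FAMILIES[zeta_family](ks, t[None, :])
    zeta2 = np.cos(ks * t[None, :])

    poly = OrthoPoly(t, r)
    eta = poly(t).T  # r x T
    eta_warp = poly(recipe.warp(t)).T

    mean_X = Psi @ (Gamma1 @ zeta1) + Lambda @ eta
    mean_Y = Psi @ (Gamma2 @ zeta2) + Lambda @ eta_warp
    X = mean_X + rng.normal(0.0, recipe.noise_sd, (p, T))
    Y = mean_Y + rng.normal(0.0, recipe.noise_sd, (p, T))

    truth = SimTruth(Lambda, Gamma1, Gamma2, Psi, mean_X, mean_Y,
                     recipe.warp, recipe.noise_sd, eta=poly)
    return PairedSeries(X, Y, t), truth


def generate_sim1(recipe: SimRecipe):
    """The baseline factor-model design (sinusoidal first-series factors)."""
    return generate_sim1_variant(recipe, "sin")


def generate_sim2(recipe: SimRecipe):
    """Area-preserving ellipse landmark design; returns (PairedSeries, SimTruth).

    At time t the first shape has axes ax(t) = 2(t+1), bx(t) = 2/(t+1)
    (so ax bx = 4 for every t) and the second shape runs on the warped
    clock: ay(t) = ax(M0(t)), by(t) = bx(M0(t)).  Features are the 24
    Cartesian coordinates of 12 landmarks at equidistant angles; the
    default is noise free, ``noise_sd > 0`` gives the low-SNR variant.
    """
    rng = np.random.default_rng(recipe.seed)
    t = recipe.grid
    T = recipe.T
    theta = 2.0 * np.pi * np.arange(12) / 12.0

    def shape_coords(u: np.ndarray) -> np.ndarray:
        a = 2.0 * (u + 1.0)
        b = 2.0 / (u + 1.0)
        rows = np.empty((24, u.size))
        rows[0::2] = np.sin(theta)[:, None] * a[None, :]
        rows[1::2] = np.cos(theta)[:, None] * b[None, :]
        return rows

    mean_X = shape_coords(t)
    mean_Y = shape_coords(recipe.warp(t))
    X = mean_X + rng.normal(0.0, recipe.noise_sd, (24, T)) if recipe.noise_sd else mean_X.copy()
    Y = mean_Y + rng.normal(0.0, recipe.noise_sd, (24, T)) if recipe.noise_sd else mean_Y.copy()

    empty = np.zeros((24, 0))
    truth = SimTruth(empty, empty, empty, np.eye(24), mean_X, mean_Y,
                     recipe.warp, recipe.noise_sd)
    return PairedSeries(X, Y, t), truth


def heldout_split(T: int, fraction: float = 0.1, seed: int = 0):
    """Random train/test split over time columns.

    Returns sorted (train, test) index arrays; the test set holds
    ``round(fraction * T)`` columns and both series share the split.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    n_test = int(round(fraction * T))
    test = np.sort(rng.choice(T, size=n_test, replace=False))
    train = np.setdiff1d(np.arange(T), test)
    return train, test
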