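"""B-spline bases on [0, 1] and the monotone time-warping construction.

The warping function is

    M(t) = sum_j gamma_j B_j(t),
    gamma_j = sum_{l=2}^{j} exp(kappa_l) / sum_{k=2}^{J} exp(kappa_k),  gamma_1 = 0,

with clamped B-spline bases B_1..B_J on [0, 1].  Because the coefficients
gamma are non-decreasing with gamma_1 = 0 and gamma_J = 1, M is a smooth
monotone increasing bijection of [0, 1] with M(0) = 0 and M(1) = 1 -- the
defining properties of a time warp.  The free parameters kappa are
unconstrained reals, which is what makes the warp amenable to
gradient-based (HMC) sampling.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["BasisSpec", "WarpSpec", "gamma_from_kappa", "eval_warp"]


def _validate_domain(t: np.ndarray) -> np.ndarray:
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if t.size and (t.min() < 0.0 or t.max() > 1.0):
        raise ValueError(
            f"evaluation points must lie in [0, 1]; got range "
            f"[{t.min():.6g}, {t.max():.6g}]"
        )
    return t


@dataclass(frozen=True)
class BasisSpec:
    """A clamped B-spline basis on [0, 1].

    Parameters
    ----------
    n_bases
        Number of basis functions (J, K, K1 or K2 in the model).
    degree
        Polynomial degree; cubic by default.  Clamped (repeated) boundary
        knots give endpoint interpolation: the first basis equals 1 at
        t=0 and the last equals 1 at t=1.
    """

    n_bases: int
    degree: int = 3
    knots: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.n_bases < self.degree + 1:
            raise ValueError(
                f"need n_bases >= degree + 1, got {self.n_bases} < {self.degree + 1}"
            )
        n_interior = self.n_bases - self.degree - 1
        interior = np.linspace(0.0, 1.0, n_interior + 2)[1:-1]
        knots = np.concatenate(
            [np.zeros(self.degree + 1), interior, np.ones(self.degree + 1)]
        )
        object.__setattr__(self, "knots", knots)
        spl = BSpline(knots, np.eye(self.n_bases), self.degree, extrapolate=False)
        object.__setattr__(self, "_spl", spl)
        object.__setattr__(self, "_dspl", spl.derivative())

    def design(self, t) -> np.ndarray:
        """Basis values at ``t``: array of shape ``(len(t), n_bases)``.

        Rows sum to one (partition of unity) and all values are in [0, 1].
        """
        t = _validate_domain(t)
        return self._spl(t)

    def design_derivative(self, t) -> np.ndarray:
        """First derivatives of each basis function at ``t``."""
        t = _validate_domain(t)
        return self._dspl(t)

    @property
    def greville(self) -> np.ndarray:
        """Greville abscissae; coefficients reproducing the identity map."""
        k, d = self.knots, self.degree
        return np.array([k[j + 1 : j + d + 1].mean() for j in range(self.n_bases)])


def eval_basis(spec: BasisSpec, t) -> np.ndarray:
    """Functional alias for :meth:`BasisSpec.design`."""
    return spec.design(t)


def gamma_from_kappa(kappa) -> np.ndarray:
    """Map free warp parameters to monotone B-spline coefficients.

    Returns a vector of length ``len(kappa) + 1`` starting at 0, ending at
    exactly 1, non-decreasing (cumulative softmax weights).
    """
    kappa = np.atleast_1d(np.asarray(kappa, dtype=float))
    if kappa.size < 1:
        raise ValueError("kappa must have length >= 1")
    if not np.all(np.isfinite(kappa)):
        raise ValueError("kappa entries must be finite")
    w = np.exp(kappa - kappa.max())
    cum = np.cumsum(w)
    cum /= cum[-1]  # normalizing the cumulative sum keeps increments >= 0
    gamma = np.concatenate([[0.0], cum])
    gamma[-1] = 1.0
    return gamma


@dataclass(frozen=True)
class WarpSpec:
    """Free coefficients kappa (length J-1) of the monotone warp."""

    kappa: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "kappa", np.atleast_1d(np.asarray(self.kappa, float)))

    @property
    def gamma(self) -> np.ndarray:
        return gamma_from_kappa(self.kappa)

    @property
    def n_bases(self) -> int:
        return self.kappa.size + 1

    @staticmethod
    def identity(basis: BasisSpec) -> "WarpSpec":
        """Warp parameters for which M(t) = t exactly (Greville increments)."""
        inc = np.diff(basis.greville)
        if np.any(inc <= 0):  # pragma: no cover - clamped equidistant knots
            raise ValueError("basis Greville abscissae must be strictly increasing")
        return WarpSpec(np.log(inc))


def eval_warp(spec: WarpSpec, basis: BasisSpec, t) -> np.ndarray:
    """Evaluate the warping function M(t) = sum_j gamma_j B_j(t)."""
    if basis.n_bases != spec.n_bases:
        raise ValueError(
            f"warp has {spec.n_bases} coefficients but basis has {basis.n_bases}"
        )
    return basis.design(t) @ spec.gamma
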