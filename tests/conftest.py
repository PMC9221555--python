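import numpy as np
import pytest

from tacifa.model import (
    FactorCoeffs,
    LoadingSet,
    ModelBases,
    ModelState,
    NoiseState,
)
from tacifa.splines import WarpSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_state(rng, p=5, r=2, r1=2, r2=2, bases: ModelBases | None = None,
                 identity_warp: bool = False) -> tuple[ModelState, ModelBases]:
    """A random valid model state with well-conditioned loadings."""
    bases = bases or ModelBases.tied(6)
    Lambda = rng.standard_normal((p, r))
    state = ModelState(
        loadings=LoadingSet(
            Lambda=Lambda,
            Gamma1=rng.standard_normal((p, r1)),
            Gamma2=rng.standard_normal((p, r2)),
            Xi1=rng.standard_normal(r),
            Xi2=rng.standard_normal(r),
        ),
        coeffs=FactorCoeffs(
            beta_shared=rng.standard_normal((r, bases.shared.n_bases)),
            beta_ind1=rng.standard_normal((r1, bases.ind1.n_bases)),
            beta_ind2=rng.standard_normal((r2, bases.ind2.n_bases)),
        ),
        warp=(WarpSpec.identity(bases.warp) if identity_warp
              else WarpSpec(rng.standard_normal(bases.warp.n_bases - 1))),
        noise=NoiseState(
            sigma1_sq=rng.uniform(0.5, 2.0, p),
            sigma2_sq=rng.uniform(0.5, 2.0, p),
        ),
    )
    return state, bases
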