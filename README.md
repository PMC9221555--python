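# tacifa

**Time Aligned Common and Individual Factor Analysis** — Bayesian
dynamic factor analysis for *pairs* of multivariate time series whose
shared dynamics are offset by a time-varying lag.

When two interacting systems are measured in parallel — two people
mimicking each other's facial movements, two animals coordinating
behavior, paired physiological channels — part of the variability is
shared and part is specific to each series, and the shared part is
rarely synchronous: one series leads, the other follows, and the lag
changes over time.  `tacifa` fits a single joint model for this
situation:

    x_t = Psi Gamma1 zeta1(t) + Lambda Xi1 eta(t)    + eps1_t
    y_t = Psi Gamma2 zeta2(t) + Lambda Xi2 eta(M(t)) + eps2_t

Both p-dimensional series load (via `Lambda` and diagonal scales `Xi`)
on common smooth latent factor curves `eta(t)`; the second series reads
those curves through an unknown monotone warping function
`M : [0,1] -> [0,1]` (`M(t) < t`: the second series lags).  Individual
structure lives in the orthogonal complement of the shared loading
space, enforced by the projector
`Psi = I - Lambda (Lambda'Lambda)^{-1} Lambda'`.  Factor curves and the
warp are B-spline expansions; the warp's coefficients are a cumulative
softmax, which makes `M` monotone with `M(0)=0, M(1)=1` while keeping
the parameters unconstrained for gradient-based sampling.

Inference is fully Bayesian: multiplicative-gamma shrinkage priors on
the loadings select the numbers of shared and individual factors
automatically (surplus columns are pruned during burn-in), conjugate
blocks are Gibbs-sampled, and the shared loadings and warp parameters
are updated by Hamiltonian Monte Carlo with analytic gradients.  Chains
are post-processed by sequential orthogonal Procrustes alignment so
that loading draws are interpretable, with per-entry sign-stability
scores `SP = |0.5 - P(entry > 0)| / 0.5` and a [0,1] similarity
statistic **Syn** comparing the two series' relative shared-variance
contributions feature by feature.

See `docs/methods.md` for the full model, priors, sampler and
post-processing details.

## Worked example

Fit the bundled factor-model simulation (15 features, rank-3 shared
structure, true warp M0(t) = sqrt(t)) and inspect what comes back:

```python
import numpy as np
from tacifa import (SimRecipe, generate_sim1, heldout_split,
                    SamplerConfig, run_mcmc, align_chain,
                    important_shared_factors, predict_heldout,
                    syn_from_chain, warp_summary)

data, truth = generate_sim1(SimRecipe(T=300, seed=11))
train, test = heldout_split(data.T, fraction=0.1, seed=5)

config = SamplerConfig(n_iter=3000, n_burnin=1500, K=10, seed=3)
chain = run_mcmc(data.subset(train), config)

pred = predict_heldout(chain, data.t[test])
print("held-out MSE X:", round(pred.mse(data.X[:, test], "X"), 3))
print("held-out MSE Y:", round(pred.mse(data.Y[:, test], "Y"), 3))
print("important shared factors:", important_shared_factors(align_chain(chain)))
print("Syn similarity:", round(syn_from_chain(chain), 3))
ws = warp_summary(chain, np.linspace(0, 1, 101))
inside = ws.band_contains(np.sqrt(ws.grid))[1:-1].mean()
print("true warp inside 95% band:", round(inside, 3))
```

Output from this exact run:

```
held-out MSE X: 1.022
held-out MSE Y: 1.062
important shared factors: 3
Syn similarity: 0.964
true warp inside 95% band: 0.98
```

Reading it: the held-out prediction error sits at the unit
observation-noise floor (the model cannot beat 1.0 and does not
overfit); the sampler, started from a conservative 15 shared factors,
identifies exactly the 3 true ones; Syn near 1 says the warped shared
structure explains the same fraction of variance in both series; and
the true warp lies inside the 95% pointwise credible band at 98% of
interior grid points.

## Command line

A thin CLI wraps the library:

```bash
tacifa simulate --recipe sim1 --t-points 300 --seed 11 --out-x x.csv --out-y y.csv
tacifa fit --data-x x.csv --data-y y.csv --time-column time \
           --n-iter 3000 --n-burnin 1500 --basis-size 10 --holdout 0.1 --outdir out/
tacifa select-k --data-x x.csv --data-y y.csv --time-column time --candidates 6,8,10,12
tacifa summarize --outdir out/
```

`fit` writes SP importance tables, the warp posterior summary,
predictive summaries, a JSON report (Syn, ranks, MSEs, coverages) and a
provenance manifest; every artifact carries the manifest hash.

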