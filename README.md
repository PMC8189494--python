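# agejs — age-structured Jolly-Seber capture-recapture models

`agejs` estimates survival, recruitment, abundance and **annual population
age structure** from individual encounter histories in open-population
(Jolly-Seber) studies, using Bayesian data augmentation. It is aimed at
wildlife demographers who mark and recapture individuals over several years
and who hold age information for some — not necessarily all — captured
animals (for example, ages read from a tooth section at first capture).

Classic Jolly-Seber (JS) superpopulation models ignore age, which discards
information: an animal first captured at age 10 must have been alive for
the previous nine years. Feeding ages into the latent state process
tightens survival, abundance and growth-rate estimates, and opens the door
to age-specific questions — survival senescence, life expectancy, the
proportion of the population in prime breeding age — without assuming a
stable age distribution.

## The model

Detection histories `y_ik` (individual `i`, occasion `k = 1..K`) are
augmented to `M` pseudo-individuals with inclusion indicators
`w_i ~ Bernoulli(ψ)`. Individuals enter the population at one of the `K`
occasions with entry probabilities `β ~ Dirichlet(b)`, re-expressed as
conditional entry probabilities `η_k = β_k / (1 − Σ_{l<k} β_l)`. The alive
state `z_ik` evolves as

    z_ik ~ Bernoulli( φ(x_ik−1) z_ik−1 + η_k Π_{l<k}(1 − z_il) ),

and detection is `y_ik ~ Bernoulli(p z_ik w_i)`. The age extension assigns
each individual an occasion-1 age category `(x_i1 + 1) ~ Categorical(π)`
with `π = (1 − η_1, η_1 π′_1..J)` — category 0 meaning "not yet entered",
`J` the maximum possible age in year 1 — after which ages increment
deterministically by one each year. Survival is either constant `φ` or
quadratic in age on the logit scale,

    logit φ(a) = α0 + α1 (a − c) + α2 (a − c)²,

with centering constant `c`. Derived per draw: annual abundance
`N_k = Σ_i z_ik w_i`, superpopulation `N* = Σ_i w_i`, alive-by-age counts
`N_kj`, growth rates `λ_k = N_k+1 / N_k`, survivorship curves, life
expectancy, and the prime-breeding-age proportion. Missing ages — of
never-captured augmented individuals, and of captured individuals without
an age record — are sampled as latent variables.

Three models are available: `js` (ageless baseline), `agejs_constant` and
`agejs_quadratic`. Fitting uses blocked Gibbs sampling over each
individual's entire latent history with conjugate parameter updates (see
`docs/methods.md`); an exact enumeration oracle over tiny instances pins
the sampler's correctness in the test suite.

## Worked example

```python
import numpy as np
from agejs import (default_configs, simulate_dataset, fit, MCMCConfig,
                   derive_series, summarize, freeman_tukey_check)

const, age_specific = default_configs()   # the two stock simulation regimes
data, truth = simulate_dataset(const, seed=42)
post = fit(data, "agejs_constant", const.design,
           mcmc=MCMCConfig(n_chains=2, n_iter=6000, n_burnin=1500, thin=5, seed=1))
der = derive_series(post, prime_age_range=(4, 6))
print(summarize(post, der))
print(freeman_tukey_check(post, data, seed=0).p_value)
```

With 227 of 400 simulated individuals observed, this prints (abridged):

```
quantity  median    q2.5   q97.5  rhat      ess
     psi   0.618   0.529   0.726 1.002  486.5
       p   0.255   0.214   0.296 1.000  755.8
     N_1 160.000 138.000 191.000 1.001  748.8
     N_7 209.000 166.000 262.025 1.002  608.4
   Nstar 420.000 366.000 491.050 1.002  487.2
     phi   0.811   0.764   0.860 0.999  905.4
lambda_1   1.086   0.981   1.195 1.000 1604.9
```

and a Freeman-Tukey posterior-predictive p-value of `0.341`. The generating
values — `φ = 0.85`, `p = 0.25`, realised `N_1 = 158`, `N_7 = 212`,
`N* = 400` — sit inside every 95% credible interval, and the p-value shows
no lack of fit (values near 0 or 1 would flag a problem).

The same pipeline is scriptable from the shell:

```sh
agejs simulate --config sim.yaml --seed 3 --out run/
agejs fit --data run/encounters.csv --ages run/ages.csv \
      --model agejs-const --J 9 --chains 3 --iters 20000 --burnin 5000 --out fit/
agejs summarize --draws fit/ --out summary.csv
agejs gof --draws fit/ --data run/encounters.csv --out gof.json
agejs study --config sim.yaml --reps 25 --models js,agejs-const --out study/
```

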