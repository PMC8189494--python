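# Methods

## Model

`agejs` implements the superpopulation (Schwarz–Arnason / POPAN-style)
formulation of the Jolly-Seber model with Bayesian data augmentation, plus
an age-structured extension. The observed `n` encounter histories are
augmented to `M` rows; each pseudo-individual carries an inclusion
indicator `w_i ~ Bernoulli(ψ)`, so the superpopulation size `N* = Σ w_i`
and annual abundances `N_k = Σ z_ik w_i` are sums of latent indicators
rather than free parameters. Entry follows a multinomial over occasions
with simplex `β`, used in conditional form `η_k = β_k / (1 − Σ_{l<k} β_l)`;
note `η_K = 1` identically, so every included individual has entered by the
final occasion and the "never entered" trajectory carries zero probability
(it is still represented in the history support for completeness). When the
remaining entry mass is zero the conditional probability is defined as 0 to
avoid 0/0.

The age extension replaces the occasion-1 entry Bernoulli with a
categorical over age categories `0..J`: category 0 ("age 0") is
not-yet-entered with probability `1 − η_1`; categories `1..J` have
probability `η_1 π′_j`, where `π′` is the initial age distribution among
animals alive in year 1 and `J` is the maximum possible age in year 1.
Ages then increment deterministically by one per occasion — *also after
death*, which is how the generative recurrence behaves; every
abundance-by-age quantity therefore gates on `z·w`, never on age alone.
Ages may exceed `J` during the study (`J` bounds only year-1 age); no
terminal-age cap is imposed, since quadratic senescent survival drives
old-age survival toward zero on its own.

Survival between occasions `k−1` and `k` uses the age held at `k−1`.
Two links are provided: constant `φ`, and logit-quadratic
`logit φ(a) = α0 + α1(a−c) + α2(a−c)²` with configurable centering `c`
(5 in the stock simulation regimes, intended to be the median observed age
in applications). Detection is Bernoulli with a single `p`, constant over
individuals and occasions (time-varying or heterogeneous `p` and `φ` are
out of scope).

**Recruitment age.** The aging recurrence assigns model age 1 at
within-study entry, but studies that mark only independent animals
effectively recruit at an older biological age. The mapping from model age
index to biological age is therefore exposed as a design field
`entry_age` (default 1): within-study recruits enter at age `entry_age`
and the feasible-history constraints shift accordingly. A study of
independent animals recruiting two-year-olds sets `entry_age = 2`.

## Priors

Beta(1,1) on `p`, `ψ` and constant `φ`; Dirichlet(**1**) on `β` and `π′`;
`invlogit(α0) ~ Beta(1,1)` (equivalently standard-logistic `α0`) and
Normal(0, sd 10) on `α1`, `α2`. All are configurable through
`sampler.Priors`.

## Sampling strategy

One individual's latent state is fully determined by the triple
(occasion-1 age `x1`, entry occasion, last occasion alive), so the sampler
enumerates the feasible-history table once per design (size
`J·K + K(K−1)/2 + 1` for the age models) and performs **blocked Gibbs**:
each individual's entire history is drawn from its categorical full
conditional. This sidesteps the slow mixing of one-coordinate alive-state
updates. Three structural facts make a sweep cheap:

1. Given parameters, the conditional history weight depends on the data
   only through the first/last detection occasions and any known-age
   constraint (the number of detections shifts all feasible weights
   equally). Observed individuals are updated in one vectorised
   Gumbel-argmax pass over a shared base-weight vector.
2. Augmented never-detected individuals are exchangeable, so the entire
   block collapses to a single multinomial draw over
   {excluded} ∪ {included with history h}.
3. Latent states of excluded (`w = 0`) individuals integrate to one in the
   likelihood and are marginalised out; parameter updates count only
   included trajectories. The invariant distribution over parameters,
   inclusion indicators and included histories is unchanged.

Parameter updates are conjugate — Beta for `ψ`, `p` and constant `φ`
(survival/death exposures), Dirichlet for `β` (entry-occasion counts) and
`π′` (year-1 age counts) — except (`α0`,`α1`,`α2`), which use
per-coordinate random-walk Metropolis on age-binned survival/death counts.
Step sizes start at (0.15, 0.08, 0.04) and are adapted every 100 burn-in
sweeps by a factor 1.3 toward a 20–45% acceptance band, then frozen.
Initial parameter values are drawn from the priors (the quadratic slopes
from tighter distributions purely as a starting point); observed
individuals' first history draw already conditions on their detections and
ages, so initialisation effects die within a few sweeps.

Known ages restrict an individual's feasible histories to those whose age
at the ageing occasion matches; an age with no consistent history raises a
validation error naming the individual. Missing ages of observed
individuals are sampled exactly like those of augmented individuals.

Correctness of the whole latent machinery is pinned by
`enumerate_reference`, an exact enumeration of the posterior of
`(N_1..K, N*)` at fixed parameters on tiny instances (guarded at ~10⁷
configurations), itself cross-checked in the tests against a raw
configuration-space enumeration that never touches the history
parameterisation.

## Defaults

- MCMC: 3 chains × 120 000 iterations, 20 000 burn-in, thinning 10
  (`case_study_mcmc()` preset: 6 chains × 220 000). Estimates are
  insensitive to thinning; retained-draw counts follow
  `(n_iter − n_burnin)/thin` per chain.
- Augmentation `M`: 3 × observed individuals unless set; a warning fires
  when `Pr(N* > 0.95 M) > 0.05`.
- R-hat: classic split-chain formula (each chain halved); both variances
  zero defines R-hat = 1. A fit is flagged when any monitored parameter has
  R-hat ≥ 1.1.
- Quantiles: linear interpolation between order statistics (numpy default),
  so 95% credible intervals are reproducible to the digit.

## Synthetic-data generator

The simulator draws the study conditions of the two stock regimes: a
superpopulation of exactly `N* = 400` (conditional simulation — the fitted
`ψ` then absorbs `M`), `K = 7` occasions, entry simplex
`β = (0.4, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1)`, `J = 9` initial age classes with
`π′ = (0.27, 0.17, 0.14, 0.12, 0.11, 0.09, 0.06, 0.03, 0.01)`, detection
`p = 0.25`, and survival either constant at 0.85 or logit-quadratic
`(α0, α1, α2) = (logit 0.85, −0.5, −0.20)` centred at age 5 — a senescent
curve running 0.63 at age 1, 0.88 at its age-4 peak, 0.03 at age 9.
Entry occasions are drawn multinomially per individual (equivalent to the
conditional-η scheme); ages attach at first capture and can be masked at an
exact fraction (`floor(fraction·n)`, sampled without replacement) for
missing-age experiments.

What the generator does *not* emulate: immigration/emigration, time- or
individual-varying detection and survival, age-reading error, and
unobservable age classes. Passing recovery tests therefore demonstrate
internal consistency of model and sampler under the stated conditions, not
robustness to those real-data complications.

## Derived quantities

- Growth rates `λ_k = N_k+1/N_k` per draw (undefined when `N_k = 0`).
- Age structure `N_kj/N_k` and the prime-age proportion
  `Σ_{j∈[lo,hi]} N_kj / N_k`; both error out for the ageless model.
- Survivorship `S(a) = Π_{u=a₀}^{a−1} φ_u`, conditional on reaching a₀
  (default 2, "independence").
- Life expectancy as the expectation of successive Bernoulli survival
  trials: `θ_j = S(j)(1−φ_j)`, `LE = Σ j θ_j`, with the survivorship mass
  beyond the truncation age assigned to death at `max_age` so that
  `Σθ = 1`; a diagnostic warns when that terminal mass exceeds 0.01, since
  the estimate is then truncation-sensitive (the formula as printed sums
  expected *age at death*, which conditional on surviving to a₀ equals
  a₀ plus the expected remaining years — both readings are reported in the
  API docs). 
- Freeman-Tukey posterior-predictive check on the yearly number of observed
  individuals: per draw, `ñ_k ~ Binomial(N_k, p)` and
  `D(v) = Σ_k (√v_k − √(p N_k))²` evaluated at that draw's `(p, N_k)` for
  both observed and replicated counts — the standard construction when the
  discrepancy's reference value is not otherwise pinned down.

## Replication-study driver

`run_replication_study` simulates paired datasets and fits the requested
models to identical data, reporting per-replicate posterior medians, 95%
intervals and CVs (posterior SD / posterior mean) for survival, detection,
abundances and growth rates, plus aggregate bias, coverage and percent CV
reduction relative to the first (baseline) model. CVs are averaged across
replicates per model before the reduction is computed; a
`per_replicate_reduction` switch gives the reduce-then-average order.
Replicate seeds spawn deterministically from one master seed and finished
replicates checkpoint to JSON, making the driver restartable and
embarrassingly parallel.

## Problem sizes used by the test suite

The acceptance-level tests scale the replication experiments to desk size:
25 paired replicates with 2 chains × 6 000 sweeps (burn-in 1 500, thin 5)
for recovery and precision ordering, and 20 replicates at 2 × 4 000 for
goodness-of-fit calibration. The blocked-Gibbs sampler typically reaches
split-chain R-hat ≈ 1.00 within a few hundred sweeps on these designs, so
the reduced budgets affect Monte-Carlo noise rather than validity; the
bias test uses a Bonferroni-adjusted t-criterion across the nine monitored
quantities. Full-scale experiments (hundreds of replicates × 3 × 120 000
sweeps) run through the same driver unchanged.

## Known limitations

- Single `p` and `φ` (age-dependence only); no covariates, random effects
  or multi-state structure.
- Geographic closure is assumed when back-propagating known ages to
  presence in earlier years.
- The exact enumeration oracle is exponential in `M` and only serves tiny
  instances.
- Life-expectancy posteriors under near-one constant survival are dominated
  by the truncation age (see the terminal-mass diagnostic).
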