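"""MCMC fitting of the JS and age-structured JS models.

Sampling strategy
-----------------
The latent state of one individual is fully determined by the triple
(initial age x1, entry occasion, last occasion alive), so instead of
one-coordinate updates of the alive matrix the sampler draws each
individual's entire history from its categorical full conditional over the
feasible-history table.  Key structural facts exploited:

* Given the parameters, individuals are independent, and the conditional
  weight of a history depends on the data only through the first/last
  detection occasions, the number of detections (a constant shift, hence
  irrelevant), and a known-age constraint.  All observed individuals can
  therefore be updated in one vectorised Gumbel-argmax pass over a shared
  base-weight vector.
* Augmented never-detected individuals are exchangeable, so the whole block
  reduces to a single multinomial draw over {excluded} ∪ {included with
  history h}.
* Latent states of excluded individuals (w = 0) are marginalised out —
  their state-process likelihood integrates to one — so parameter updates
  count only included trajectories.  The invariant posterior over
  (parameters, inclusion, included histories) is unchanged.

Parameter updates are conjugate (Beta for psi, p and constant phi;
Dirichlet for beta and pi_prime given entry-occasion and year-1 age counts)
except the quadratic survival coefficients, which use per-coordinate
random-walk Metropolis on age-binned survival/death counts with step sizes
adapted during burn-in.

``enumerate_reference`` computes the exact posterior of (N_1..K, N*) at
fixed parameters on tiny instances by per-individual enumeration and
convolution; it is the correctness oracle for the Gibbs machinery.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from itertools import product as _iproduct

import numpy as np
from scipy.special import expit, logsumexp

from .model import (
    CaptureData,
    ConstantSurvival,
    LatentHistory,
    ParameterState,
    QuadraticSurvival,
    StudyDesign,
    ValidationError,
    feasible_histories,
    survival_at_age,
    trajectory_log_prob,
)

logger = logging.getLogger("agejs")

MODELS = ("js", "agejs_constant", "agejs_quadratic")

_TINY = 1e-300


@dataclass
class MCMCConfig:
    n_chains: int = 3
    n_iter: int = 120_000
    n_burnin: int = 20_000
    thin: int = 10
    seed: int = 0
    step_alpha: tuple[float, float, float] = (0.15, 0.08, 0.04)
    adapt: bool = True

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValidationError("n_chains must be >= 1")
        if not self.n_iter > self.n_burnin >= 0:
            raise ValidationError("need n_iter > n_burnin >= 0")
        if self.thin < 1:
            raise ValidationError("thin must be >= 1")


def case_study_mcmc() -> MCMCConfig:
    """The heavier preset used for the case-study fits (6 chains x 220k)."""
    return MCMCConfig(n_chains=6, n_iter=220_000, n_burnin=20_000, thin=10)


@dataclass
class Priors:
    """Vague priors: Beta(1,1) for p, psi and constant phi; Dirichlet(1) for
    beta and pi_prime; invlogit(alpha0) ~ Beta(1,1) (i.e. standard-logistic
    alpha0) and Normal(0, sd=10) for alpha1, alpha2."""

    psi: tuple[float, float] = (1.0, 1.0)
    p: tuple[float, float] = (1.0, 1.0)
    phi: tuple[float, float] = (1.0, 1.0)
    beta_conc: float = 1.0
    pi_conc: float = 1.0
    alpha_sd: float = 10.0


@dataclass
class PosteriorDraws:
    """Retained draws, one leading axis per chain then per retained sweep."""

    model: str
    design: StudyDesign
    mcmc: MCMCConfig
    draws: dict[str, np.ndarray]
    acceptance: dict[str, float] = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.draws["psi"].shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws["psi"].shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws for one quantity with chains concatenated."""
        a = self.draws[name]
        return a.reshape(-1, *a.shape[2:])

    def scalar_items(self):
        """Yield (name, (n_chains, n_draws) array) for every scalar quantity."""
        for name, a in self.draws.items():
            if a.ndim == 2:
                yield name, a
            elif a.ndim == 3:
                for j in range(a.shape[2]):
                    yield f"{name}_{j + 1}", a[:, :, j]


# ---------------------------------------------------------------------------
# history table
# ---------------------------------------------------------------------------


class _HistoryTable:
    """Precomputed per-history statistics shared by all individuals."""

    def __init__(self, design: StudyDesign, age_structured: bool):
        self.design = design
        self.age_structured = age_structured
        K, J = design.K, design.J
        self.A = design.max_age + 1  # age index 0..max_age

        hists: list[LatentHistory] = [LatentHistory(0, 0, 0)]  # never entered
        for entry in range(1, K + 1):
            x1_opts = range(1, J + 1) if (age_structured and entry == 1) else [0]
            for x1 in x1_opts:
                for last in range(entry, K + 1):
                    hists.append(LatentHistory(x1=x1, entry=entry, last=last))
        self.histories = hists
        H = len(hists)
        self.H = H

        self.entry = np.array([h.entry for h in hists])
        self.last = np.array([h.last for h in hists])
        self.x1 = np.array([h.x1 for h in hists])
        self.alive = np.zeros((H, K), dtype=bool)
        self.age = np.zeros((H, K), dtype=np.int64)
        self.S = np.zeros((H, self.A))        # survive-transition counts by age
        self.death_age = np.full(H, -1)
        for i, h in enumerate(hists):
            if h.entry == 0:
                continue
            start = h.x1 if h.entry == 1 else design.entry_age
            if not age_structured:
                start = design.entry_age
            for k in range(h.entry, K + 1):
                self.age[i, k - 1] = start + (k - h.entry)
                if k <= h.last:
                    self.alive[i, k - 1] = True
            for k in range(h.entry + 1, h.last + 1):
                self.S[i, self.age[i, k - 2]] += 1
            if h.last < K:
                self.death_age[i] = self.age[i, h.last - 1]
        self.n_alive = self.alive.sum(axis=1).astype(float)
        self.entry_idx = np.where(self.entry > 0, self.entry - 1, K)
        self.death_onehot = np.zeros((H, self.A))
        has_death = self.death_age >= 0
        self.death_onehot[np.flatnonzero(has_death), self.death_age[has_death]] = 1.0
        if age_structured:
            self.age_ind = np.zeros((H, K, self.A), dtype=np.int8)
            hh, kk = np.nonzero(self.alive)
            self.age_ind[hh, kk, self.age[hh, kk]] = 1
        else:
            self.age_ind = None

    def base_log_weights(self, params: dict) -> np.ndarray:
        """log P(history) + n_alive * log(1-p) per history (w=1, no detections)."""
        K = self.design.K
        beta = params["beta"]
        remaining = 1.0 - np.concatenate([[0.0], np.cumsum(beta)[:-1]])
        eta = np.where(remaining > _TINY, beta / np.maximum(remaining, _TINY), 0.0)
        eta = np.clip(eta, 0.0, 1.0)
        log_eta = np.log(np.clip(eta, _TINY, 1.0))
        log_1meta = np.log(np.clip(1.0 - eta, _TINY, 1.0))
        cum = np.concatenate([[0.0], np.cumsum(log_1meta)])

        entered = self.entry > 0
        lp = np.where(entered, cum[self.entry - 1] + log_eta[self.entry_idx % K], cum[K])
        if self.age_structured:
            log_pi = np.log(np.clip(params["pi_prime"], _TINY, 1.0))
            first = self.entry == 1
            lp = lp + np.where(first, log_pi[np.maximum(self.x1, 1) - 1], 0.0)

        phi_age = self._phi_by_age(params)
        log_phi = np.log(np.clip(phi_age, _TINY, 1.0))
        log_1mphi = np.log(np.clip(1.0 - phi_age, _TINY, 1.0))
        lp = lp + self.S @ log_phi + self.death_onehot @ log_1mphi
        lp = lp + self.n_alive * math.log(max(1.0 - params["p"], _TINY))
        return lp

    def _phi_by_age(self, params: dict) -> np.ndarray:
        ages = np.arange(self.A, dtype=float)
        if "phi" in params:
            return np.full(self.A, params["phi"])
        a0, a1, a2 = params["alpha"]
        d = ages - params["alpha_center"]
        return expit(a0 + a1 * d + a2 * d * d)


# ---------------------------------------------------------------------------
# fitting engine
# ---------------------------------------------------------------------------


class _Engine:
    def __init__(
        self,
        data: CaptureData,
        model: str,
        design: StudyDesign,
        priors: Priors,
    ):
        if model not in MODELS:
            raise ValidationError(f"unknown model {model!r}; choose one of {MODELS}")
        if design.M is None or design.M < data.n:
            raise ValidationError(
                f"augmentation size M={design.M} must be set and >= n_observed={data.n}"
            )
        self.model = model
        self.age_structured = model != "js"
        if self.age_structured:
            data.validate_against(design)
        self.data = data
        self.design = design
        self.priors = priors
        self.table = _HistoryTable(design, self.age_structured)

        t = self.table
        y = data.y
        first = np.argmax(y == 1, axis=1) + 1
        last = y.shape[1] - np.argmax(y[:, ::-1] == 1, axis=1)
        mask = (
            (t.entry[None, :] > 0)
            & (t.entry[None, :] <= first[:, None])
            & (t.last[None, :] >= last[:, None])
        )
        if self.age_structured:
            for i in range(data.n):
                k0, a0 = int(data.age_occasion[i]), int(data.age_value[i])
                if k0 < 0:
                    continue
                ok = t.alive[:, k0 - 1] & (t.age[:, k0 - 1] == a0)
                mask[i] &= ok
        if not mask.any(axis=1).all():
            i = int(np.argmin(mask.any(axis=1)))
            raise ValidationError(
                f"individual {data.ids[i]!r}: no latent history is consistent with its "
                f"detections and observed age under J={design.J}, entry_age={design.entry_age}"
            )
        self.obs_mask = mask
        self.n_aug = design.M - data.n
        self.total_det = float(y.sum())

    # -- initialisation ----------------------------------------------------

    def init_params(self, rng: np.random.Generator) -> dict:
        pr = self.priors
        params: dict = {
            "psi": rng.beta(*pr.psi),
            "p": rng.beta(*pr.p),
            "beta": rng.dirichlet(np.full(self.design.K, pr.beta_conc)),
        }
        if self.age_structured:
            params["pi_prime"] = rng.dirichlet(np.full(self.design.J, pr.pi_conc))
        if self.model == "agejs_quadratic":
            params["alpha"] = np.array(
                [rng.logistic(), rng.normal(0, 1.0), -abs(rng.normal(0, 0.1))]
            )
            params["alpha_center"] = self.alpha_center
        else:
            params["phi"] = rng.beta(*pr.phi)
        return params

    alpha_center: float = 5.0

    # -- one sweep ---------------------------------------------------------

    def sweep(self, params: dict, rng: np.random.Generator, step: np.ndarray,
              acc: np.ndarray, n_prop: np.ndarray, update_params: bool = True):
        t = self.table
        base = t.base_log_weights(params)

        # observed individuals: vectorised categorical via Gumbel argmax
        W = np.where(self.obs_mask, base[None, :], -np.inf)
        W = W + rng.gumbel(size=W.shape)
        h_obs = np.argmax(W, axis=1)
        c = np.bincount(h_obs, minlength=t.H).astype(float)

        # augmented block: one multinomial over {excluded} + histories
        n_w1_aug = 0
        if self.n_aug > 0:
            psi = min(max(params["psi"], _TINY), 1 - 1e-12)
            logq = np.concatenate([[math.log1p(-psi)], math.log(psi) + base])
            probs = np.exp(logq - logsumexp(logq))
            probs /= probs.sum()
            counts = rng.multinomial(self.n_aug, probs)
            c += counts[1:]
            n_w1_aug = int(self.n_aug - counts[0])

        n_w1 = self.data.n + n_w1_aug
        stats = {"c": c, "n_w1": n_w1, "Nstar": n_w1}
        if update_params:
            self._update_params(params, stats, rng, step, acc, n_prop)
        return stats

    def _update_params(self, params, stats, rng, step, acc, n_prop):
        t, pr, des = self.table, self.priors, self.design
        c, n_w1 = stats["c"], stats["n_w1"]
        M = des.M
        params["psi"] = rng.beta(pr.psi[0] + n_w1, pr.psi[1] + M - n_w1)
        exposure = float(c @ t.n_alive)
        params["p"] = rng.beta(
            pr.p[0] + self.total_det, pr.p[1] + max(exposure - self.total_det, 0.0)
        )
        entry_counts = np.bincount(t.entry_idx, weights=c, minlength=des.K + 1)[: des.K]
        params["beta"] = rng.dirichlet(pr.beta_conc + entry_counts)
        if self.age_structured:
            x1_counts = np.bincount(t.x1, weights=c, minlength=des.J + 1)[1:]
            params["pi_prime"] = rng.dirichlet(pr.pi_conc + x1_counts)

        sv_age = c @ t.S
        dt_age = c @ t.death_onehot
        if "phi" in params:
            params["phi"] = rng.beta(pr.phi[0] + sv_age.sum(), pr.phi[1] + dt_age.sum())
        else:
            self._update_alpha(params, sv_age, dt_age, rng, step, acc, n_prop)

    def _update_alpha(self, params, sv_age, dt_age, rng, step, acc, n_prop):
        used = (sv_age + dt_age) > 0
        ages = np.flatnonzero(used).astype(float)
        sv, dt = sv_age[used], dt_age[used]
        d = ages - params["alpha_center"]
        X = np.stack([np.ones_like(d), d, d * d], axis=1)

        def loglik(alpha):
            lin = X @ alpha
            # binomial log-likelihood on the logit scale, stable for |lin| large
            return float(np.sum(sv * (-np.logaddexp(0.0, -lin)) + dt * (-np.logaddexp(0.0, lin))))

        def logprior(alpha):
            lp = -np.logaddexp(0.0, alpha[0]) - np.logaddexp(0.0, -alpha[0])
            lp -= 0.5 * (alpha[1] ** 2 + alpha[2] ** 2) / self.priors.alpha_sd**2
            return float(lp)

        alpha = params["alpha"].copy()
        cur = loglik(alpha) + logprior(alpha)
        for j in range(3):
            prop = alpha.copy()
            prop[j] += rng.normal(0.0, step[j])
            new = loglik(prop) + logprior(prop)
            n_prop[j] += 1
            if math.log(rng.random() + _TINY) < new - cur:
                alpha, cur = prop, new
                acc[j] += 1
        params["alpha"] = alpha


def _run_chain(engine: _Engine, mcmc: MCMCConfig, rng: np.random.Generator,
               chain_id: int) -> tuple[dict, np.ndarray]:
    params = engine.init_params(rng)
    step = np.array(mcmc.step_alpha, dtype=float)
    acc = np.zeros(3)
    n_prop = np.zeros(3)
    n_ret = (mcmc.n_iter - mcmc.n_burnin + mcmc.thin - 1) // mcmc.thin
    des, t = engine.design, engine.table

    out: dict[str, np.ndarray] = {
        "psi": np.empty(n_ret),
        "p": np.empty(n_ret),
        "beta": np.empty((n_ret, des.K)),
        "N": np.empty((n_ret, des.K)),
        "Nstar": np.empty(n_ret),
    }
    if engine.age_structured:
        out["pi_prime"] = np.empty((n_ret, des.J))
        out["Nkj"] = np.empty((n_ret, des.K, t.A))
    if engine.model == "agejs_quadratic":
        out["alpha"] = np.empty((n_ret, 3))
    else:
        out["phi"] = np.empty(n_ret)

    marks = {int(mcmc.n_iter * q / 10) for q in range(1, 11)}
    r = 0
    for it in range(mcmc.n_iter):
        stats = engine.sweep(params, rng, step, acc, n_prop)
        if mcmc.adapt and it < mcmc.n_burnin and it and it % 100 == 0 and n_prop[0] > 0:
            rate = acc / np.maximum(n_prop, 1)
            step *= np.where(rate > 0.45, 1.3, np.where(rate < 0.2, 1 / 1.3, 1.0))
            acc[:] = 0
            n_prop[:] = 0
        if it >= mcmc.n_burnin and (it - mcmc.n_burnin) % mcmc.thin == 0:
            out["psi"][r] = params["psi"]
            out["p"][r] = params["p"]
            out["beta"][r] = params["beta"]
            out["N"][r] = stats["c"] @ t.alive
            out["Nstar"][r] = stats["Nstar"]
            if engine.age_structured:
                out["pi_prime"][r] = params["pi_prime"]
                out["Nkj"][r] = np.tensordot(stats["c"], t.age_ind, axes=([0], [0]))
            if "alpha" in params:
                out["alpha"][r] = params["alpha"]
            else:
                out["phi"][r] = params["phi"]
            r += 1
        if it + 1 in marks:
            logger.info("chain %d: %d/%d sweeps", chain_id, it + 1, mcmc.n_iter)
    rates = acc / np.maximum(n_prop, 1)
    return out, rates


def fit(
    data: CaptureData,
    model: str,
    design: StudyDesign,
    priors: Priors | None = None,
    mcmc: MCMCConfig | None = None,
    alpha_center: float | None = None,
) -> PosteriorDraws:
    """Fit one of the three models by MCMC and return retained draws.

    ``model`` is one of ``"js"`` (ageless), ``"agejs_constant"`` or
    ``"agejs_quadratic"``.  If ``design.M`` is None it defaults to three
    times the number of observed individuals.  ``alpha_center`` sets the
    age-centering constant of the quadratic survival model.
    """
    priors = priors or Priors()
    mcmc = mcmc or MCMCConfig()
    if design.M is None:
        design = replace(design, M=3 * data.n)
    engine = _Engine(data, model, design, priors)
    if alpha_center is not None:
        engine.alpha_center = float(alpha_center)

    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
    chains = []
    rates = []
    for ci, ss in enumerate(seeds):
        out, rate = _run_chain(engine, mcmc, np.random.default_rng(ss), ci)
        chains.append(out)
        rates.append(rate)
    draws = {k: np.stack([ch[k] for ch in chains]) for k in chains[0]}
    acceptance = {}
    if model == "agejs_quadratic":
        mean_rate = np.mean(rates, axis=0)
        acceptance = {f"alpha{j}": float(mean_rate[j]) for j in range(3)}

    post = PosteriorDraws(model=model, design=design, mcmc=mcmc, draws=draws,
                          acceptance=acceptance)
    pr_full = float((post.stacked("Nstar") > 0.95 * design.M).mean())
    if pr_full > 0.05:
        warnings.warn(
            f"posterior mass near the augmentation ceiling (Pr(N* > 0.95 M) = "
            f"{pr_full:.3f}); increase M",
            stacklevel=2,
        )
    return post


def sample_latent_fixed_params(
    data: CaptureData,
    params: ParameterState,
    design: StudyDesign,
    n_sweeps: int,
    seed: int = 0,
    burnin: int = 0,
) -> dict[str, np.ndarray]:
    """Gibbs-sample latent states with all parameters held fixed.

    Returns per-sweep draws of N (n_sweeps x K) and N*; used to check the
    latent machinery against :func:`enumerate_reference`.
    """
    model = "js" if params.pi_prime is None else (
        "agejs_constant" if isinstance(params.survival, ConstantSurvival) else "agejs_quadratic"
    )
    engine = _Engine(data, model, design, Priors())
    pd: dict = {"psi": params.psi, "p": params.p, "beta": params.beta}
    if params.pi_prime is not None:
        pd["pi_prime"] = params.pi_prime
    if isinstance(params.survival, ConstantSurvival):
        pd["phi"] = params.survival.phi
    else:
        pd["alpha"] = np.array(
            [params.survival.alpha0, params.survival.alpha1, params.survival.alpha2]
        )
        pd["alpha_center"] = params.survival.center
    rng = np.random.default_rng(seed)
    dummy = np.zeros(3)
    N = np.empty((n_sweeps, design.K))
    Nstar = np.empty(n_sweeps)
    for s in range(burnin + n_sweeps):
        stats = engine.sweep(pd, rng, dummy, dummy, dummy, update_params=False)
        if s >= burnin:
            N[s - burnin] = stats["c"] @ engine.table.alive
            Nstar[s - burnin] = stats["Nstar"]
    return {"N": N, "Nstar": Nstar}


# ---------------------------------------------------------------------------
# exact enumeration oracle
# ---------------------------------------------------------------------------


def enumerate_reference(
    data: CaptureData,
    params: ParameterState,
    design: StudyDesign,
    guard: float = 1e7,
) -> dict[tuple, float]:
    """Exact joint distribution of (N_1..K, N*) at fixed parameters.

    Exploits independence across individuals: the per-individual posterior
    over (w, history) is enumerated from :func:`feasible_histories` and
    :func:`trajectory_log_prob`, then distributions of the alive-vector are
    convolved.  Refuses when the full latent configuration space exceeds
    ``guard`` (the cost proxy is the product of per-individual support
    sizes).
    """
    if design.M is None or design.M < data.n:
        raise ValidationError("design.M must be set and >= n_observed")
    K = design.K
    zero_row = np.zeros(K, dtype=int)
    full_set = feasible_histories(zero_row, design)

    supports = []
    log_size = 0.0
    for i in range(data.n):
        use_age = params.pi_prime is not None
        hset = feasible_histories(
            data.y[i], design,
            age_occasion=int(data.age_occasion[i]) if use_age else -1,
            age_value=int(data.age_value[i]) if use_age else -1,
        )
        supports.append((data.y[i], hset, True))
        log_size += math.log(max(len(hset), 1))
    n_aug = design.M - data.n
    log_size += n_aug * math.log(len(full_set) + 1)
    if log_size > math.log(guard):
        raise ValidationError(
            f"latent configuration space ~exp({log_size:.1f}) exceeds guard {guard:g}"
        )

    def individual_dist(y_i, hset, observed):
        d: dict[tuple, float] = {}
        for h in hset:
            lp = trajectory_log_prob(h, y_i, params, design, w=1)
            if lp == -math.inf:
                continue
            key = tuple(int(h.alive_at(k)) for k in range(1, K + 1)) + (1,)
            d[key] = d.get(key, 0.0) + math.exp(lp)
        if not observed:
            d[(0,) * K + (0,)] = 1.0 - params.psi  # w = 0, state marginalised
        tot = sum(d.values())
        return {k: v / tot for k, v in d.items()}

    dist: dict[tuple, float] = {(0,) * (K + 1): 1.0}

    def convolve(dist, di, times=1):
        for _ in range(times):
            new: dict[tuple, float] = {}
            for s, ps in dist.items():
                for u, pu in di.items():
                    key = tuple(a + b for a, b in zip(s, u))
                    new[key] = new.get(key, 0.0) + ps * pu
            dist = new
        return dist

    for y_i, hset, obs in supports:
        dist = convolve(dist, individual_dist(y_i, hset, obs))
    if n_aug:
        aug_dist = individual_dist(zero_row, full_set, observed=False)
        dist = convolve(dist, aug_dist, times=n_aug)
    return dist


def marginal_of(dist: dict[tuple, float], index: int) -> dict[int, float]:
    """Marginal distribution of one component of the (N_1..K, N*) tuple."""
    out: dict[int, float] = {}
    for key, p in dist.items():
        out[key[index]] = out.get(key[index], 0.0) + p
    return out


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------


def gelman_rubin(chains: np.ndarray) -> float:
    """Classic split-chain potential scale reduction factor.

    ``chains`` has shape (n_chains, n_draws).  Each chain is split in half
    (an odd final draw is dropped), then R-hat = sqrt(((n-1)/n W + B/n)/W)
    with W the mean within-half-chain variance and B = n * var(half-chain
    means).  Both variances zero returns 1.0 by convention.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2:
        raise ValidationError("chains must be a 2-d (n_chains, n_draws) array")
    if x.shape[0] < 2:
        raise ValidationError("R-hat needs >= 2 chains; run more chains")
    n = x.shape[1] // 2
    if n < 2:
        raise ValidationError("chains too short to split for R-hat")
    halves = np.concatenate([x[:, :n], x[:, n : 2 * n]], axis=0)
    W = halves.var(axis=1, ddof=1).mean()
    B = n * halves.mean(axis=1).var(ddof=1)
    if W == 0.0:
        return 1.0 if B == 0.0 else math.inf
    var_plus = (n - 1) / n * W + B / n
    return math.sqrt(var_plus / W)


def rhat_table(post: PosteriorDraws) -> dict[str, float]:
    """Split-chain R-hat for every scalar quantity in a posterior."""
    if post.n_chains < 2:
        raise ValidationError("R-hat needs >= 2 chains; run more chains")
    return {name: gelman_rubin(a) for name, a in post.scalar_items()}
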