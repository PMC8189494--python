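"""Derived demographic quantities and goodness-of-fit.

All functions here are per-draw transforms of retained posterior samples —
no re-estimation happens.  Abundance N_k and the superpopulation N* come
straight from the sampler; growth rates, annual age structure, the
prime-breeding-age proportion, survivorship curves and life expectancy are
computed draw by draw so that their posterior uncertainty propagates
exactly.  The posterior-predictive check replays the number of individuals
observed each year through a Binomial(N_k, p) kernel and scores observed
versus replicated counts with the Freeman-Tukey discrepancy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd

from .model import CaptureData, SurvivalModel, ValidationError, survival_at_age
from .sampler import PosteriorDraws, gelman_rubin


class UnsupportedModelError(ValidationError):
    """Raised when an age-structured quantity is requested from an ageless fit."""


@dataclass
class DerivedSeries:
    """Per-draw derived series; leading axes are (chain, draw)."""

    N: np.ndarray                      # (..., K)
    Nstar: np.ndarray                  # (...,)
    growth: np.ndarray                 # (..., K-1), lambda_k = N_{k+1} / N_k
    age_prop: np.ndarray | None = None   # (..., K, A), N_kj / N_k
    prime_prop: np.ndarray | None = None  # (..., K)


def derive_series(
    post: PosteriorDraws, prime_age_range: tuple[int, int] | None = None
) -> DerivedSeries:
    """Growth rates, age-structure proportions and the prime-age proportion.

    ``prime_age_range`` is an inclusive (lo, hi) age band; requesting it (or
    any age-structure output) from an ageless JS fit raises
    :class:`UnsupportedModelError`.
    """
    N = post.draws["N"]
    Nstar = post.draws["Nstar"]
    with np.errstate(divide="ignore", invalid="ignore"):
        growth = np.where(N[..., :-1] > 0, N[..., 1:] / np.maximum(N[..., :-1], 1e-300), np.nan)

    age_prop = prime_prop = None
    if post.model == "js":
        if prime_age_range is not None:
            raise UnsupportedModelError(
                "age structure is not defined for the ageless JS model; "
                "fit agejs_constant or agejs_quadratic"
            )
    else:
        Nkj = post.draws["Nkj"]
        denom = np.maximum(N[..., None], 1e-300)
        age_prop = np.where(N[..., None] > 0, Nkj / denom, np.nan)
        if prime_age_range is not None:
            lo, hi = prime_age_range
            if not 0 <= lo <= hi:
                raise ValidationError("prime_age_range must satisfy 0 <= lo <= hi")
            hi = min(hi, Nkj.shape[-1] - 1)
            band = Nkj[..., lo : hi + 1].sum(axis=-1)
            prime_prop = np.where(N > 0, band / np.maximum(N, 1e-300), np.nan)
    return DerivedSeries(N=N, Nstar=Nstar, growth=growth, age_prop=age_prop,
                         prime_prop=prime_prop)


def _phi_at(age: int, survival: SurvivalModel) -> np.ndarray:
    return np.atleast_1d(np.asarray(survival_at_age(age, survival), dtype=float))


def cumulative_survival(
    survival: SurvivalModel, from_age: int = 2, to_age: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Survivorship S(a) = prod_{u=from_age}^{a-1} phi_u, with S(from_age) = 1.

    Survival parameters may be posterior-draw arrays, in which case the
    returned curve has one row per draw.  Returns ``(ages, S)`` with ``ages``
    running from ``from_age`` to ``to_age`` and ``S`` of shape
    ``(n_draws, len(ages))`` (``n_draws = 1`` for scalar parameters).
    """
    if to_age < from_age:
        raise ValidationError("to_age must be >= from_age")
    ages = np.arange(from_age, to_age + 1)
    n_draws = _phi_at(from_age, survival).shape[0]
    phis = np.stack([_phi_at(a, survival) for a in ages[:-1]], axis=-1) \
        if len(ages) > 1 else np.ones((n_draws, 0))
    S = np.concatenate(
        [np.ones((*phis.shape[:-1], 1)), np.cumprod(phis, axis=-1)], axis=-1
    )
    return ages, S


def life_expectancy(
    survival: SurvivalModel, from_age: int = 2, max_age: int = 40
) -> tuple[np.ndarray, np.ndarray]:
    """Expected age at death, conditional on surviving to ``from_age``.

    Death at age j carries mass theta_j = prod_{a=from_age}^{j-1} phi_a *
    (1 - phi_j); survivorship beyond the truncation point is assigned to
    death at ``max_age`` so the masses sum to one.  Returns
    ``(life_expectancy, terminal_mass)`` per draw; a warning reports when
    the terminal mass exceeds 0.01 (truncation-sensitive estimates).
    """
    if max_age < from_age:
        raise ValidationError("max_age must be >= from_age")
    ages, S = cumulative_survival(survival, from_age, max_age)
    phi = np.stack([_phi_at(a, survival) for a in ages], axis=-1)
    theta = S * (1.0 - phi)
    terminal = S[..., -1] * phi[..., -1]
    le = (theta * ages).sum(axis=-1) + terminal * max_age
    frac = float(np.mean(terminal > 0.01))
    if frac > 0:
        warnings.warn(
            f"life expectancy truncated at age {max_age}: terminal survivorship mass "
            f"> 0.01 in {100 * frac:.1f}% of draws",
            stacklevel=2,
        )
    return le, terminal


@dataclass
class FreemanTukeyResult:
    d_obs: np.ndarray
    d_rep: np.ndarray
    p_value: float


def freeman_tukey(
    n_obs_k: np.ndarray, p_draws: np.ndarray, N_draws: np.ndarray, seed: int = 0
) -> FreemanTukeyResult:
    """Freeman-Tukey posterior-predictive discrepancy on annual observed counts.

    Per draw, the expected count is ``p * N_k`` and a replicate is drawn as
    ``Binomial(N_k, p)``; both observed and replicated counts are scored
    with D(v) = sum_k (sqrt(v_k) - sqrt(p N_k))^2.  The Bayesian p-value is
    the fraction of draws with D(replicate) >= D(observed).
    """
    rng = np.random.default_rng(seed)
    n_obs_k = np.asarray(n_obs_k, dtype=float)
    expected = p_draws[:, None] * N_draws
    n_rep = rng.binomial(np.round(N_draws).astype(np.int64), p_draws[:, None]).astype(float)
    d_obs = ((np.sqrt(n_obs_k[None, :]) - np.sqrt(expected)) ** 2).sum(axis=1)
    d_rep = ((np.sqrt(n_rep) - np.sqrt(expected)) ** 2).sum(axis=1)
    return FreemanTukeyResult(
        d_obs=d_obs, d_rep=d_rep, p_value=float((d_rep >= d_obs).mean())
    )


def freeman_tukey_check(
    post: PosteriorDraws, data: CaptureData, seed: int = 0
) -> FreemanTukeyResult:
    """Posterior-predictive check of a fit against its data (see :func:`freeman_tukey`)."""
    return freeman_tukey(data.y.sum(axis=0), post.stacked("p"), post.stacked("N"), seed)


def summarize_columns(columns: dict[str, np.ndarray]) -> pd.DataFrame:
    """Summary table from named (n_chains, n_draws) arrays.

    Quantiles use linear interpolation between order statistics (numpy's
    default), so intervals are reproducible across runs.  One row per
    quantity, in input order.
    """
    rows = []
    for name, chains in columns.items():
        chains = np.asarray(chains, dtype=float)
        flat = chains.reshape(-1)
        flat = flat[np.isfinite(flat)]
        if flat.size == 0:
            continue
        med, lo, hi = np.percentile(flat, [50.0, 2.5, 97.5])
        rhat = ess = np.nan
        if chains.shape[0] >= 2 and chains.shape[1] >= 4:
            rhat = gelman_rubin(chains)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ess = float(az.ess(np.ascontiguousarray(chains)))
        rows.append({"quantity": name, "median": med, "q2.5": lo, "q97.5": hi,
                     "rhat": rhat, "ess": ess})
    return pd.DataFrame(rows)


def summarize(post: PosteriorDraws, derived: DerivedSeries | None = None) -> pd.DataFrame:
    """Posterior medians, 95% credible intervals, R-hat and effective sample size."""
    cols: dict[str, np.ndarray] = dict(post.scalar_items())
    if derived is not None:
        for k in range(derived.growth.shape[-1]):
            cols[f"lambda_{k + 1}"] = derived.growth[..., k]
        if derived.prime_prop is not None:
            for k in range(derived.prime_prop.shape[-1]):
                cols[f"prime_prop_{k + 1}"] = derived.prime_prop[..., k]
    return summarize_columns(cols)
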