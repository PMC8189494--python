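"""Synthetic capture-recapture + age data under the age-structured JS model.

The generator draws a superpopulation of exactly ``N_star`` individuals,
allocates each to an entry occasion by a multinomial over the entry simplex
``beta`` (occasion-1 entrants receive a categorical initial age from
``pi_prime``; later recruits enter at ``entry_age``), runs Bernoulli
survival forward with the age-appropriate annual survival, and applies
Bernoulli detection with probability ``p`` at every alive occasion.  The
truth (latent states, realised abundances and age structure) is retained so
recovery tests can compare posteriors against the generating process.

Two stock configurations mirror a medium-duration study of a long-lived
species: 400 individuals over 7 occasions, entry mass 0.4 then 0.1 per year,
9 initial age classes, detection 0.25, and survival either constant at 0.85
or a logit-quadratic in age centred at 5 years (0.63 at age 1, peaking at
0.88 at age 4, collapsing to 0.03 by age 9 — a senescent curve).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from typing import Sequence

import numpy as np
from scipy.special import logit

from .model import (
    CaptureData,
    ConstantSurvival,
    QuadraticSurvival,
    StudyDesign,
    SurvivalModel,
    ValidationError,
    _check_simplex,
    survival_at_age,
)


@dataclass
class SimConfig:
    N_star: int
    design: StudyDesign
    beta: np.ndarray
    survival: SurvivalModel
    p: float
    pi_prime: np.ndarray | None = None
    missing_age_fraction: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.N_star < 1:
            raise ValidationError(f"N_star must be >= 1, got {self.N_star}")
        self.beta = _check_simplex(self.beta, "beta")
        if self.beta.size != self.design.K:
            raise ValidationError("beta must have one entry per occasion")
        if self.pi_prime is not None:
            self.pi_prime = _check_simplex(self.pi_prime, "pi_prime")
            if self.pi_prime.size != self.design.J:
                raise ValidationError("pi_prime must have one entry per initial age class")
        if not 0.0 <= self.p <= 1.0:
            raise ValidationError(f"p must lie in [0, 1], got {self.p}")
        if not 0.0 <= self.missing_age_fraction <= 1.0:
            raise ValidationError("missing_age_fraction must lie in [0, 1]")


@dataclass
class SimTruth:
    """Generating configuration plus realised latent states for all N_star individuals."""

    config: SimConfig
    entry: np.ndarray      # entry occasion per individual (1-based)
    x1: np.ndarray         # age at occasion 1 (0 if not present then)
    z: np.ndarray          # alive matrix, N_star x K
    x: np.ndarray          # age matrix, N_star x K (increments once entered)
    N: np.ndarray          # realised annual abundance
    N_star: int            # realised superpopulation size (== config.N_star)
    Nkj: np.ndarray        # realised alive-by-age counts, K x (max_age + 1)

    def to_json(self) -> str:
        d = {
            "config": _config_to_dict(self.config),
            "entry": self.entry.tolist(),
            "x1": self.x1.tolist(),
            "z": self.z.tolist(),
            "x": self.x.tolist(),
            "N": self.N.tolist(),
            "N_star": int(self.N_star),
            "Nkj": self.Nkj.tolist(),
        }
        return json.dumps(d)


def _config_to_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["beta"] = cfg.beta.tolist()
    if cfg.pi_prime is not None:
        d["pi_prime"] = cfg.pi_prime.tolist()
    d["survival"] = {"kind": "constant", "phi": cfg.survival.phi} \
        if isinstance(cfg.survival, ConstantSurvival) else {
            "kind": "quadratic",
            "alpha0": cfg.survival.alpha0,
            "alpha1": cfg.survival.alpha1,
            "alpha2": cfg.survival.alpha2,
            "center": cfg.survival.center,
        }
    d["design"] = {
        "K": cfg.design.K, "J": cfg.design.J,
        "entry_age": cfg.design.entry_age, "M": cfg.design.M,
    }
    return d


def config_from_dict(d: dict) -> SimConfig:
    """Rebuild a SimConfig from its JSON/YAML dictionary form."""
    s = d["survival"]
    survival: SurvivalModel
    if s["kind"] == "constant":
        survival = ConstantSurvival(phi=float(s["phi"]))
    elif s["kind"] == "quadratic":
        survival = QuadraticSurvival(
            alpha0=float(s["alpha0"]), alpha1=float(s["alpha1"]),
            alpha2=float(s["alpha2"]), center=float(s.get("center", 5.0)),
        )
    else:
        raise ValidationError(f"unknown survival kind {s['kind']!r}")
    dd = d["design"]
    design = StudyDesign(
        K=int(dd["K"]), J=int(dd["J"]),
        entry_age=int(dd.get("entry_age", 1)), M=dd.get("M"),
    )
    return SimConfig(
        N_star=int(d["N_star"]), design=design,
        beta=np.asarray(d["beta"], dtype=float), survival=survival,
        p=float(d["p"]),
        pi_prime=np.asarray(d["pi_prime"], dtype=float) if d.get("pi_prime") is not None else None,
        missing_age_fraction=float(d.get("missing_age_fraction", 0.0)),
        seed=d.get("seed"),
    )


def default_configs() -> tuple[SimConfig, SimConfig]:
    """The two stock simulation regimes (constant and age-specific survival)."""
    design = StudyDesign(K=7, J=9, entry_age=1)
    beta = np.array([0.4, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1])
    pi_prime = np.array([0.27, 0.17, 0.14, 0.12, 0.11, 0.09, 0.06, 0.03, 0.01])
    common = dict(N_star=400, design=design, beta=beta, pi_prime=pi_prime, p=0.25)
    constant = SimConfig(survival=ConstantSurvival(phi=0.85), **common)
    age_specific = SimConfig(
        survival=QuadraticSurvival(
            alpha0=float(logit(0.85)), alpha1=-0.5, alpha2=-0.20, center=5.0
        ),
        **common,
    )
    return constant, age_specific


def simulate_dataset(
    config: SimConfig, seed: int | None = None
) -> tuple[CaptureData, SimTruth]:
    """Draw one dataset; returns observed captures and full latent truth.

    ``seed`` overrides ``config.seed``.  Ages are attached at first capture
    and then masked at ``missing_age_fraction`` (exact-count masking).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    des = config.design
    N, K = config.N_star, des.K

    entry = rng.choice(np.arange(1, K + 1), size=N, p=config.beta)
    x1 = np.zeros(N, dtype=np.int64)
    first_mask = entry == 1
    if config.pi_prime is not None:
        x1[first_mask] = rng.choice(
            np.arange(1, des.J + 1), size=int(first_mask.sum()), p=config.pi_prime
        )
    else:
        x1[first_mask] = des.entry_age

    z = np.zeros((N, K), dtype=np.int8)
    x = np.zeros((N, K), dtype=np.int64)
    alive = np.zeros(N, dtype=bool)
    for k in range(1, K + 1):
        entering = entry == k
        x[entering, k - 1] = np.where(k == 1, x1[entering], des.entry_age)
        if k > 1:
            entered_before = (entry < k) & (x[:, k - 2] > 0)
            x[entered_before, k - 1] = x[entered_before, k - 2] + 1  # ages tick even after death
            phi_prev = np.asarray(survival_at_age(x[alive, k - 2], config.survival))
            survived = rng.random(phi_prev.shape) < phi_prev
            alive[np.flatnonzero(alive)[~survived]] = False
        alive |= entering
        z[alive, k - 1] = 1

    y_all = (rng.random((N, K)) < config.p).astype(np.int8) * z
    Nk = z.sum(axis=0)
    max_age = des.max_age
    Nkj = np.zeros((K, max_age + 1), dtype=np.int64)
    for k in range(K):
        idx = z[:, k] == 1
        np.add.at(Nkj[k], x[idx, k], 1)

    observed = np.flatnonzero(y_all.sum(axis=1) > 0)
    ids = [f"ind{i + 1}" for i in observed]
    y_obs = y_all[observed]
    first_cap = np.argmax(y_obs == 1, axis=1) + 1
    age_occ = first_cap.astype(np.int64)
    age_val = x[observed, first_cap - 1].astype(np.int64)
    data = CaptureData(ids=ids, y=y_obs, age_occasion=age_occ, age_value=age_val)
    if config.missing_age_fraction > 0:
        data = mask_ages(data, config.missing_age_fraction, seed=int(rng.integers(2**31)))

    truth = SimTruth(
        config=config, entry=entry, x1=x1, z=z, x=x,
        N=Nk, N_star=N, Nkj=Nkj,
    )
    return data, truth


def mask_ages(data: CaptureData, fraction: float, seed: int | None = None) -> CaptureData:
    """Set a uniformly chosen exact fraction (floor(fraction * n)) of ages to missing."""
    if not 0.0 <= fraction <= 1.0:
        raise ValidationError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_mask = int(np.floor(fraction * data.n))
    chosen = rng.choice(data.n, size=n_mask, replace=False)
    age_occ = data.age_occasion.copy()
    age_val = data.age_value.copy()
    age_occ[chosen] = -1
    age_val[chosen] = -1
    return CaptureData(
        ids=list(data.ids), y=data.y.copy(), age_occasion=age_occ, age_value=age_val
    )
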