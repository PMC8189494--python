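"""Shared fixtures and independent brute-force oracles.

The oracles below enumerate raw latent configurations (inclusion w, initial
age x1, alive vector z) and evaluate the generative kernels sequentially —
deliberately *not* via the package's history parameterisation — so they can
serve as an independent check of the feasible-history enumeration, the
trajectory log-probability, and the exact reference distribution.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pytest

from agejs import (
    CaptureData,
    ConstantSurvival,
    ParameterState,
    StudyDesign,
    compose_initial_age_dist,
    survival_at_age,
)


def brute_force_config_prob(w, x1, z, y, params, design):
    """Probability of one raw latent configuration and detection row.

    Walks the state equations occasion by occasion: occasion-1 age category
    (mixing 'not yet entered' with the initial age distribution), entry via
    the conditional entry probabilities, survival at the age held the year
    before, deterministic ageing, and Bernoulli detection gated by z*w.
    """
    K, J = design.K, design.J
    eta = params.eta
    psi, p = params.psi, params.p
    prob = psi if w == 1 else 1.0 - psi

    if params.pi_prime is not None:
        pi_mix = compose_initial_age_dist(eta[0], params.pi_prime)
        if (z[0] == 1) != (x1 > 0):
            return 0.0  # occasion-1 state is a deterministic function of age
        prob *= pi_mix[x1]
    else:
        if x1 != 0:
            return 0.0
        prob *= eta[0] if z[0] == 1 else 1.0 - eta[0]

    x_prev = x1 if params.pi_prime is not None else (design.entry_age if z[0] else 0)
    entered = z[0] == 1
    for k in range(2, K + 1):
        if z[k - 2] == 1:
            phi = float(survival_at_age(x_prev, params.survival))
            prob *= phi if z[k - 1] == 1 else 1.0 - phi
        elif not entered:
            prob *= eta[k - 1] if z[k - 1] == 1 else 1.0 - eta[k - 1]
        elif z[k - 1] == 1:
            return 0.0  # no re-entry after death
        if entered:
            x_prev += 1  # ages tick deterministically once entered
        elif z[k - 1] == 1:
            x_prev = design.entry_age
            entered = True

    # redo age walk to apply detection with the correct alive state
    for k in range(1, K + 1):
        pk = p if (z[k - 1] == 1 and w == 1) else 0.0
        prob *= pk if y[k - 1] == 1 else 1.0 - pk
    return prob


def brute_force_marginal(y, params, design):
    """Marginal P(y) for one individual, summing over all raw configurations."""
    K, J = design.K, design.J
    x1_range = range(J + 1) if params.pi_prime is not None else [0]
    total = 0.0
    for w in (0, 1):
        for x1 in x1_range:
            for z in product((0, 1), repeat=K):
                total += brute_force_config_prob(w, x1, z, y, params, design)
    return total


def brute_force_joint(data: CaptureData, params, design):
    """Exact joint posterior of (N_1..K, N*) by raw enumeration + convolution."""
    K = design.K
    x1_range = range(design.J + 1) if params.pi_prime is not None else [0]

    def individual(y_i, observed):
        d = {}
        for w in ((1,) if observed else (0, 1)):
            for x1 in x1_range:
                for z in product((0, 1), repeat=K):
                    pr = brute_force_config_prob(w, x1, z, y_i, params, design)
                    if pr > 0:
                        key = tuple(zi * w for zi in z) + (w,)
                        d[key] = d.get(key, 0.0) + pr
        tot = sum(d.values())
        return {k: v / tot for k, v in d.items()}

    dist = {(0,) * (K + 1): 1.0}
    zero = np.zeros(K, dtype=int)
    parts = [(data.y[i], True) for i in range(data.n)]
    parts += [(zero, False)] * ((design.M or data.n) - data.n)
    for y_i, obs in parts:
        di = individual(y_i, obs)
        new = {}
        for s, ps in dist.items():
            for u, pu in di.items():
                key = tuple(a + b for a, b in zip(s, u))
                new[key] = new.get(key, 0.0) + ps * pu
        dist = new
    return dist


def total_variation(d1: dict, d2: dict) -> float:
    keys = set(d1) | set(d2)
    return 0.5 * sum(abs(d1.get(k, 0.0) - d2.get(k, 0.0)) for k in keys)


@pytest.fixture
def tiny_design() -> StudyDesign:
    return StudyDesign(K=2, J=2, M=4)


@pytest.fixture
def tiny_params() -> ParameterState:
    return ParameterState(
        psi=0.5,
        p=0.25,
        beta=np.array([0.4, 0.6]),
        survival=ConstantSurvival(0.85),
        pi_prime=np.array([0.6, 0.4]),
    )


@pytest.fixture
def tiny_data() -> CaptureData:
    return CaptureData(
        ids=["a", "b"],
        y=np.array([[1, 0], [1, 1]]),
        age_occasion=np.array([1, -1]),
        age_value=np.array([1, -1]),
    )
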