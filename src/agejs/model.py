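"""Core probability kernels for the age-structured Jolly-Seber (JS) model.

The superpopulation JS formulation augments the observed individuals to M
pseudo-individuals, each with an inclusion indicator ``w ~ Bernoulli(psi)``.
Included individuals enter the population at one of K occasions according to
entry probabilities ``beta`` (a simplex), survive between occasions with
probability ``phi`` (constant, or a quadratic-in-age function on the logit
scale), and are detected with probability ``p`` while alive.  The
age-structured extension assigns each individual present at occasion 1 an
initial age drawn from ``pi_prime`` over ages ``1..J`` (J is the maximum
possible age in year 1); ages then increment deterministically by one per
occasion.  Within-study recruits enter at model age ``entry_age``
(default 1).

This module holds the exact single-individual kernels — the conditional
entry transform, the initial-age mixture, the survival link, the enumeration
of latent histories consistent with a detection row, and the log joint
probability of one individual's latent history and detections.  Everything
here is deterministic and vectorisation-free; the MCMC machinery in
:mod:`agejs.sampler` builds fast tabulated versions of the same kernels and
is tested against these.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

SIMPLEX_TOL = 1e-8


class ValidationError(ValueError):
    """Raised when inputs violate a model contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StudyDesign:
    """Dimensions of a capture-recapture study.

    Parameters
    ----------
    K
        Number of sampling occasions (>= 2).
    J
        Maximum possible age in year 1 (>= 1); bounds only the initial age —
        individuals may age past J during the study.
    entry_age
        Model age assigned at within-study recruitment (default 1).
    M
        Data-augmentation size; may be ``None`` until fitting time.
    """

    K: int
    J: int
    entry_age: int = 1
    M: int | None = None

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValidationError(f"K must be >= 2, got {self.K}")
        if self.J < 1:
            raise ValidationError(f"J must be >= 1, got {self.J}")
        if self.entry_age < 1:
            raise ValidationError(f"entry_age must be >= 1, got {self.entry_age}")
        if self.M is not None and self.M < 1:
            raise ValidationError(f"M must be positive, got {self.M}")

    @property
    def max_age(self) -> int:
        """Largest age reachable during the study (J in year 1 plus K-1)."""
        return self.J + self.K - 1


@dataclass
class CaptureData:
    """Observed detections plus (possibly incomplete) age records.

    ``y`` is the n_observed x K binary detection matrix.  ``age_occasion``
    and ``age_value`` give, per individual, the occasion (1-based) at which
    age was determined and the age itself; -1 in both marks a missing age.
    """

    ids: list[str]
    y: np.ndarray
    age_occasion: np.ndarray
    age_value: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int8)
        self.age_occasion = np.asarray(self.age_occasion, dtype=np.int64)
        self.age_value = np.asarray(self.age_value, dtype=np.int64)
        n = self.y.shape[0]
        if len(self.ids) != n or self.age_occasion.shape != (n,) or self.age_value.shape != (n,):
            raise ValidationError("ids, y, age_occasion, age_value have inconsistent lengths")
        if len(set(self.ids)) != n:
            raise ValidationError("duplicate individual ids")
        if not np.isin(self.y, (0, 1)).all():
            bad = np.argwhere(~np.isin(self.y, (0, 1)))[0]
            raise ValidationError(
                f"non-binary detection value at row {bad[0] + 1}, occasion {bad[1] + 1}"
            )
        if (self.y.sum(axis=1) == 0).any():
            i = int(np.argmin(self.y.sum(axis=1)))
            raise ValidationError(f"individual {self.ids[i]!r} (row {i + 1}) has no detections")
        if ((self.age_occasion < 0) != (self.age_value < 0)).any():
            raise ValidationError("age_occasion and age_value must be missing together")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def K(self) -> int:
        return self.y.shape[1]

    def validate_against(self, design: StudyDesign) -> None:
        """Check age records for consistency with the design.

        An age ``a`` stated at occasion ``k`` implies presence at occasion 1
        with initial age ``a - (k-1)`` whenever that quantity is >=
        ``entry_age``; that initial age must then be <= J.  Otherwise the
        individual is a within-study recruit and ``a`` must be reachable
        from ``entry_age``.
        """
        if self.K != design.K:
            raise ValidationError(f"data has K={self.K} but design has K={design.K}")
        for i in range(self.n):
            k0, a0 = int(self.age_occasion[i]), int(self.age_value[i])
            if k0 < 0:
                continue
            if not (1 <= k0 <= design.K):
                raise ValidationError(f"individual {self.ids[i]!r}: age occasion {k0} out of range")
            if a0 < design.entry_age:
                raise ValidationError(
                    f"individual {self.ids[i]!r}: observed age {a0} below entry age "
                    f"{design.entry_age}"
                )
            x1 = a0 - (k0 - 1)
            recruit_occ = k0 - (a0 - design.entry_age)
            ok_initial = 1 <= x1 <= design.J
            ok_recruit = 2 <= recruit_occ <= design.K
            if not (ok_initial or ok_recruit):
                raise ValidationError(
                    f"individual {self.ids[i]!r}: age {a0} at occasion {k0} is inconsistent "
                    f"with J={design.J}, entry_age={design.entry_age}"
                )


@dataclass(frozen=True)
class ConstantSurvival:
    """Age-constant annual survival probability."""

    phi: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.phi <= 1.0:
            raise ValidationError(f"phi must lie in [0, 1], got {self.phi}")


@dataclass(frozen=True)
class QuadraticSurvival:
    """Quadratic-in-age survival on the logit scale.

    logit(phi(a)) = alpha0 + alpha1 (a - center) + alpha2 (a - center)^2
    """

    alpha0: float
    alpha1: float
    alpha2: float
    center: float = 5.0


SurvivalModel = ConstantSurvival | QuadraticSurvival


def _check_simplex(v: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValidationError(f"{name} must be a 1-d probability vector")
    if (arr < 0).any():
        raise ValidationError(f"{name} has negative entries")
    s = arr.sum()
    if abs(s - 1.0) > SIMPLEX_TOL:
        raise ValidationError(f"{name} must sum to 1 (got {s!r})")
    return arr / s


@dataclass
class ParameterState:
    """One full set of model parameters.

    ``pi_prime`` is ``None`` for the ageless JS model.  ``eta`` is always
    derived from ``beta`` (conditional entry probabilities).
    """

    psi: float
    p: float
    beta: np.ndarray
    survival: SurvivalModel
    pi_prime: np.ndarray | None = None
    eta: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        for nm, v in (("psi", self.psi), ("p", self.p)):
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{nm} must lie in [0, 1], got {v}")
        self.beta = _check_simplex(self.beta, "beta")
        if self.pi_prime is not None:
            self.pi_prime = _check_simplex(self.pi_prime, "pi_prime")
        self.eta = eta_from_beta(self.beta)


# ---------------------------------------------------------------------------
# Entry-probability transforms
# ---------------------------------------------------------------------------


def eta_from_beta(beta: Sequence[float]) -> np.ndarray:
    """Conditional entry probabilities from the entry simplex.

    ``eta_k = beta_k / (1 - sum_{l<k} beta_l)``; when the remaining entry
    mass is zero the ratio is defined as 0 (no one left to enter).  Note
    ``eta_K = 1`` for any simplex with mass on the last occasion: every
    included individual enters by the final occasion.
    """
    b = _check_simplex(beta, "beta")
    remaining = 1.0 - np.concatenate([[0.0], np.cumsum(b)[:-1]])
    eta = np.zeros_like(b)
    pos = remaining > SIMPLEX_TOL
    eta[pos] = b[pos] / remaining[pos]
    return np.clip(eta, 0.0, 1.0)


def beta_from_eta(eta: Sequence[float]) -> np.ndarray:
    """Inverse transform: entry simplex from conditional entry probabilities."""
    e = np.asarray(eta, dtype=float)
    if e.ndim != 1 or ((e < 0) | (e > 1)).any():
        raise ValidationError("eta must be probabilities in [0, 1]")
    not_entered = np.concatenate([[1.0], np.cumprod(1.0 - e)[:-1]])
    return e * not_entered


def compose_initial_age_dist(eta1: float, pi_prime: Sequence[float]) -> np.ndarray:
    """Mixture distribution over {0..J} for the occasion-1 age category.

    Category 0 ("age 0") means not yet entered, with probability
    ``1 - eta1``; categories 1..J carry ``eta1 * pi_prime_j``.
    """
    if not 0.0 <= eta1 <= 1.0:
        raise ValidationError(f"eta1 must lie in [0, 1], got {eta1}")
    pp = _check_simplex(pi_prime, "pi_prime")
    return np.concatenate([[1.0 - eta1], eta1 * pp])


# ---------------------------------------------------------------------------
# Survival link
# ---------------------------------------------------------------------------


def survival_at_age(age, survival: SurvivalModel):
    """Annual survival probability at integer age(s).

    Constant models return ``phi`` for every age.  Quadratic models return
    ``invlogit(alpha0 + alpha1 (age-c) + alpha2 (age-c)^2)``; the alphas may
    be arrays (e.g. posterior draws), in which case broadcasting applies.
    """
    age = np.asarray(age, dtype=float)
    if isinstance(survival, ConstantSurvival):
        return np.broadcast_to(np.asarray(survival.phi, dtype=float), age.shape).copy() \
            if age.shape else float(survival.phi)
    d = age - np.asarray(survival.center, dtype=float)
    lin = (
        np.asarray(survival.alpha0, dtype=float)
        + np.asarray(survival.alpha1, dtype=float) * d
        + np.asarray(survival.alpha2, dtype=float) * d * d
    )
    out = 1.0 / (1.0 + np.exp(-lin))
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# Latent histories
# ---------------------------------------------------------------------------


class LatentHistory(NamedTuple):
    """One individual's latent trajectory, compactly parameterised.

    ``entry`` is the 1-based entry occasion (0 = never entered), ``x1`` the
    age at occasion 1 (0 unless entry == 1), and ``last`` the last occasion
    alive (0 if never entered).  The alive/age matrices of the state-space
    formulation are deterministic functions of this triple.
    """

    x1: int
    entry: int
    last: int

    def alive_at(self, k: int) -> bool:
        return self.entry != 0 and self.entry <= k <= self.last

    def age_at(self, k: int, design: StudyDesign) -> int:
        """Model age at occasion k (0 before entry; keeps incrementing after death)."""
        if self.entry == 0 or k < self.entry:
            return 0
        start = self.x1 if self.entry == 1 else design.entry_age
        return start + (k - self.entry)


NEVER_ENTERED = LatentHistory(x1=0, entry=0, last=0)


def feasible_histories(
    y_i: Sequence[int],
    design: StudyDesign,
    age_occasion: int = -1,
    age_value: int = -1,
) -> list[LatentHistory]:
    """All latent histories consistent with one detection row.

    Every returned history is alive at each detection occasion (entry <=
    first detection, last alive >= last detection).  For an all-zero row the
    never-entered history is included as well.  If a known age is supplied
    (1-based ``age_occasion``, ``age_value``), only histories whose age at
    that occasion matches are returned.
    """
    y = np.asarray(y_i, dtype=int)
    if y.shape != (design.K,) or not np.isin(y, (0, 1)).all():
        raise ValidationError("y_i must be a binary vector of length K")
    det = np.flatnonzero(y) + 1
    first = int(det[0]) if det.size else design.K + 1
    last_det = int(det[-1]) if det.size else 0

    out: list[LatentHistory] = []
    if det.size == 0:
        out.append(NEVER_ENTERED)
    for entry in range(1, design.K + 1):
        if entry > first:
            break
        x1_options = range(1, design.J + 1) if entry == 1 else [0]
        for x1 in x1_options:
            for last in range(max(entry, last_det), design.K + 1):
                h = LatentHistory(x1=x1, entry=entry, last=last)
                if age_occasion >= 1:
                    if not h.alive_at(age_occasion) or h.age_at(age_occasion, design) != age_value:
                        continue
                out.append(h)
    return out


def trajectory_log_prob(
    history: LatentHistory,
    y_i: Sequence[int],
    params: ParameterState,
    design: StudyDesign,
    w: int = 1,
) -> float:
    """Log joint probability of one individual's latent history and detections.

    Multiplies the inclusion kernel P(w | psi), the entry/initial-age kernel
    (eta chain, and pi_prime for occasion-1 ages in age-structured models),
    the survival chain evaluated at the age held the year before each
    transition, and the Bernoulli detection terms.  Inconsistent
    combinations (a detection while dead or excluded) return ``-inf`` rather
    than raising, so Gibbs normalisers over history sets are well defined.
    """
    y = np.asarray(y_i, dtype=int)
    eta = params.eta

    def _log(v: float) -> float:
        return math.log(v) if v > 0 else -math.inf

    lp = math.log(params.psi) if w == 1 else math.log1p(-params.psi)

    # state process (defined for every augmented individual, whatever w)
    if history.entry == 0:
        for k in range(design.K):
            lp += _log(1.0 - eta[k])
    else:
        e = history.entry
        for k in range(1, e):
            lp += _log(1.0 - eta[k - 1])
        lp += _log(eta[e - 1])
        if e == 1 and params.pi_prime is not None:
            if not 1 <= history.x1 <= design.J:
                return -math.inf
            lp += _log(params.pi_prime[history.x1 - 1])
        # survival chain: transition from k-1 to k uses the age held at k-1
        for k in range(e + 1, history.last + 1):
            lp += _log(float(survival_at_age(history.age_at(k - 1, design), params.survival)))
        if history.last < design.K:
            lp += _log(
                1.0 - float(survival_at_age(history.age_at(history.last, design), params.survival))
            )

    # detections: Bernoulli(p * z * w)
    for k in range(1, design.K + 1):
        in_pop = w == 1 and history.alive_at(k)
        if y[k - 1]:
            if not in_pop:
                return -math.inf
            lp += _log(params.p)
        elif in_pop:
            lp += _log(1.0 - params.p)
    return lp
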