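"""Linear kinetics of a three-state repair pathway with reversible steps.

The model tracks a single damaged locus through three states: the damage
substrate ``S``, a potentially toxic intermediate ``I`` and the repaired
product ``P``.  Five mass-action steps connect them, each catalysed by a
distinct enzyme:

=========  ==========  =================================
edge       rate        enzyme
=========  ==========  =================================
S -> I     ``k1``      F1  (first forward step)
I -> S     ``k_m1``    R1  (first backward step)
I -> P     ``k2``      F2  (second forward step)
P -> I     ``k_m2``    R2  (second backward step)
S -> P     ``k3``      EC  (compensatory pathway)
=========  ==========  =================================

Because the system is linear and closed, concentrations and single-molecule
state probabilities coincide up to scale; we work with probabilities, so
every state vector sums to one.  The dynamics are those of a continuous-time
Markov chain with generator ``Q`` (columns indexed by source state,
``dx/dt = Q x``).

Knockouts set a rate to zero, which can make the chain reducible and create
absorbing "kinetic traps".  The long-time state therefore depends on the
initial condition; all fate evaluations start from fully damaged DNA
(``S = 1``), and :func:`limiting_distribution` computes the exact t -> oo
limit via the spectral projector onto the generator's null space (the zero
eigenvalue of a CTMC generator is semisimple, so the limit always exists).
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm, null_space
from scipy.optimize import brentq

from .errors import (
    InputError,
    InvalidDistributionError,
    InvalidRateError,
    RouteUndefinedError,
)

__all__ = [
    "STATE_NAMES",
    "RATE_NAMES",
    "RateSet",
    "PathwayDistribution",
    "TimeCourse",
    "Enzyme",
    "FULLY_DAMAGED",
    "build_generator",
    "simulate_timecourse",
    "limiting_distribution",
    "time_to_repair",
    "compensatory_route_probability",
]

STATE_NAMES = ("S", "I", "P")
RATE_NAMES = ("k1", "k_m1", "k2", "k_m2", "k3")

#: Tolerance on probability conservation (closed system: no creation or
#: destruction of loci).
CONSERVATION_TOL = 1e-9

#: Residual tolerance for the linear steady-state solve.
STEADY_STATE_RESIDUAL_TOL = 1e-10


@dataclass(frozen=True)
class RateSet:
    """The five nonnegative kinetic rate constants of the pathway scheme.

    Rates are in arbitrary inverse-time units; only ratios matter for
    long-time behaviour (uniformly rescaling all five rates rescales time
    but leaves every limiting distribution unchanged).
    """

    k1: float
    k_m1: float
    k2: float
    k_m2: float
    k3: float

    def __post_init__(self) -> None:
        for name in RATE_NAMES:
            value = getattr(self, name)
            if not isinstance(value, (int, float)) or not math.isfinite(value):
                raise InvalidRateError(f"rate {name} must be a finite real number, got {value!r}")
            if value < 0:
                raise InvalidRateError(f"rate {name} must be nonnegative, got {value}")
            object.__setattr__(self, name, float(value))
        if not any(getattr(self, name) > 0 for name in RATE_NAMES):
            raise InvalidRateError("at least one rate must be positive")

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.k1, self.k_m1, self.k2, self.k_m2, self.k3)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in RATE_NAMES}

    def replace(self, **rates: float) -> "RateSet":
        """Return a copy with the given rates substituted."""
        unknown = set(rates) - set(RATE_NAMES)
        if unknown:
            raise InvalidRateError(f"unknown rate name(s): {sorted(unknown)}")
        return dataclasses.replace(self, **rates)

    def scaled(self, factor: float) -> "RateSet":
        """Uniformly rescale all five rates (a change of time unit)."""
        if factor <= 0 or not math.isfinite(factor):
            raise InvalidRateError(f"scale factor must be positive and finite, got {factor}")
        return RateSet(*(factor * v for v in self.as_tuple()))

    @property
    def max_rate(self) -> float:
        return max(self.as_tuple())

    @property
    def min_positive_rate(self) -> float:
        return min(v for v in self.as_tuple() if v > 0)


class Enzyme(str, enum.Enum):
    """The five abstract enzymes, each catalysing one step of the scheme."""

    F1 = "F1"
    R1 = "R1"
    F2 = "F2"
    R2 = "R2"
    EC = "EC"

    @property
    def rate_field(self) -> str:
        return _ENZYME_TO_RATE[self]


_ENZYME_TO_RATE = {
    Enzyme.F1: "k1",
    Enzyme.R1: "k_m1",
    Enzyme.F2: "k2",
    Enzyme.R2: "k_m2",
    Enzyme.EC: "k3",
}


@dataclass(frozen=True)
class PathwayDistribution:
    """Probabilities of the locus being in state S, I or P."""

    s: float
    i: float
    p: float

    def __post_init__(self) -> None:
        for name in ("s", "i", "p"):
            value = float(getattr(self, name))
            if not math.isfinite(value) or value < -CONSERVATION_TOL or value > 1 + CONSERVATION_TOL:
                raise InvalidDistributionError(
                    f"probability {name}={value!r} outside [0, 1]"
                )
            object.__setattr__(self, name, min(max(value, 0.0), 1.0))
        total = self.s + self.i + self.p
        if abs(total - 1.0) > CONSERVATION_TOL:
            raise InvalidDistributionError(f"probabilities sum to {total}, expected 1")

    @classmethod
    def from_vector(cls, vec: Sequence[float]) -> "PathwayDistribution":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (3,):
            raise InvalidDistributionError(f"expected 3 probabilities, got shape {vec.shape}")
        return cls(*vec)

    def as_array(self) -> np.ndarray:
        return np.array([self.s, self.i, self.p])

    def __getitem__(self, state: str) -> float:
        try:
            return {"S": self.s, "I": self.i, "P": self.p}[state]
        except KeyError:
            raise KeyError(f"unknown state {state!r}; expected one of {STATE_NAMES}") from None


#: Initial condition used for all fate evaluations: freshly damaged DNA.
FULLY_DAMAGED = PathwayDistribution(1.0, 0.0, 0.0)


@dataclass(frozen=True)
class TimeCourse:
    """A deterministic trajectory: one state distribution per time point."""

    times: np.ndarray
    states: tuple[PathwayDistribution, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "states", tuple(self.states))
        if len(self.times) != len(self.states):
            raise InputError("times and states must have equal length")

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "S": [d.s for d in self.states],
                "I": [d.i for d in self.states],
                "P": [d.p for d in self.states],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_generator(rates: RateSet) -> np.ndarray:
    """Transition-rate matrix Q of the chain over states (S, I, P).

    Orientation: **columns are source states** and rows are destinations, so
    the master equation reads ``dx/dt = Q @ x`` for a column state vector
    ``x``.  Off-diagonal entries carry the five rates on their edges; each
    column sums to zero (probability conservation).
    """
    k1, k_m1, k2, k_m2, k3 = rates.as_tuple()
    return np.array(
        [
            [-(k1 + k3), k_m1, 0.0],
            [k1, -(k_m1 + k2), k_m2],
            [k3, k2, -k_m2],
        ]
    )


def _clean_probability_vector(vec: np.ndarray) -> PathwayDistribution:
    # Exact arithmetic can leave ~1e-16 negatives; clip strictly tiny noise only.
    vec = np.where((vec < 0) & (vec > -CONSERVATION_TOL), 0.0, vec)
    return PathwayDistribution.from_vector(vec)


def simulate_timecourse(
    rates: RateSet,
    initial: PathwayDistribution = FULLY_DAMAGED,
    times: Sequence[float] = (),
) -> TimeCourse:
    """Exact solution of the linear kinetics at the requested time points.

    Uses the matrix exponential ``x(t) = expm(Q t) x(0)``, which is exact for
    this constant-coefficient linear system (no integration tolerance).
    """
    t = np.asarray(list(times), dtype=float)
    if t.size == 0:
        raise InputError("at least one time point is required")
    if np.any(t < 0):
        raise InputError("times must be nonnegative")
    if np.any(np.diff(t) <= 0):
        raise InputError("times must be strictly increasing")
    q = build_generator(rates)
    x0 = initial.as_array()
    states = []
    for ti in t:
        x = x0 if ti == 0 else expm(q * ti) @ x0
        states.append(_clean_probability_vector(x))
    return TimeCourse(times=t, states=tuple(states))


def limiting_distribution(
    rates: RateSet, initial: PathwayDistribution = FULLY_DAMAGED
) -> PathwayDistribution:
    """The exact t -> oo limit of the kinetics started from ``initial``.

    For an irreducible chain this is the unique stationary distribution and
    is independent of the start.  Knockouts can make the chain reducible
    (absorbing kinetic traps); the limit then depends on ``initial`` and is
    computed as the spectral projection of the start vector onto the
    generator's null space: ``x_oo = V (W^T V)^{-1} W^T x0`` with V, W
    orthonormal bases of the right and left null spaces.  The zero eigenvalue
    of a CTMC generator is semisimple and every other eigenvalue has strictly
    negative real part, so this projection is exactly the long-time limit.
    """
    q = build_generator(rates) / rates.max_rate  # same kernel, conditioning ~1
    v = null_space(q)
    w = null_space(q.T)
    x = v @ np.linalg.solve(w.T @ v, w.T @ initial.as_array())
    residual = float(np.abs(q @ x).max())
    if residual > STEADY_STATE_RESIDUAL_TOL:
        raise ArithmeticError(f"steady-state residual {residual:.2e} exceeds tolerance")
    return _clean_probability_vector(x)


def time_to_repair(
    rates: RateSet,
    initial: PathwayDistribution = FULLY_DAMAGED,
    threshold: float = 0.5,
) -> float:
    """Smallest time at which the repaired probability p(t) reaches ``threshold``.

    Returns ``math.inf`` when the limiting repaired probability stays below
    the threshold (the locus is never repaired to that level).  The crossing
    is located by geometric bracketing of the exact solution followed by
    Brent root finding to relative tolerance 1e-6.
    """
    if not (0 < threshold < 1):
        raise InputError(f"threshold must lie in (0, 1), got {threshold}")
    if initial.p >= threshold:
        return 0.0
    q = build_generator(rates)
    x0 = initial.as_array()

    def p_of(t: float) -> float:
        return float((expm(q * t) @ x0)[2])

    if limiting_distribution(rates, initial).p < threshold:
        return math.inf
    scale = 1.0 / rates.max_rate
    # Bracket the first crossing geometrically; a fine growth factor keeps the
    # bracket tight enough that p(t) crosses the threshold once inside it.
    t_lo, t_hi = 0.0, scale
    crossed = False
    for _ in range(200):
        if p_of(t_hi) >= threshold:
            crossed = True
            break
        t_lo, t_hi = t_hi, t_hi * 1.5
    if not crossed:  # limit sits exactly at the threshold; never strictly reached
        return math.inf
    t_star = brentq(lambda t: p_of(t) - threshold, t_lo, t_hi, rtol=1e-9, xtol=1e-12 * scale)
    return float(t_star)


def compensatory_route_probability(rates: RateSet) -> float:
    """Probability that the first entry into P uses the direct S -> P edge.

    First-step analysis from S: with ``a = k3/(k1+k3)`` (leave S directly to
    P), ``b = k1/(k1+k3)`` (leave S into the intermediate) and
    ``c = k_m1/(k2+k_m1)`` (return from I to S rather than progress), the
    chance that repair, when it first happens, came through the compensatory
    route is the geometric sum ``q = a / (1 - b c)``.  The backward rate
    k_m2 plays no role: we stop at the first entry into P.

    When the chain can be trapped in I (``k2 = k_m1 = 0`` with ``k1 > 0``),
    q is the unconditional probability that the first entry into P both
    happens and uses the direct edge.
    """
    k1, k_m1, k2, _, k3 = rates.as_tuple()
    if k1 + k3 == 0:
        raise RouteUndefinedError("S has no outgoing edge; P is unreachable")
    if k3 == 0 and not (k1 > 0 and k2 > 0):
        raise RouteUndefinedError("P is unreachable from S")
    a = k3 / (k1 + k3)
    b = k1 / (k1 + k3)
    c = k_m1 / (k2 + k_m1) if (k2 + k_m1) > 0 else 0.0
    return a / (1.0 - b * c)
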