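"""Fate classification of a pathway genotype and the phase-diagram color rule.

A rate set (a genotype: knockouts zero a rate, overexpression multiplies
one) is mapped to one of five qualitative fates from the long-time state of
a freshly damaged locus:

* ``REPAIRED_MAIN`` — repaired (P > 50%), mostly through the main pathway;
* ``COMPENSATED`` — repaired, but the first passage into P runs through the
  compensatory S -> P route with probability > 1/2;
* ``DD`` — death by DNA damage: the substrate S retains > 50% probability;
* ``DT`` — death by toxicity: the intermediate I retains > 50% probability
  (the kinetic-trap outcome);
* ``DEAD_MIXED`` — not repaired, but no single dead state exceeds 50%.

All thresholds are strict (*strictly* greater than 50%); a probability
exactly at the threshold does not qualify.

Viable unperturbed genotypes are further split by robustness to single
knockouts: Normal-Robust (``NR``) survives zeroing any one of the five
rates, Normal-Fragile (``NF``) does not.  The difference is governed by the
ratio of the two backward rates, r_b = k_m1 / k_m2.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional

from .errors import BaselineNotViableError, InputError
from .kinetics import (
    FULLY_DAMAGED,
    Enzyme,
    PathwayDistribution,
    RateSet,
    compensatory_route_probability,
    limiting_distribution,
)

__all__ = [
    "ControlParameters",
    "FateLabel",
    "BaselineLabel",
    "PhaseColor",
    "control_parameters",
    "classify_fate",
    "classify_baseline",
    "phase_color",
]


class FateLabel(enum.Enum):
    REPAIRED_MAIN = "REPAIRED_MAIN"
    COMPENSATED = "COMPENSATED"
    DD = "DD"
    DT = "DT"
    DEAD_MIXED = "DEAD_MIXED"

    @property
    def viable(self) -> bool:
        return self in (FateLabel.REPAIRED_MAIN, FateLabel.COMPENSATED)


class BaselineLabel(enum.Enum):
    NR = "NR"  # Normal Robust: no single knockout is lethal
    NF = "NF"  # Normal Fragile: some single knockout is lethal


class PhaseColor(enum.Enum):
    RED = "RED"  # repaired: P > 1/2
    GREEN = "GREEN"  # trapped: I beats S among the unrepaired
    BLUE = "BLUE"  # damaged: S beats or ties I


@dataclass(frozen=True)
class ControlParameters:
    """The three rate ratios governing steady-state classification.

    ``r1 = k1 / k_m1`` and ``r2 = k2 / k_m2`` compare each step's forward
    rate to its own backward rate; ``rb = k_m1 / k_m2`` compares the two
    backward rates and separates the NR and NF regimes.  A ratio with a zero
    denominator and positive numerator is ``math.inf``; a 0/0 ratio is
    undefined and stored as ``None``.
    """

    r1: Optional[float]
    r2: Optional[float]
    rb: Optional[float]


def _ratio(numerator: float, denominator: float) -> Optional[float]:
    if denominator > 0:
        return numerator / denominator
    if numerator > 0:
        return math.inf
    return None


def control_parameters(rates: RateSet) -> ControlParameters:
    return ControlParameters(
        r1=_ratio(rates.k1, rates.k_m1),
        r2=_ratio(rates.k2, rates.k_m2),
        rb=_ratio(rates.k_m1, rates.k_m2),
    )


def classify_fate(rates: RateSet, threshold: float = 0.5) -> FateLabel:
    """Map a genotype to its qualitative fate (see module docstring).

    The limiting distribution is evaluated from fully damaged DNA (S = 1),
    which keeps reducible (knockout) chains well-defined.
    """
    if not (0 < threshold < 1):
        raise InputError(f"threshold must lie in (0, 1), got {threshold}")
    d = limiting_distribution(rates, FULLY_DAMAGED)
    if d.p > threshold:
        # p > 0 from S=1 implies P is reachable, so routing is defined.
        route = compensatory_route_probability(rates)
        return FateLabel.COMPENSATED if route > 0.5 else FateLabel.REPAIRED_MAIN
    if d.s > threshold:
        return FateLabel.DD
    if d.i > threshold:
        return FateLabel.DT
    return FateLabel.DEAD_MIXED


def classify_baseline(
    rates: RateSet, threshold: float = 0.5
) -> tuple[BaselineLabel, dict[Enzyme, FateLabel]]:
    """Robustness of a viable genotype to each of the five single knockouts.

    Returns the label (NR when every single knockout stays viable, NF
    otherwise) together with the per-knockout fate table.
    """
    base_fate = classify_fate(rates, threshold)
    if not base_fate.viable:
        raise BaselineNotViableError(
            f"baseline fate is {base_fate.value}; NR/NF is defined only for viable genotypes"
        )
    knockout_fates = {
        enzyme: classify_fate(rates.replace(**{enzyme.rate_field: 0.0}), threshold)
        for enzyme in Enzyme
    }
    label = (
        BaselineLabel.NR
        if all(f.viable for f in knockout_fates.values())
        else BaselineLabel.NF
    )
    return label, knockout_fates


def phase_color(d: PathwayDistribution) -> PhaseColor:
    """Phase-diagram color: RED when repaired (p > 1/2); otherwise GREEN when
    trapping in the intermediate beats the unrepaired substrate (i > s), BLUE
    in the opposite case."""
    if d.p > 0.5:
        return PhaseColor.RED
    return PhaseColor.GREEN if d.i > d.s else PhaseColor.BLUE
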