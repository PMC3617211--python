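"""Genotype scenarios: single and double knockouts / overexpressions.

Each scenario perturbs one of the two reference baselines (Normal Robust or
Normal Fragile) and carries the qualitative fate the model is expected to
produce.  Knockout sets the targeted enzyme's rate to zero; overexpression
multiplies it by a factor (default 20) large enough to flip the steady
state qualitatively.

Highlights of the catalogue:

* ``bpSL`` (F1 and EC knocked out) — both routes to repair severed, death by
  damage accumulation (DD);
* ``wrpSL`` (R1 and F2 knocked out) — the intermediate can neither progress
  nor reverse: a kinetic trap, death by toxicity (DT).  This is the model
  analog of the srs2 rad54 double mutant;
* dosage lethality (F1 overexpressed with F2 knocked out, or R2
  overexpressed) — trapping induced by pushing flux into, or back into, the
  intermediate.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import pandas as pd

from .classification import FateLabel, classify_fate
from .errors import ConfigurationError, PerturbationConflictError
from .kinetics import (
    FULLY_DAMAGED,
    Enzyme,
    PathwayDistribution,
    RateSet,
    limiting_distribution,
    time_to_repair,
)
from .synth import reference_ratesets

__all__ = [
    "DEFAULT_OVEREXPRESSION_FACTOR",
    "Mode",
    "Perturbation",
    "Scenario",
    "ScenarioResult",
    "apply_perturbations",
    "scenario_catalogue",
    "evaluate_catalogue",
    "results_to_frame",
]

#: A factor of 20 pushes the R2-overexpression scenarios' trapped
#: intermediate clearly past the 50% death bound on the NF baseline
#: (a factor of 10 leaves them in the mixed boundary zone).
DEFAULT_OVEREXPRESSION_FACTOR = 20.0


class Mode(enum.Enum):
    KNOCKOUT = "KNOCKOUT"
    OVEREXPRESS = "OVEREXPRESS"


@dataclass(frozen=True)
class Perturbation:
    """One enzyme perturbed: knocked out, or overexpressed by ``factor``.

    ``factor=None`` on an overexpression defers to the factor supplied at
    evaluation time.
    """

    enzyme: Enzyme
    mode: Mode
    factor: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mode is Mode.KNOCKOUT and self.factor is not None:
            raise ConfigurationError("knockouts take no factor")
        if self.mode is Mode.OVEREXPRESS and self.factor is not None and self.factor <= 1:
            raise ConfigurationError(f"overexpression factor must exceed 1, got {self.factor}")

    def short(self) -> str:
        arrow = "v" if self.mode is Mode.KNOCKOUT else "^"
        return f"{self.enzyme.value}{arrow}"


def knockout(enzyme: Enzyme) -> Perturbation:
    return Perturbation(enzyme, Mode.KNOCKOUT)


def overexpress(enzyme: Enzyme, factor: Optional[float] = None) -> Perturbation:
    return Perturbation(enzyme, Mode.OVEREXPRESS, factor)


@dataclass(frozen=True)
class Scenario:
    """A named genotype with its expected qualitative fate.

    ``parameter_sensitive`` marks scenarios whose outcome depends on rate
    choices the model does not pin down; they are reported but excluded
    from hard pass criteria.  ``note`` records the biological reading.
    """

    name: str
    baseline: str  # "NR" or "NF"
    perturbations: tuple[Perturbation, ...]
    expected_fate: FateLabel
    note: str = ""
    parameter_sensitive: bool = False

    def __post_init__(self) -> None:
        enzymes = [p.enzyme for p in self.perturbations]
        if len(enzymes) != len(set(enzymes)):
            raise PerturbationConflictError(
                f"scenario {self.name!r} perturbs an enzyme more than once"
            )


@dataclass(frozen=True)
class ScenarioResult:
    scenario: Scenario
    rates: RateSet
    distribution: PathwayDistribution
    fate: FateLabel
    repair_time: float
    passed: bool


def apply_perturbations(
    rates: RateSet, perturbations: Sequence[Perturbation]
) -> RateSet:
    """Apply knockouts (rate -> 0) and overexpressions (rate x factor)."""
    enzymes = [p.enzyme for p in perturbations]
    if len(enzymes) != len(set(enzymes)):
        dup = next(e for e in enzymes if enzymes.count(e) > 1)
        raise PerturbationConflictError(f"enzyme {dup.value} perturbed more than once")
    updates: dict[str, float] = {}
    for p in perturbations:
        current = getattr(rates, p.enzyme.rate_field)
        if p.mode is Mode.KNOCKOUT:
            updates[p.enzyme.rate_field] = 0.0
        else:
            if p.factor is None:
                raise ConfigurationError(
                    f"overexpression of {p.enzyme.value} has no factor; "
                    "supply one or evaluate through evaluate_catalogue"
                )
            updates[p.enzyme.rate_field] = current * p.factor
    return rates.replace(**updates)


def scenario_catalogue() -> tuple[Scenario, ...]:
    """The reference scenario set (unperturbed baselines, SL doubles,
    single knockouts, dosage-lethal combinations and rescues)."""
    F1, R1, F2, R2, EC = Enzyme.F1, Enzyme.R1, Enzyme.F2, Enzyme.R2, Enzyme.EC
    C, RM, DD, DT = (
        FateLabel.COMPENSATED,
        FateLabel.REPAIRED_MAIN,
        FateLabel.DD,
        FateLabel.DT,
    )
    return (
        Scenario("NR_baseline", "NR", (), RM, "robust normal pathway, unperturbed"),
        Scenario("NF_baseline", "NF", (), RM, "fragile normal pathway, unperturbed"),
        Scenario(
            "irreversible",
            "NR",
            (knockout(R1), knockout(R2)),
            RM,
            "removing both backward steps barely changes repair efficiency",
        ),
        Scenario(
            "bpSL",
            "NR",
            (knockout(F1), knockout(EC)),
            DD,
            "main entry and compensatory route both severed: damage accumulates",
        ),
        Scenario(
            "downstream_block_uncompensated",
            "NR",
            (knockout(F2), knockout(EC)),
            DT,
            "no progression past I and no bypass: toxic intermediate accumulates",
        ),
        Scenario(
            "wrpSL",
            "NF",
            (knockout(R1), knockout(F2)),
            DT,
            "kinetic trap in the toxic intermediate (srs2 rad54 analog)",
        ),
        Scenario(
            "F1_knockout",
            "NR",
            (knockout(F1),),
            C,
            "upstream block: repair rerouted through the compensatory pathway",
        ),
        Scenario(
            "F2_knockout_NR",
            "NR",
            (knockout(F2),),
            C,
            "downstream block, slow backward drain to S lets EC compensate",
        ),
        Scenario(
            "F2_knockout_NF",
            "NF",
            (knockout(F2),),
            DT,
            "the one lethal single knockout of the fragile baseline",
        ),
        Scenario(
            "F2_knockout_R1_overexpression",
            "NR",
            (knockout(F2), overexpress(R1)),
            C,
            "boosting the backward step rescues the downstream block via EC",
        ),
        Scenario(
            "R2_overexpression",
            "NF",
            (overexpress(R2),),
            DT,
            "dosage lethality: backward flux P->I overwhelms progression",
        ),
        Scenario(
            "R2_overexpression_F1_knockout",
            "NF",
            (overexpress(R2), knockout(F1)),
            C,
            "partial rescue of R2 dosage lethality by removing the main entry",
            parameter_sensitive=True,
        ),
        Scenario(
            "F1_overexpression_F2_knockout",
            "NF",
            (overexpress(F1), knockout(F2)),
            DT,
            "synthetic dosage lethality: flux forced into a blocked intermediate",
        ),
        Scenario(
            "EC_knockout_R2_overexpression",
            "NF",
            (knockout(EC), overexpress(R2)),
            DT,
            "no bypass plus amplified backward flux traps the intermediate",
        ),
        Scenario(
            "R1_knockout_R2_overexpression",
            "NF",
            (knockout(R1), overexpress(R2)),
            DT,
            "trap built from the other side: no reversal out of I, fast P->I",
        ),
    )


def _resolve_baseline(name: str) -> RateSet:
    refs = reference_ratesets()
    try:
        return refs[name]
    except KeyError:
        raise ConfigurationError(f"unknown baseline {name!r}; expected one of {sorted(refs)}") from None


def evaluate_catalogue(
    catalogue: Optional[Sequence[Scenario]] = None,
    overexpression_factor: float = DEFAULT_OVEREXPRESSION_FACTOR,
    repair_threshold: float = 0.5,
) -> list[ScenarioResult]:
    """Run every scenario through perturbation -> fate classification.

    Deferred overexpression factors take ``overexpression_factor``.
    ``passed`` compares realized and expected fate; parameter-sensitive
    scenarios report it like any other but callers should not gate on them.
    """
    if overexpression_factor <= 1:
        raise ConfigurationError("overexpression factor must exceed 1")
    if catalogue is None:
        catalogue = scenario_catalogue()
    results = []
    for scenario in catalogue:
        perts = tuple(
            replace(p, factor=overexpression_factor)
            if p.mode is Mode.OVEREXPRESS and p.factor is None
            else p
            for p in scenario.perturbations
        )
        rates = apply_perturbations(_resolve_baseline(scenario.baseline), perts)
        dist = limiting_distribution(rates, FULLY_DAMAGED)
        fate = classify_fate(rates)
        t_repair = time_to_repair(rates, FULLY_DAMAGED, repair_threshold)
        results.append(
            ScenarioResult(
                scenario=scenario,
                rates=rates,
                distribution=dist,
                fate=fate,
                repair_time=t_repair,
                passed=fate is scenario.expected_fate,
            )
        )
    return results


def results_to_frame(results: Sequence[ScenarioResult]) -> pd.DataFrame:
    """Tabulate scenario results (one row per scenario)."""
    return pd.DataFrame(
        {
            "scenario": [r.scenario.name for r in results],
            "baseline": [r.scenario.baseline for r in results],
            "perturbations": [
                "+".join(p.short() for p in r.scenario.perturbations) or "-"
                for r in results
            ],
            "S_ss": [r.distribution.s for r in results],
            "I_ss": [r.distribution.i for r in results],
            "P_ss": [r.distribution.p for r in results],
            "fate": [r.fate.value for r in results],
            "expected": [r.scenario.expected_fate.value for r in results],
            "parameter_sensitive": [r.scenario.parameter_sensitive for r in results],
            "repair_time": [r.repair_time for r in results],
            "passed": [r.passed for r in results],
        }
    )
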