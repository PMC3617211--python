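"""Synthetic inputs: reference rate sets and simulated interaction screens.

Two kinds of fixtures are produced here, both first-class parts of the
package:

* :func:`reference_ratesets` — the Normal-Robust and Normal-Fragile
  reference parameterizations of the kinetic model.  Both satisfy the
  normal-regime constraint that forward steps outpace their backward steps;
  they differ only in the backward-rate ratio r_b = k_m1/k_m2 (100 vs 1),
  which is what separates robustness from fragility to single knockouts.

* :func:`generate_interaction_dataset` — a seeded emulation of a
  genome-wide genetic-interaction screen: every unordered gene pair
  independently becomes a negative (aggravating) interaction with a
  background probability, an elevated probability when both genes belong to
  a planted pathway, and a separate probability when both belong to a
  molecular complex.  Negative pairs receive an epistasis score well below
  the stringent filter and a small p-value; a fraction of the remaining
  pairs is emitted with mild scores to exercise filtering.  Everything is
  reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import GeneSet, write_gmt
from .errors import ConfigurationError
from .kinetics import RateSet

__all__ = [
    "InteractionSimConfig",
    "GroundTruth",
    "SyntheticScreen",
    "reference_ratesets",
    "generate_interaction_dataset",
    "expected_proportions",
    "write_dataset",
]


def reference_ratesets() -> dict[str, RateSet]:
    """Reference parameterizations of the kinetic model, one per regime.

    ``NR`` (Normal Robust, r_b = 100): every single knockout leaves the
    pathway viable.  ``NF`` (Normal Fragile, r_b = 1): the F2 knockout is
    lethal by intermediate trapping.  Both obey the normal-regime ordering
    k1 > k_m1 and k2 > k_m2.
    """
    return {
        "NR": RateSet(k1=1.0, k_m1=0.1, k2=1.0, k_m2=0.001, k3=0.1),
        "NF": RateSet(k1=1.0, k_m1=0.1, k2=1.0, k_m2=0.1, k3=0.1),
    }


@dataclass(frozen=True)
class InteractionSimConfig:
    """Configuration of the simulated genetic-interaction screen.

    Defaults emulate a stringently filtered genome-wide screen: a 1% chance
    that an arbitrary gene pair interacts negatively, one planted pathway of
    20 genes whose internal pairs interact at 27/190 ~ 14.2% (the scale of
    the top-ranked DNA-repair pathway in real screens), decoy pathways at
    background rate, and a 4-gene complex nested in the planted pathway
    whose pairs interact at 50% (within-complex interactions are flagged and
    excluded by the enrichment statistic).
    """

    n_genes: int = 250
    pathway_sizes: Sequence[int] = (20, 15, 12, 10)
    n_planted: int = 1
    complex_sizes: Sequence[Sequence[int]] = ((4,), (), (), ())
    p_bg: float = 0.01
    p_wp: float = 27.0 / 190.0
    p_c: float = 0.5
    epsilon_negative: tuple[float, float] = (-0.6, -0.15)
    epsilon_null: tuple[float, float] = (-0.08, 0.08)
    p_value_negative: tuple[float, float] = (0.0, 0.01)
    p_value_null: tuple[float, float] = (0.0, 1.0)
    null_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_bg <= self.p_wp <= 1.0):
            raise ConfigurationError("require 0 <= p_bg <= p_wp <= 1")
        if not (0.0 <= self.p_c <= 1.0):
            raise ConfigurationError("require 0 <= p_c <= 1")
        if len(self.complex_sizes) != len(self.pathway_sizes):
            raise ConfigurationError("complex_sizes must list one (possibly empty) group per pathway")
        if not (0 <= self.n_planted <= len(self.pathway_sizes)):
            raise ConfigurationError("n_planted must index a prefix of pathway_sizes")
        if any(s < 1 for s in self.pathway_sizes):
            raise ConfigurationError("pathway sizes must be >= 1")
        if sum(self.pathway_sizes) > self.n_genes:
            raise ConfigurationError("pathways (disjoint) cannot exceed the gene universe")
        for size, complexes in zip(self.pathway_sizes, self.complex_sizes):
            if sum(complexes) > size:
                raise ConfigurationError("complexes nested in a pathway cannot exceed its size")
            if any(c < 2 for c in complexes):
                raise ConfigurationError("complex sizes must be >= 2")
        if not (0.0 <= self.null_fraction <= 1.0):
            raise ConfigurationError("null_fraction must lie in [0, 1]")

    def pathway_ids(self) -> list[str]:
        return [f"pw{idx + 1:02d}" for idx in range(len(self.pathway_sizes))]

    def planted_ids(self) -> list[str]:
        return self.pathway_ids()[: self.n_planted]


@dataclass(frozen=True)
class GroundTruth:
    """Which pathways were planted, and the label of every emitted pair."""

    planted_pathways: tuple[str, ...]
    pair_labels: pd.DataFrame  # columns: gene_a, gene_b, label, is_negative


@dataclass(frozen=True)
class SyntheticScreen:
    interactions: pd.DataFrame  # columns: gene_a, gene_b, epsilon, p_value
    pathways: tuple[GeneSet, ...]
    complexes: tuple[GeneSet, ...]
    truth: GroundTruth


def _memberships(config: InteractionSimConfig) -> tuple[list[str], list[GeneSet], list[GeneSet]]:
    genes = [f"g{idx + 1:04d}" for idx in range(config.n_genes)]
    pathways: list[GeneSet] = []
    complexes: list[GeneSet] = []
    cursor = 0
    for pw_idx, (size, complex_group) in enumerate(
        zip(config.pathway_sizes, config.complex_sizes)
    ):
        members = genes[cursor : cursor + size]
        pw_id = f"pw{pw_idx + 1:02d}"
        pathways.append(GeneSet(id=pw_id, description=f"synthetic pathway {pw_idx + 1}", members=frozenset(members)))
        c_cursor = 0
        for c_idx, c_size in enumerate(complex_group):
            c_members = members[c_cursor : c_cursor + c_size]
            complexes.append(
                GeneSet(
                    id=f"{pw_id}_cx{c_idx + 1}",
                    description=f"synthetic complex {c_idx + 1} in {pw_id}",
                    members=frozenset(c_members),
                )
            )
            c_cursor += c_size
        cursor += size
    return genes, pathways, complexes


def generate_interaction_dataset(config: InteractionSimConfig) -> SyntheticScreen:
    """Simulate one screen: memberships, per-pair Bernoulli draws, scores.

    Deterministic given ``config.seed``: repeated calls with an identical
    config produce identical tables.
    """
    genes, pathways, complexes = _memberships(config)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0x5EED]))

    n = config.n_genes
    ia, ib = np.triu_indices(n, k=1)
    gene_arr = np.array(genes)

    pathway_of = np.full(n, -1)
    for idx, pw in enumerate(pathways):
        members = np.isin(gene_arr, list(pw.members))
        pathway_of[members] = idx
    complex_of = np.full(n, -1)
    for idx, cx in enumerate(complexes):
        members = np.isin(gene_arr, list(cx.members))
        complex_of[members] = idx

    prob = np.full(ia.shape, config.p_bg)
    same_planted = (
        (pathway_of[ia] >= 0)
        & (pathway_of[ia] == pathway_of[ib])
        & (pathway_of[ia] < config.n_planted)
    )
    prob[same_planted] = config.p_wp
    same_complex = (complex_of[ia] >= 0) & (complex_of[ia] == complex_of[ib])
    prob[same_complex] = config.p_c

    is_negative = rng.random(ia.shape) < prob
    labels = np.where(same_complex, "within_complex", np.where(same_planted, "within_pathway", "background"))

    neg_idx = np.flatnonzero(is_negative)
    pos_idx = np.flatnonzero(~is_negative)
    n_null = int(round(config.null_fraction * pos_idx.size))
    null_idx = np.sort(rng.choice(pos_idx, size=n_null, replace=False)) if n_null else np.array([], dtype=int)

    def _uniform(bounds: tuple[float, float], size: int) -> np.ndarray:
        lo, hi = bounds
        return rng.uniform(lo, hi, size)

    records = pd.DataFrame(
        {
            "gene_a": np.concatenate([gene_arr[ia[neg_idx]], gene_arr[ia[null_idx]]]),
            "gene_b": np.concatenate([gene_arr[ib[neg_idx]], gene_arr[ib[null_idx]]]),
            "epsilon": np.concatenate(
                [_uniform(config.epsilon_negative, neg_idx.size), _uniform(config.epsilon_null, null_idx.size)]
            ),
            "p_value": np.concatenate(
                [_uniform(config.p_value_negative, neg_idx.size), _uniform(config.p_value_null, null_idx.size)]
            ),
        }
    )
    emitted = np.concatenate([neg_idx, null_idx])
    pair_labels = pd.DataFrame(
        {
            "gene_a": gene_arr[ia[emitted]],
            "gene_b": gene_arr[ib[emitted]],
            "label": labels[emitted],
            "is_negative": np.concatenate(
                [np.ones(neg_idx.size, dtype=bool), np.zeros(null_idx.size, dtype=bool)]
            ),
        }
    )
    truth = GroundTruth(planted_pathways=tuple(config.planted_ids()), pair_labels=pair_labels)
    return SyntheticScreen(
        interactions=records,
        pathways=tuple(pathways),
        complexes=tuple(complexes),
        truth=truth,
    )


def expected_proportions(config: InteractionSimConfig) -> dict[str, float]:
    """Closed-form expectation of each pathway's normalized proportion.

    A pathway of size S has T = S(S-1)/2 pairs, of which E lie inside nested
    complexes and are excluded from the numerator regardless of outcome; the
    remaining T - E pairs are negative with probability p_wp (planted) or
    p_bg (decoy), so E[proportion] = rate * (T - E) / T.
    """
    out: dict[str, float] = {}
    for idx, (size, complex_group) in enumerate(zip(config.pathway_sizes, config.complex_sizes)):
        total_pairs = size * (size - 1) // 2
        if total_pairs == 0:
            out[f"pw{idx + 1:02d}"] = 0.0
            continue
        excluded = sum(c * (c - 1) // 2 for c in complex_group)
        rate = config.p_wp if idx < config.n_planted else config.p_bg
        out[f"pw{idx + 1:02d}"] = rate * (total_pairs - excluded) / total_pairs
    return out


def write_dataset(screen: SyntheticScreen, out_dir) -> dict[str, Path]:
    """Write interactions.tsv, pathways.gmt, complexes.gmt and truth.tsv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "interactions": out_dir / "interactions.tsv",
        "pathways": out_dir / "pathways.gmt",
        "complexes": out_dir / "complexes.gmt",
        "truth": out_dir / "truth.tsv",
    }
    screen.interactions.to_csv(paths["interactions"], sep="\t", index=False)
    write_gmt(screen.pathways, paths["pathways"])
    write_gmt(screen.complexes, paths["complexes"])
    truth = screen.truth.pair_labels.copy()
    truth.insert(0, "planted_pathways", ";".join(screen.truth.planted_pathways))
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
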