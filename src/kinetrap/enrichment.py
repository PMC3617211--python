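"""Within-pathway negative genetic-interaction enrichment.

Given a table of pairwise epistasis measurements, gene-set definitions of
pathways and of molecular complexes, this module computes, per pathway, the
normalized proportion of negative interactions::

    proportion = (# negative pairs inside the pathway, excluding pairs that
                  co-occur in a molecular complex) / (S (S - 1) / 2)

where S is the pathway size.  Excluding within-complex pairs separates
"two subunits of one machine" interactions from genuinely within-pathway
ones.  Pathways are ranked by this proportion and a display filter keeps
only those at or above a minimum (1% by default).

Negative interactions are defined by a stringent filter on the epistasis
measure, ``epsilon < epsilon_max`` (default -0.12) together with
``p_value < p_max`` (default 0.05).  Pairs are unordered: (a, b) and (b, a)
denote the same measurement and are deduplicated keeping the most negative
score.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError, UndefinedStatisticError

__all__ = [
    "DEFAULT_EPSILON_MAX",
    "DEFAULT_P_MAX",
    "DEFAULT_MIN_PROPORTION",
    "INTERACTION_COLUMNS",
    "GeneSet",
    "EnrichmentResult",
    "read_interactions",
    "read_gmt",
    "write_gmt",
    "filter_negative",
    "within_pathway_counts",
    "normalized_proportion",
    "rank_pathways",
    "complex_fraction",
]

DEFAULT_EPSILON_MAX = -0.12
DEFAULT_P_MAX = 0.05
DEFAULT_MIN_PROPORTION = 0.01

INTERACTION_COLUMNS = ("gene_a", "gene_b", "epsilon", "p_value")


@dataclass(frozen=True)
class GeneSet:
    """A named gene set: a pathway or a molecular complex."""

    id: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if len(self.members) < 1:
            raise InputError(f"gene set {self.id!r} must have at least one member")

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class EnrichmentResult:
    pathway: str
    n_genes: int
    n_neg_within: int
    n_neg_within_complex: int
    normalized_proportion: float

    @property
    def n_neg_excl_complex(self) -> int:
        return self.n_neg_within - self.n_neg_within_complex


def read_interactions(path) -> pd.DataFrame:
    """Read a pairwise interaction TSV with header gene_a, gene_b, epsilon, p_value."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    missing = [c for c in INTERACTION_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"interaction table {path} is missing column(s) {missing}")
    df = df.loc[:, list(INTERACTION_COLUMNS)]
    _validate_interactions(df)
    return df


def _validate_interactions(df: pd.DataFrame) -> None:
    if (df["gene_a"] == df["gene_b"]).any():
        bad = df.loc[df["gene_a"] == df["gene_b"], "gene_a"].iloc[0]
        raise InputError(f"self-interaction for gene {bad!r}; gene_a must differ from gene_b")


def read_gmt(path) -> list[GeneSet]:
    """Read GMT (one set per line: id <tab> description <tab> member genes)."""
    sets: list[GeneSet] = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise InputError(f"{path}:{line_no}: GMT line needs id, description and >=1 member")
        sets.append(GeneSet(id=fields[0], description=fields[1], members=frozenset(fields[2:])))
    return sets


def write_gmt(sets: Iterable[GeneSet], path) -> None:
    lines = [
        "\t".join([s.id, s.description, *sorted(s.members)]) for s in sets
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def _canonical_pairs(df: pd.DataFrame) -> pd.DataFrame:
    a = df["gene_a"].to_numpy(dtype=str)
    b = df["gene_b"].to_numpy(dtype=str)
    out = df.copy()
    swap = a > b
    out["gene_a"] = np.where(swap, b, a)
    out["gene_b"] = np.where(swap, a, b)
    return out


def filter_negative(
    records: pd.DataFrame,
    epsilon_max: float = DEFAULT_EPSILON_MAX,
    p_max: float = DEFAULT_P_MAX,
) -> pd.DataFrame:
    """Stringent negative-interaction filter.

    Keeps records with ``epsilon < epsilon_max`` and ``p_value < p_max``;
    unordered duplicates collapse to the single most negative measurement.
    """
    if not np.isfinite(epsilon_max) or not np.isfinite(p_max):
        raise ConfigurationError("thresholds must be finite")
    if epsilon_max >= 0:
        raise ConfigurationError(f"epsilon_max must be negative, got {epsilon_max}")
    _validate_interactions(records)
    kept = records.loc[(records["epsilon"] < epsilon_max) & (records["p_value"] < p_max)]
    kept = _canonical_pairs(kept)
    kept = kept.sort_values("epsilon", kind="stable")
    kept = kept.drop_duplicates(subset=["gene_a", "gene_b"], keep="first")
    return kept.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)


def _pair_set(negatives: pd.DataFrame) -> set[tuple[str, str]]:
    return {
        tuple(sorted((a, b)))
        for a, b in zip(negatives["gene_a"], negatives["gene_b"])
    }


def _in_any_complex(pair: tuple[str, str], complexes: Sequence[GeneSet]) -> bool:
    a, b = pair
    return any(a in cx.members and b in cx.members for cx in complexes)


def within_pathway_counts(
    negatives: pd.DataFrame,
    pathway: GeneSet,
    complexes: Sequence[GeneSet] = (),
) -> tuple[int, int]:
    """Count negative pairs with both genes in the pathway, and the subset of
    those that also co-occur in at least one molecular complex."""
    pairs = _pair_set(negatives)
    within = [p for p in pairs if p[0] in pathway.members and p[1] in pathway.members]
    within_complex = sum(1 for p in within if _in_any_complex(p, complexes))
    return len(within), within_complex


def normalized_proportion(n_neg_excl_complex: int, n_genes: int) -> float:
    """Count divided by the S(S-1)/2 possible pairs of an S-gene pathway."""
    if n_genes < 2:
        raise UndefinedStatisticError(
            f"normalized proportion undefined for a pathway of {n_genes} gene(s)"
        )
    return n_neg_excl_complex / (n_genes * (n_genes - 1) / 2)


def rank_pathways(
    negatives: pd.DataFrame,
    pathways: Sequence[GeneSet],
    complexes: Sequence[GeneSet] = (),
    min_proportion: float = DEFAULT_MIN_PROPORTION,
) -> pd.DataFrame:
    """Per-pathway enrichment table, ranked by normalized proportion.

    Pathways below ``min_proportion`` are dropped (display filter).  Ties
    break by pathway size descending, then identifier.  Columns:
    pathway, n_genes, n_neg_within, n_neg_within_complex,
    n_neg_excl_complex, normalized_proportion.
    """
    rows = []
    for pw in pathways:
        n_within, n_cx = within_pathway_counts(negatives, pw, complexes)
        proportion = normalized_proportion(n_within - n_cx, pw.size) if pw.size >= 2 else 0.0
        rows.append(
            {
                "pathway": pw.id,
                "n_genes": pw.size,
                "n_neg_within": n_within,
                "n_neg_within_complex": n_cx,
                "n_neg_excl_complex": n_within - n_cx,
                "normalized_proportion": proportion,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "pathway",
            "n_genes",
            "n_neg_within",
            "n_neg_within_complex",
            "n_neg_excl_complex",
            "normalized_proportion",
        ],
    )
    table = table.loc[table["normalized_proportion"] >= min_proportion]
    table = table.sort_values(
        by=["normalized_proportion", "n_genes", "pathway"],
        ascending=[False, False, True],
        kind="stable",
    )
    return table.reset_index(drop=True)


def complex_fraction(
    negatives: pd.DataFrame,
    pathways: Sequence[GeneSet],
    complexes: Sequence[GeneSet] = (),
) -> float:
    """Fraction of all within-pathway negative pairs that lie within a complex.

    A pair occurring in several pathways is counted once in this global
    tally.  Undefined (raises) when there are no within-pathway negatives.
    """
    pairs = _pair_set(negatives)
    within = {
        p
        for p in pairs
        if any(p[0] in pw.members and p[1] in pw.members for pw in pathways)
    }
    if not within:
        raise UndefinedStatisticError("no within-pathway negative interactions")
    n_cx = sum(1 for p in within if _in_any_complex(p, complexes))
    return n_cx / len(within)
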