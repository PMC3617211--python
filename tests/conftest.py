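import numpy as np
import pandas as pd
import pytest

from kinetrap import GeneSet, RateSet, reference_ratesets


@pytest.fixture(scope="session")
def nr_rates() -> RateSet:
    return reference_ratesets()["NR"]


@pytest.fixture(scope="session")
def nf_rates() -> RateSet:
    return reference_ratesets()["NF"]


def random_ratesets(n: int, seed: int = 20260928, lo: float = 0.05, hi: float = 20.0):
    """Strictly positive (hence irreducible) log-uniform rate sets."""
    rng = np.random.default_rng(seed)
    draws = np.exp(rng.uniform(np.log(lo), np.log(hi), size=(n, 5)))
    return [RateSet(*row) for row in draws]


@pytest.fixture()
def toy_enrichment():
    """Five-gene pathway, three negative pairs, one within the {D, E} complex."""
    negatives = pd.DataFrame(
        {
            "gene_a": ["A", "A", "D"],
            "gene_b": ["B", "C", "E"],
            "epsilon": [-0.3, -0.25, -0.4],
            "p_value": [0.001, 0.002, 0.0005],
        }
    )
    pathway = GeneSet(id="toy", description="toy pathway", members=frozenset("ABCDE"))
    complexes = [GeneSet(id="cx", description="toy complex", members=frozenset("DE"))]
    return negatives, pathway, complexes
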