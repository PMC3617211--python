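"""Independent oracles used by the tests.

These deliberately avoid the package's own solution paths: the stationary
distribution comes from the Markov-chain tree theorem (spanning in-trees of
the 5-edge reaction graph, enumerated by hand), the long-time state from
scipy's matrix exponential at a very large time, and the enrichment counts
from a brute-force recount over all gene pairs.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import expm


def generator_matrix(k1, k_m1, k2, k_m2, k3):
    """dx/dt = Q x with columns as source states (S, I, P)."""
    return np.array(
        [
            [-(k1 + k3), k_m1, 0.0],
            [k1, -(k_m1 + k2), k_m2],
            [k3, k2, -k_m2],
        ]
    )


def tree_stationary(k1, k_m1, k2, k_m2, k3):
    """Stationary distribution by the tree theorem (irreducible chains).

    Spanning in-trees of the reaction graph S->I(k1), I->S(k_m1), I->P(k2),
    P->I(k_m2), S->P(k3), rooted at each state:
      w(S) = k_m1*k_m2
      w(I) = k_m2*(k1 + k3)
      w(P) = k1*k2 + k3*k2 + k3*k_m1
    """
    w_s = k_m1 * k_m2
    w_i = k_m2 * (k1 + k3)
    w_p = k1 * k2 + k3 * k2 + k3 * k_m1
    total = w_s + w_i + w_p
    return np.array([w_s, w_i, w_p]) / total


def longtime_state(k1, k_m1, k2, k_m2, k3, x0=(1.0, 0.0, 0.0), horizon=1e5):
    """Integrate to t = horizon / (smallest positive rate) via expm."""
    rates = (k1, k_m1, k2, k_m2, k3)
    t = horizon / min(r for r in rates if r > 0)
    return expm(generator_matrix(*rates) * t) @ np.asarray(x0, dtype=float)


def brute_force_enrichment(negative_pairs, pathway_members, complexes):
    """Recount (n_within, n_within_complex, proportion) over all pairs.

    negative_pairs: iterable of 2-tuples (order-insensitive, may repeat).
    pathway_members: iterable of gene ids.  complexes: iterable of member
    iterables.
    """
    members = sorted(set(pathway_members))
    negatives = {frozenset(p) for p in negative_pairs}
    complex_sets = [set(c) for c in complexes]
    n_within = 0
    n_within_complex = 0
    for a, b in itertools.combinations(members, 2):
        if frozenset((a, b)) not in negatives:
            continue
        n_within += 1
        if any(a in cx and b in cx for cx in complex_sets):
            n_within_complex += 1
    n_pairs = len(members) * (len(members) - 1) // 2
    proportion = (n_within - n_within_complex) / n_pairs if n_pairs else 0.0
    return n_within, n_within_complex, proportion
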