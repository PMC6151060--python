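"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the code paths they check: seed sets are
re-derived from a dense transitive closure, hypergeometric tails from exact
rational enumeration, and food scores from inline spreadsheet arithmetic.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from gutseed.network_io import Compound, MetabolicNetwork


def build_network(edges, nodes=(), organism_id="test") -> MetabolicNetwork:
    net = MetabolicNetwork(organism_id=organism_id)
    for n in nodes:
        net.add_compound(Compound(raw_id=n, base_id=n))
    for u, v in edges:
        net.add_edge(u, v)
    return net


def oracle_seed_set(net: MetabolicNetwork) -> dict[str, float]:
    """Brute-force seeds: v is a seed iff every u reaching v is reached by v.

    Confidence is 1/|mutual-reachability class of v|.  Dense reflexive
    transitive closure via repeated boolean matrix squaring.
    """
    nodes = sorted(net.compounds)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    reach = np.eye(n, dtype=bool)
    for u, v in net.edges:
        reach[idx[u], idx[v]] = True
    while True:
        nxt = reach | (reach @ reach)
        if (nxt == reach).all():
            break
        reach = nxt
    seeds = {}
    for v in range(n):
        ancestors = np.flatnonzero(reach[:, v])
        if all(reach[v, u] for u in ancestors):
            cls = sum(1 for u in ancestors if reach[v, u] and reach[u, v])
            seeds[nodes[v]] = 1.0 / cls
    return seeds


def oracle_hypergeom_tail(N: int, K: int, n: int, k: int) -> Fraction:
    """Exact upper-tail probability by rational enumeration."""
    total = comb(N, n)
    return Fraction(
        sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1)),
        total,
    )


def random_digraph(rng: np.random.Generator, n_max: int = 60,
                   density_range=(0.02, 0.2)) -> MetabolicNetwork:
    n = int(rng.integers(2, n_max + 1))
    density = rng.uniform(*density_range)
    nodes = [f"n{i:03d}" for i in range(n)]
    net = build_network([], nodes)
    mask = rng.random((n, n)) < density
    np.fill_diagonal(mask, False)
    for i, j in zip(*np.nonzero(mask)):
        net.add_edge(nodes[i], nodes[j])
    return net


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
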