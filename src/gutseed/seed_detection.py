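"""Seed-set detection on directed compound graphs.

The *seed set* of a metabolic network is the minimal set of compounds that
cannot be synthesized from other compounds in the network and must therefore
be acquired from the environment.  On the condensation of the graph into
strongly connected components (SCCs), seeds are exactly the members of
*source components* — SCCs with no incoming edges.  Each member of a source
component of size ``s`` receives confidence ``1/s``: the component as a whole
must be fed from outside, but any single member suffices to unlock it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .network_io import MetabolicNetwork

__all__ = ["SCCDecomposition", "SeedSet", "condensation", "detect_seeds", "seed_report"]


@dataclass
class SCCDecomposition:
    """Strongly connected components and the acyclic condensation graph.

    ``components`` is deterministic: each component's members are sorted, and
    components are sorted by their smallest member.  ``condensation_edges``
    contains (i, j) component-index pairs, i ≠ j.
    """

    components: list[tuple[str, ...]]
    condensation_edges: set[tuple[int, int]]

    @property
    def source_indices(self) -> list[int]:
        targets = {j for _, j in self.condensation_edges}
        return [i for i in range(len(self.components)) if i not in targets]


@dataclass
class SeedSet:
    """Per-organism exogenous-requirement profile: compound → confidence."""

    organism_id: str
    seeds: dict[str, float] = field(default_factory=dict)

    @property
    def total_weight(self) -> float:
        return sum(self.seeds.values())

    def __contains__(self, base_id: str) -> bool:
        return base_id in self.seeds

    def __len__(self) -> int:
        return len(self.seeds)

    def members(self) -> set[str]:
        return set(self.seeds)


def condensation(network: MetabolicNetwork) -> SCCDecomposition:
    """SCC decomposition with deterministic component ordering."""
    if not network.compounds:
        raise ValueError("cannot decompose an empty network")
    g = network.to_networkx()
    comps = [tuple(sorted(c)) for c in nx.strongly_connected_components(g)]
    comps.sort(key=lambda c: c[0])
    index = {node: i for i, comp in enumerate(comps) for node in comp}
    cedges = {
        (index[u], index[v]) for u, v in network.edges if index[u] != index[v]
    }
    return SCCDecomposition(components=comps, condensation_edges=cedges)


def detect_seeds(network: MetabolicNetwork, min_confidence: float = 0.0) -> SeedSet:
    """Identify the seed set of a network.

    Seeds are members of source components of the condensation; each gets
    confidence ``1/|component|``.  Members whose confidence falls below
    ``min_confidence`` are removed after assignment (default 0: keep all).
    With the full seed set every network node is reachable.
    """
    if not 0.0 <= min_confidence <= 1.0:
        raise ValueError("min_confidence must lie in [0, 1]")
    decomp = condensation(network)  # raises on empty network
    seeds: dict[str, float] = {}
    for i in decomp.source_indices:
        comp = decomp.components[i]
        conf = 1.0 / len(comp)
        if conf < min_confidence:
            continue
        for node in comp:
            seeds[node] = conf
    return SeedSet(organism_id=network.organism_id, seeds=seeds)


def seed_report(seed_set: SeedSet,
                catalog: dict | None = None) -> pd.DataFrame:
    """Tabulate a seed set: one row per seed compound.

    Sorted by descending confidence, then compound id.  ``catalog`` maps
    base_id → Compound (e.g. ``network.compounds``) to fill the name column.
    """
    catalog = catalog or {}
    rows = [
        {
            "compound_id": cid,
            "name": getattr(catalog.get(cid), "name", "") or "",
            "confidence": conf,
        }
        for cid, conf in seed_set.seeds.items()
    ]
    df = pd.DataFrame(rows, columns=["compound_id", "name", "confidence"])
    if len(df):
        df = df.sort_values(
            ["confidence", "compound_id"], ascending=[False, True]
        ).reset_index(drop=True)
    return df


def community_seed_matrix(seed_sets: list[SeedSet]) -> pd.DataFrame:
    """Wide compounds × organisms confidence matrix (0 where not a seed)."""
    ids = [s.organism_id for s in seed_sets]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate organism ids in community")
    universe = sorted(set().union(*(s.members() for s in seed_sets)) if seed_sets else set())
    data = {
        s.organism_id: [s.seeds.get(c, 0.0) for c in universe] for s in seed_sets
    }
    return pd.DataFrame(data, index=universe)
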