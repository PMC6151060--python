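"""Pairwise reverse-ecology indices over seed sets.

Three indices, all fractions of the *focal* organism's seed compounds and
asymmetric in general:

support(focal, host)
    Fraction of the focal organism's seeds present anywhere in the host
    network — the host's capacity to meet the microbe's requirements.
    High values (> 0.75) typify parasites; gut commensals score lower.
complementarity(focal, partner)
    Fraction of focal seeds found in the partner's network but *not* among
    the partner's own seeds — potential for syntrophy/crossfeeding.
competition(focal, partner)
    Fraction of focal seeds that are also partner seeds — nutritional niche
    overlap.

The confidence-weighted variants (default) weight each seed by its
1/|source component| confidence; the unweighted variants count members.
For any pair, weighted complementarity + weighted competition equals the
weighted fraction of focal seeds present in the partner's network.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .network_io import MetabolicNetwork
from .seed_detection import SeedSet

__all__ = [
    "InteractionScore",
    "biosynthetic_support",
    "complementarity",
    "competition",
    "pairwise_matrices",
    "write_matrix_tsv",
]

PARASITE_SUPPORT_THRESHOLD = 0.75


@dataclass(frozen=True)
class InteractionScore:
    focal: str
    partner: str
    kind: str  # support | complementarity | competition
    value: float
    weighted: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0 + 1e-12:
            raise ValueError(f"{self.kind} index {self.value} outside [0, 1]")


def _fraction(seed_set: SeedSet, member_test, weighted: bool) -> float:
    if not seed_set.seeds:
        raise ValueError(f"organism {seed_set.organism_id!r} has an empty seed set")
    if weighted:
        hit = sum(conf for cid, conf in seed_set.seeds.items() if member_test(cid))
        return hit / seed_set.total_weight
    hit = sum(1 for cid in seed_set.seeds if member_test(cid))
    return hit / len(seed_set.seeds)


def biosynthetic_support(focal: SeedSet, host_network: MetabolicNetwork,
                         weighted: bool = True) -> InteractionScore:
    """Fraction of focal seeds present as nodes of the host network."""
    host_nodes = host_network.nodes
    value = _fraction(focal, host_nodes.__contains__, weighted)
    return InteractionScore(focal.organism_id, host_network.organism_id,
                            "support", value, weighted)


def complementarity(focal: SeedSet, partner: SeedSet,
                    partner_network: MetabolicNetwork,
                    weighted: bool = True) -> InteractionScore:
    """Fraction of focal seeds in the partner's network but not its seeds."""
    nodes = partner_network.nodes
    value = _fraction(
        focal, lambda cid: cid in nodes and cid not in partner.seeds, weighted
    )
    return InteractionScore(focal.organism_id, partner.organism_id,
                            "complementarity", value, weighted)


def competition(focal: SeedSet, partner: SeedSet,
                weighted: bool = True) -> InteractionScore:
    """Fraction of focal seeds that are also partner seeds."""
    if not partner.seeds:
        raise ValueError(f"organism {partner.organism_id!r} has an empty seed set")
    value = _fraction(focal, partner.seeds.__contains__, weighted)
    return InteractionScore(focal.organism_id, partner.organism_id,
                            "competition", value, weighted)


def pairwise_matrices(community: list[tuple[SeedSet, MetabolicNetwork]],
                      host: MetabolicNetwork | None = None,
                      weighted: bool = True) -> dict[str, pd.DataFrame]:
    """Full ordered-pair index grids for a community.

    Row = focal organism, column = partner.  Diagonals: competition 1.0,
    complementarity 0.0.  When ``host`` is given, a one-column ``support``
    frame (organism × host) is included.  Returns
    ``{"competition": ..., "complementarity": ..., ["support": ...]}``.
    """
    if len(community) < 2:
        raise ValueError("need at least 2 organisms")
    ids = [s.organism_id for s, _ in community]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate organism_id in community")

    comp = pd.DataFrame(0.0, index=ids, columns=ids)
    compl = pd.DataFrame(0.0, index=ids, columns=ids)
    for fs, _ in community:
        for ps, pnet in community:
            comp.loc[fs.organism_id, ps.organism_id] = competition(
                fs, ps, weighted).value
            compl.loc[fs.organism_id, ps.organism_id] = complementarity(
                fs, ps, pnet, weighted).value
    out = {"competition": comp, "complementarity": compl}
    if host is not None:
        out["support"] = pd.DataFrame(
            {host.organism_id: [
                biosynthetic_support(fs, host, weighted).value
                for fs, _ in community
            ]},
            index=ids,
        )
    return out


def overlap_diagnostics(community: list[tuple[SeedSet, MetabolicNetwork]]) -> pd.DataFrame:
    """Per-pair raw node/seed overlap counts.

    A matrix of all-zero indices usually means a namespace mismatch between
    models (e.g. KEGG vs BiGG compound ids); these counts expose it.
    """
    rows = []
    for fs, _ in community:
        for ps, pnet in community:
            if fs.organism_id == ps.organism_id:
                continue
            rows.append({
                "focal": fs.organism_id,
                "partner": ps.organism_id,
                "seed_node_overlap": len(fs.members() & pnet.nodes),
                "seed_seed_overlap": len(fs.members() & ps.members()),
            })
    return pd.DataFrame(rows, columns=["focal", "partner",
                                       "seed_node_overlap", "seed_seed_overlap"])


def write_matrix_tsv(matrix: pd.DataFrame, path, weighted: bool = True) -> None:
    """Emit a matrix with the row/column convention in a header comment."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# focal=row partner=column weighted={str(weighted).lower()}\n")
        matrix.to_csv(fh, sep="\t", lineterminator="\n")
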