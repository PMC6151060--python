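"""Community-level partition of seed compounds.

Splits the union of a community's seed compounds into *core* (required by
every member), *unique* (required by exactly one member, when the community
has more than one member) and *shared* (required by at least two members but
not all).  Membership, not confidence, drives the partition — the counts
mirror how communities of strains are usually summarized.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .seed_detection import SeedSet

__all__ = ["SeedPartition", "partition_seeds", "group_summary", "GroupSummary"]


@dataclass
class SeedPartition:
    universe: set[str]
    core: set[str]
    unique: set[str]
    shared: set[str]
    n_organisms: int

    def sizes(self) -> dict[str, int]:
        return {
            "universe": len(self.universe),
            "core": len(self.core),
            "unique": len(self.unique),
            "shared": len(self.shared),
        }


def partition_seeds(seed_sets: list[SeedSet]) -> SeedPartition:
    """Exact set algebra over seed membership.

    For a single-organism community core takes precedence: every seed is
    core, unique and shared are empty, keeping |core|+|unique|+|shared| =
    |universe| valid for any community size.
    """
    if not seed_sets:
        raise ValueError("need at least one organism")
    k = len(seed_sets)
    counts: Counter[str] = Counter()
    for s in seed_sets:
        counts.update(s.members())
    universe = set(counts)
    core = {c for c, n in counts.items() if n == k}
    if k == 1:
        unique: set[str] = set()
        shared: set[str] = set()
    else:
        unique = {c for c, n in counts.items() if n == 1}
        shared = {c for c, n in counts.items() if 2 <= n < k}
    return SeedPartition(universe=universe, core=core, unique=unique,
                         shared=shared, n_organisms=k)


@dataclass
class GroupSummary:
    partitions: dict[str, SeedPartition]
    # exclusives[(a, b)] = compounds in group a's universe absent from b's
    exclusives: dict[tuple[str, str], set[str]] = field(default_factory=dict)


def group_summary(seed_sets: list[SeedSet],
                  grouping: dict[str, str]) -> GroupSummary:
    """Per-taxon-group partitions plus cross-group exclusive compounds.

    ``grouping`` maps organism_id → group label (e.g. genus); every organism
    must be labeled.
    """
    unlabeled = [s.organism_id for s in seed_sets if s.organism_id not in grouping]
    if unlabeled:
        raise ValueError(f"unlabeled organisms: {sorted(unlabeled)}")
    by_label: dict[str, list[SeedSet]] = {}
    for s in seed_sets:
        by_label.setdefault(grouping[s.organism_id], []).append(s)
    partitions = {label: partition_seeds(members)
                  for label, members in sorted(by_label.items())}
    exclusives = {}
    for a in partitions:
        for b in partitions:
            if a != b:
                exclusives[(a, b)] = (
                    partitions[a].universe - partitions[b].universe
                )
    return GroupSummary(partitions=partitions, exclusives=exclusives)
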