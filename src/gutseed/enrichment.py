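"""Hypergeometric overrepresentation of seed compounds in pathways.

For each organism, seed compounds carrying a KEGG identifier are tested for
overrepresentation in each metabolism-class pathway.  With a universe of N
compounds, K of them in the pathway, n seed compounds in the universe and k
in the overlap, the p value is the upper tail

    p = sum_{i=k}^{min(K,n)} C(K,i) C(N-K, n-i) / C(N,n).

Raw p values are compared to 0.05; no multiple-testing correction is applied
by default (a Benjamini–Hochberg option is provided).  The universe is
per-organism: the union of compounds over that organism's pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .seed_detection import SeedSet

__all__ = [
    "PathwayAnnotation",
    "EnrichmentResult",
    "hypergeom_upper_tail",
    "enrich_seeds",
    "community_enrichment_summary",
]

SIGNIFICANCE_THRESHOLD = 0.05


@dataclass
class PathwayAnnotation:
    """Organism-scoped pathway → compound-set map (metabolism class only)."""

    organism_id: str
    pathways: dict[str, tuple[str, frozenset[str]]]  # id -> (name, compounds)
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.universe:
            self.universe = frozenset().union(
                *(c for _, c in self.pathways.values())
            ) if self.pathways else frozenset()
        for pid, (_, comps) in self.pathways.items():
            if not comps <= self.universe:
                raise ValueError(f"pathway {pid} has compounds outside the universe")


@dataclass(frozen=True)
class EnrichmentResult:
    organism_id: str
    pathway_id: str
    pathway_name: str
    N: int
    K: int
    n: int
    k: int
    p: float

    @property
    def significant(self) -> bool:
        return self.p < SIGNIFICANCE_THRESHOLD


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n), computed stably.

    k = 0 gives exactly 1.0.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"invalid hypergeometric bounds N={N} K={K} n={n} k={k}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_seeds(seed_set: SeedSet, annotation: PathwayAnnotation,
                 kegg_map: dict[str, str] | None = None) -> tuple[list[EnrichmentResult], dict]:
    """Test every pathway of an annotation for seed overrepresentation.

    ``kegg_map`` maps seed base ids to KEGG compound ids; identity when
    omitted (seeds already in KEGG namespace).  Seeds without a KEGG id or
    outside the universe are excluded from n; the exclusion counts are
    returned alongside the results.  One result per pathway with K >= 1.
    """
    if not annotation.universe:
        raise ValueError("annotation universe is empty")
    mapped, no_kegg = [], 0
    for cid in seed_set.members():
        kid = kegg_map.get(cid) if kegg_map is not None else cid
        if kid is None:
            no_kegg += 1
        else:
            mapped.append(kid)
    in_universe = sorted(set(mapped) & annotation.universe)
    outside = len(set(mapped)) - len(in_universe)

    N = len(annotation.universe)
    n = len(in_universe)
    seed_kegg = set(in_universe)
    results = []
    for pid in sorted(annotation.pathways):
        name, comps = annotation.pathways[pid]
        K = len(comps)
        if K < 1:
            continue
        k = len(seed_kegg & comps)
        results.append(EnrichmentResult(
            organism_id=seed_set.organism_id, pathway_id=pid,
            pathway_name=name, N=N, K=K, n=n, k=k,
            p=hypergeom_upper_tail(N, K, n, k),
        ))
    info = {"seeds_total": len(seed_set), "no_kegg_id": no_kegg,
            "outside_universe": outside, "tested_n": n}
    return results, info


def benjamini_hochberg(pvals: list[float]) -> list[float]:
    """BH-adjusted q values (monotone step-up)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q.tolist()


def community_enrichment_summary(
    results_by_organism: dict[str, list[EnrichmentResult]],
    headline_threshold: float = SIGNIFICANCE_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate per-organism enrichment over a community.

    Returns ``(summary, long)``.  ``summary`` has one row per pathway with
    the mean p over organisms in which the pathway exists (absent pathways
    contribute nothing), the number of organisms where it is significant,
    and a headline flag (mean p below threshold).  ``long`` is the full
    organism × pathway record for heatmapping.
    """
    if not results_by_organism:
        raise ValueError("no results supplied")
    rows = []
    for org, results in results_by_organism.items():
        for r in results:
            rows.append({
                "organism_id": org, "pathway_id": r.pathway_id,
                "pathway_name": r.pathway_name,
                "N": r.N, "K": r.K, "n": r.n, "k": r.k,
                "p": r.p, "significant": r.significant,
            })
    long = pd.DataFrame(rows, columns=[
        "organism_id", "pathway_id", "pathway_name",
        "N", "K", "n", "k", "p", "significant"])
    if long.empty:
        return (pd.DataFrame(columns=["pathway_id", "pathway_name", "mean_p",
                                      "n_significant", "n_tested", "headline"]),
                long)
    grp = long.groupby(["pathway_id", "pathway_name"], sort=True)
    summary = grp.agg(
        mean_p=("p", "mean"),
        n_significant=("significant", "sum"),
        n_tested=("p", "size"),
    ).reset_index()
    summary["n_significant"] = summary["n_significant"].astype(int)
    summary["headline"] = summary["mean_p"] < headline_threshold
    return summary.sort_values(["mean_p", "pathway_id"]).reset_index(drop=True), long


def read_annotation_tsv(path) -> dict[str, PathwayAnnotation]:
    """Load `organism	pathway_id	pathway_name	compound_id` TSV into annotations."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = ["organism", "pathway_id", "pathway_name", "compound_id"]
    if list(df.columns) != required:
        raise ValueError(f"annotation TSV must have columns {required}")
    out = {}
    for org, sub in df.groupby("organism", sort=True):
        pathways = {}
        for (pid, name), rows in sub.groupby(["pathway_id", "pathway_name"], sort=True):
            pathways[pid] = (name, frozenset(rows["compound_id"]))
        out[org] = PathwayAnnotation(organism_id=org, pathways=pathways)
    return out
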