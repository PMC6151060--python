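"""Synthetic inputs with planted ground truth.

Every pipeline stage has a generator here that fabricates its input *and* a
manifest recording the truth planted into it (true seed sets, programmed
pairwise overlaps, the enriched pathway, food-cascade survivors, corpus term
placements).  Manifest quantities are computed by direct construction or
brute-force enumeration inside the generator, never by calling the module
under test, so recovery tests are exact rather than statistical.

All generators are deterministic under a single integer seed; each draws
from its own named RNG stream, so adding a generator never perturbs the
fixtures of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np

from .comention_mining import DictEntry, Dictionary, DocumentRecord
from .enrichment import PathwayAnnotation
from .network_io import Compound, MetabolicNetwork
from .seed_detection import SeedSet

__all__ = [
    "stream_rng",
    "generate_network",
    "generate_community",
    "generate_food_table",
    "generate_annotation",
    "generate_corpus",
    "default_dictionaries",
    "CommunityDesign",
]

_STREAMS = {"network": 1, "community": 2, "food": 3, "annotation": 4, "corpus": 5}


def stream_rng(rng_seed: int, stream: str) -> np.random.Generator:
    """Named RNG stream derived from one integer seed."""
    return np.random.default_rng(np.random.SeedSequence([int(rng_seed), _STREAMS[stream]]))


# ---------------------------------------------------------------------------
# directed compound graphs with planted source components

def generate_network(
    n_components: int,
    component_size_dist: Sequence[int] | tuple[int, int] = (1, 4),
    n_source_components: int = 1,
    rng_seed: int = 0,
    organism_id: str = "synthetic",
) -> tuple[MetabolicNetwork, SeedSet, dict]:
    """Random digraph with exactly ``n_source_components`` source SCCs.

    An acyclic component skeleton is built with the first
    ``n_source_components`` components as sources (no incoming skeleton
    edges) and every other component given at least one parent; each
    component is expanded to a strongly connected subgraph (cycle plus
    random chords), and skeleton edges become node-level edges.  True seeds
    are the members of source components at confidence 1/|component|.
    """
    if not 1 <= n_source_components <= n_components:
        raise ValueError("need 1 <= n_source_components <= n_components")
    rng = stream_rng(rng_seed, "network")
    if isinstance(component_size_dist, tuple) and len(component_size_dist) == 2:
        lo, hi = component_size_dist
        sizes = [int(rng.integers(lo, hi + 1)) for _ in range(n_components)]
    else:
        sizes = [int(s) for s in component_size_dist]
        if len(sizes) != n_components:
            raise ValueError("explicit size list must have n_components entries")
    if any(s < 1 for s in sizes):
        raise ValueError("component sizes must be >= 1")

    comp_nodes = [
        [f"c{i:03d}n{j:02d}" for j in range(sizes[i])] for i in range(n_components)
    ]
    net = MetabolicNetwork(organism_id=organism_id,
                           provenance={"source": "generate_network",
                                       "rng_seed": rng_seed})
    for nodes in comp_nodes:
        for n in nodes:
            net.add_compound(Compound(raw_id=n, base_id=n))

    # strong connectivity inside each component: a cycle plus chords
    for nodes in comp_nodes:
        s = len(nodes)
        if s == 1:
            continue
        for j in range(s):
            net.add_edge(nodes[j], nodes[(j + 1) % s])
        n_chords = int(rng.integers(0, s))
        for _ in range(n_chords):
            a, b = rng.integers(0, s, size=2)
            if a != b:
                net.add_edge(nodes[a], nodes[b])

    # acyclic skeleton: edges only from lower to higher component index,
    # targets restricted to non-source components
    skeleton = set()
    for j in range(n_source_components, n_components):
        parent = int(rng.integers(0, j))
        skeleton.add((parent, j))
        for extra in range(j):
            if rng.random() < 0.15:
                skeleton.add((extra, j))
    for i, j in sorted(skeleton):
        u = comp_nodes[i][int(rng.integers(0, sizes[i]))]
        v = comp_nodes[j][int(rng.integers(0, sizes[j]))]
        net.add_edge(u, v)

    seeds = {}
    for i in range(n_source_components):
        conf = 1.0 / sizes[i]
        for n in comp_nodes[i]:
            seeds[n] = conf
    true_seeds = SeedSet(organism_id=organism_id, seeds=seeds)
    manifest = {
        "rng_seed": rng_seed,
        "component_sizes": sizes,
        "n_source_components": n_source_components,
        "components": [list(nodes) for nodes in comp_nodes],
        "true_seeds": dict(seeds),
        "n_edges": len(net.edges),
    }
    return net, true_seeds, manifest


# ---------------------------------------------------------------------------
# communities with programmed pairwise seed overlap

@dataclass
class CommunityDesign:
    organisms: list[tuple[SeedSet, MetabolicNetwork]]
    host: Optional[MetabolicNetwork]
    manifest: dict = field(default_factory=dict)


def generate_community(
    k: int,
    seeds_per_organism: int | Sequence[int] = 10,
    overlap_matrix: Optional[Sequence[Sequence[float]]] = None,
    complementarity_matrix: Optional[Sequence[Sequence[float]]] = None,
    host_support: Optional[Sequence[float]] = None,
    rng_seed: int = 0,
) -> CommunityDesign:
    """Community with exact programmed pairwise seed overlap.

    Every seed is a singleton source component (confidence 1).  Shared
    compounds are exclusive to their pair, so
    ``|seed_i ∩ seed_j| / |seed_i|`` hits the overlap target exactly;
    complementarity targets are planted as internal (non-seed) nodes of the
    partner network drawn from the focal organism's unique seeds; host
    support targets likewise use unique seeds.  Targets must be realizable
    as integer counts — infeasible designs raise with the violated
    constraint.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = ([int(seeds_per_organism)] * k if isinstance(seeds_per_organism, int)
         else [int(x) for x in seeds_per_organism])
    if len(n) != k:
        raise ValueError("seeds_per_organism must be scalar or length k")

    def _target_count(frac: float, total: int, what: str) -> int:
        cnt = frac * total
        if abs(cnt - round(cnt)) > 1e-9:
            raise ValueError(
                f"infeasible design: {what} target {frac} of {total} seeds "
                "is not an integer count")
        return int(round(cnt))

    shared_counts: dict[tuple[int, int], int] = {}
    if overlap_matrix is not None:
        ov = np.asarray(overlap_matrix, dtype=float)
        if ov.shape != (k, k):
            raise ValueError("overlap_matrix must be k x k")
        for i, j in combinations(range(k), 2):
            cij = _target_count(ov[i][j], n[i], f"overlap({i},{j})")
            cji = _target_count(ov[j][i], n[j], f"overlap({j},{i})")
            if cij != cji:
                raise ValueError(
                    f"infeasible design: overlap({i},{j}) implies "
                    f"{cij} shared compounds but overlap({j},{i}) implies {cji}")
            shared_counts[(i, j)] = cij
    for i in range(k):
        total_shared = sum(c for (a, b), c in shared_counts.items() if i in (a, b))
        if total_shared > n[i]:
            raise ValueError(
                f"infeasible design: organism {i} needs {total_shared} shared "
                f"seeds but has only {n[i]}")

    seed_ids: list[list[str]] = [[] for _ in range(k)]
    for (i, j), cnt in sorted(shared_counts.items()):
        for t in range(cnt):
            cid = f"shr_{i:02d}_{j:02d}_{t:02d}"
            seed_ids[i].append(cid)
            seed_ids[j].append(cid)
    n_unique = []
    for i in range(k):
        need = n[i] - len(seed_ids[i])
        n_unique.append(need)
        for t in range(need):
            seed_ids[i].append(f"unq_{i:02d}_{t:02d}")

    # complementarity plantings: focal-unique compounds inserted as internal
    # nodes of the partner network
    planted_internal: dict[int, list[str]] = {j: [] for j in range(k)}
    comp_targets = np.zeros((k, k))
    if complementarity_matrix is not None:
        cm = np.asarray(complementarity_matrix, dtype=float)
        if cm.shape != (k, k):
            raise ValueError("complementarity_matrix must be k x k")
        for i in range(k):
            for j in range(k):
                if i == j:
                    if cm[i][j] != 0:
                        raise ValueError("complementarity diagonal must be 0")
                    continue
                cnt = _target_count(cm[i][j], n[i], f"complementarity({i},{j})")
                if cnt > n_unique[i]:
                    raise ValueError(
                        f"infeasible design: complementarity({i},{j}) needs "
                        f"{cnt} unique seeds of organism {i}, only {n_unique[i]}")
                uniq = [c for c in seed_ids[i] if c.startswith("unq_")]
                planted_internal[j].extend(uniq[:cnt])
                comp_targets[i][j] = cm[i][j]

    organisms = []
    for i in range(k):
        net = MetabolicNetwork(organism_id=f"org{i:02d}",
                               provenance={"source": "generate_community",
                                           "rng_seed": rng_seed})
        sink = f"int_{i:02d}_sink"
        net.add_compound(Compound(raw_id=sink, base_id=sink))
        for cid in seed_ids[i]:
            net.add_compound(Compound(raw_id=cid, base_id=cid))
            net.add_edge(cid, sink)
        for cid in planted_internal[i]:
            net.add_edge(sink, cid)
        seeds = SeedSet(organism_id=net.organism_id,
                        seeds={cid: 1.0 for cid in seed_ids[i]})
        organisms.append((seeds, net))

    host = None
    support_targets = None
    if host_support is not None:
        if len(host_support) != k:
            raise ValueError("host_support must have length k")
        host = MetabolicNetwork(organism_id="host",
                                provenance={"source": "generate_community"})
        hub = "host_hub"
        host.add_compound(Compound(raw_id=hub, base_id=hub))
        support_targets = []
        for i, frac in enumerate(host_support):
            cnt = _target_count(frac, n[i], f"host_support({i})")
            if cnt > n_unique[i]:
                raise ValueError(
                    f"infeasible design: host_support({i}) needs {cnt} unique "
                    f"seeds of organism {i}, only {n_unique[i]}")
            uniq = [c for c in seed_ids[i] if c.startswith("unq_")]
            for cid in uniq[:cnt]:
                host.add_edge(hub, cid)
            support_targets.append(cnt / n[i])

    competition_targets = np.eye(k)
    for (i, j), cnt in shared_counts.items():
        competition_targets[i][j] = cnt / n[i]
        competition_targets[j][i] = cnt / n[j]

    manifest = {
        "rng_seed": rng_seed,
        "k": k,
        "seeds_per_organism": n,
        "seed_ids": [list(s) for s in seed_ids],
        "competition": competition_targets.tolist(),
        "complementarity": comp_targets.tolist(),
        "support": support_targets,
    }
    return CommunityDesign(organisms=organisms, host=host, manifest=manifest)


# ---------------------------------------------------------------------------
# food-composition tables with planted cascade violations

_FOOD_WEIGHTS = {  # kept inline so manifest scoring is independent
    "vitamins": 10.0, "amino_acids": 8.0, "oligosaccharides": 6.0,
    "bioactive_substances": 4.0, "nitrogenous_compounds": 2.0,
    "monosaccharides": 1.0, "NSN": -100.0,
}
_CATS = tuple(_FOOD_WEIGHTS)
_GROWTH = ("amino_acids", "vitamins", "oligosaccharides", "monosaccharides")
# mg/100 g log-normal location per category, loosely spanning the orders of
# magnitude seen in composition databases (vitamins trace, sugars bulk)
_CAT_SCALE = {
    "vitamins": 0.5, "amino_acids": 50.0, "oligosaccharides": 100.0,
    "bioactive_substances": 20.0, "nitrogenous_compounds": 5.0,
    "monosaccharides": 500.0, "NSN": 1.0,
}


def generate_food_table(
    n_foods: int = 50,
    compounds_per_category: int = 3,
    n_unmatched_seed_names: int = 5,
    n_loq_violators: int = 3,
    n_class_violators: int = 3,
    n_growth_violators: int = 3,
    n_no_match: int = 2,
    rng_seed: int = 0,
):
    """Food table emulating a composition database, with planted violations.

    Returns ``(table, category_map, seed_names, manifest)``.  ``table`` is a
    pandas DataFrame in the food-table schema.  Designated foods violate
    exactly one cascade stage each; one baby-food control row passes through
    unfiltered.  The manifest records per-stage survivor sets and a score
    ranking computed with straight spreadsheet-style arithmetic, independent
    of the scoring module.
    """
    import pandas as pd

    if n_foods < 1:
        raise ValueError("n_foods must be >= 1")
    rng = stream_rng(rng_seed, "food")

    compounds = {}
    for cat in _CATS:
        for t in range(compounds_per_category):
            compounds[f"cmp {cat} {t:02d}".replace("_", " ")] = cat
    comp_names = sorted(compounds)
    seed_names = set(comp_names) | {
        f"vmh internal {t:02d}" for t in range(n_unmatched_seed_names)
    }

    n_special = n_loq_violators + n_class_violators + n_growth_violators + n_no_match + 1
    if n_special > n_foods:
        raise ValueError("not enough foods for the requested planted violations")

    rows = []
    roles = {}
    fid_list = [f"food_{i:03d}" for i in range(n_foods)]
    cursor = 0

    def take(count, role):
        nonlocal cursor
        ids = fid_list[cursor:cursor + count]
        for f in ids:
            roles[f] = role
        cursor += count
        return ids

    loq_foods = take(n_loq_violators, "loq_violator")
    class_foods = take(n_class_violators, "class_violator")
    growth_foods = take(n_growth_violators, "growth_violator")
    nomatch_foods = take(n_no_match, "no_match")
    control_foods = take(1, "control")
    regular_foods = take(n_foods - cursor, "regular")

    def conc(cat):
        return float(np.round(_CAT_SCALE[cat] * rng.lognormal(0.0, 0.8), 2))

    def add_full_profile(fid, food_class, detection="quantified"):
        # one compound from every category, all growth factors present
        for cat in _CATS:
            name = f"cmp {cat} 00".replace("_", " ")
            rows.append((fid, f"Food {fid[-3:]}", food_class, name,
                         conc(cat) if detection == "quantified" else np.nan,
                         detection))

    for fid in regular_foods:
        # random subset per category but growth factors guaranteed
        for cat in _CATS:
            n_have = int(rng.integers(1, compounds_per_category + 1)) \
                if cat in _GROWTH else int(rng.integers(0, compounds_per_category + 1))
            picks = rng.choice(compounds_per_category, size=n_have, replace=False)
            for t in sorted(int(x) for x in picks):
                name = f"cmp {cat} {t:02d}".replace("_", " ")
                rows.append((fid, f"Food {fid[-3:]}", "regular", name,
                             conc(cat), "quantified"))

    for fid in loq_foods:
        add_full_profile(fid, "regular", detection="below_LOQ")
    for i, fid in enumerate(class_foods):
        cls = ["processed", "alcohol", "other-undefined"][i % 3]
        add_full_profile(fid, cls)
    for fid in growth_foods:
        missing = _GROWTH[int(rng.integers(0, len(_GROWTH)))]
        for cat in _CATS:
            name = f"cmp {cat} 00".replace("_", " ")
            if cat == missing:
                rows.append((fid, f"Food {fid[-3:]}", "regular", name,
                             np.nan, "not_detected"))
            else:
                rows.append((fid, f"Food {fid[-3:]}", "regular", name,
                             conc(cat), "quantified"))
    for fid in nomatch_foods:
        rows.append((fid, f"Food {fid[-3:]}", "regular", "filler compound",
                     conc("NSN"), "quantified"))
    for fid in control_foods:
        add_full_profile(fid, "baby-food")

    table = pd.DataFrame(rows, columns=[
        "food_id", "food_name", "food_class", "compound_name",
        "concentration_mg_per_100g", "detection"])

    # --- manifest: cascade + scoring by direct arithmetic -----------------
    matched = set(comp_names)  # every table compound except the filler
    matched_rows = table[table["compound_name"].isin(matched)]
    stage1 = set(matched_rows["food_id"])

    def control(fid):
        return roles[fid] == "control"

    stage2 = {f for f in stage1 if control(f) or not (
        matched_rows[matched_rows["food_id"] == f]["detection"] != "quantified"
    ).all()}
    stage3 = {f for f in stage2 if control(f)
              or roles[f] not in ("class_violator",)}
    stage4 = set()
    for f in stage3:
        if control(f):
            stage4.add(f)
            continue
        sub = matched_rows[(matched_rows["food_id"] == f)
                           & (matched_rows["detection"] != "not_detected")]
        cats_present = {compounds[nm] for nm in sub["compound_name"]}
        if all(c in cats_present for c in _GROWTH):
            stage4.add(f)

    profiles = {}
    for f in sorted(stage4):
        sub = matched_rows[(matched_rows["food_id"] == f)
                           & (matched_rows["detection"] == "quantified")]
        prof = {c: 0.0 for c in _CATS}
        for cat in _CATS:
            vals = [v for nm, v in zip(sub["compound_name"],
                                       sub["concentration_mg_per_100g"])
                    if compounds[nm] == cat]
            if vals:
                prof[cat] = float(np.mean(vals))
        profiles[f] = prof

    scores = {}
    for cat in _CATS:
        vals = [profiles[f][cat] for f in profiles]
        lo, hi = min(vals), max(vals)
        for f in profiles:
            norm = 0.0 if hi == lo else (profiles[f][cat] - lo) / (hi - lo)
            scores[f] = scores.get(f, 0.0) + _FOOD_WEIGHTS[cat] * norm
    ranking = sorted(profiles, key=lambda f: (-scores[f], f"Food {f[-3:]}"))

    manifest = {
        "rng_seed": rng_seed,
        "roles": roles,
        "matched_count": len(matched),
        "unmatched_count": n_unmatched_seed_names,
        "cascade": {
            "stage1_contains_matched": len(stage1),
            "stage2_above_loq": len(stage2),
            "stage3_allowed_class": len(stage3),
            "stage4_growth_factors_detected": len(stage4),
        },
        "survivors": sorted(stage4),
        "profiles": profiles,
        "scores": scores,
        "ranking": ranking,
    }
    category_map = dict(compounds)
    return table, category_map, seed_names, manifest


# ---------------------------------------------------------------------------
# pathway annotations with a planted enriched pathway

def generate_annotation(
    n_pathways: int = 20,
    universe_size: int = 200,
    n_seed_compounds: int = 15,
    planted_pathway_size: int = 10,
    planted_overlap: int = 8,
    background_pathway_size: tuple[int, int] = (5, 30),
    organism_id: str = "synthetic",
    seed_compounds: Optional[Sequence[str]] = None,
    rng_seed: int = 0,
) -> tuple[PathwayAnnotation, list[str], dict]:
    """Annotation with one pathway given elevated seed overlap.

    Background pathways draw compounds uniformly from the universe; the
    planted pathway takes ``planted_overlap`` compounds from the seed list
    and the rest from non-seeds.  ``seed_compounds`` may fix the seed list
    explicitly (must lie inside the universe); otherwise it is sampled.
    The manifest records (N, K, n, k) for every pathway, counted directly
    during construction.
    """
    rng = stream_rng(rng_seed, "annotation")
    universe = [f"C{i + 1:05d}" for i in range(universe_size)]
    if seed_compounds is not None:
        seed_list = sorted(str(c) for c in seed_compounds)
        if not set(seed_list) <= set(universe):
            raise ValueError("seed_compounds must lie inside the universe")
        n_seed_compounds = len(seed_list)
    else:
        seed_list = sorted(
            str(x) for x in rng.choice(universe, size=n_seed_compounds,
                                       replace=False)
        )
    if planted_overlap > min(planted_pathway_size, n_seed_compounds):
        raise ValueError("planted overlap exceeds pathway or seed size")
    non_seeds = sorted(set(universe) - set(seed_list))

    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    planted_id = "path000"
    chosen = list(rng.choice(seed_list, size=planted_overlap, replace=False))
    chosen += list(rng.choice(
        non_seeds, size=planted_pathway_size - planted_overlap, replace=False))
    pathways[planted_id] = ("Planted pathway", frozenset(str(c) for c in chosen))
    for p in range(1, n_pathways):
        size = int(rng.integers(background_pathway_size[0],
                                background_pathway_size[1] + 1))
        comps = frozenset(
            str(x) for x in rng.choice(universe, size=size, replace=False))
        pathways[f"path{p:03d}"] = (f"Background pathway {p}", comps)

    annotation = PathwayAnnotation(organism_id=organism_id, pathways=pathways,
                                   universe=frozenset(universe))
    seed_set = set(seed_list)
    manifest = {
        "rng_seed": rng_seed,
        "planted_pathway": planted_id,
        "per_pathway": {
            pid: {"N": universe_size, "K": len(comps),
                  "n": n_seed_compounds, "k": len(seed_set & comps)}
            for pid, (_, comps) in pathways.items()
        },
    }
    return annotation, seed_list, manifest


# ---------------------------------------------------------------------------
# corpora with planted dictionary co-mentions

CONCEPT_DICTIONARIES = (
    "gut-microbes", "immune-related", "infection-disease", "chemical-related",
)

_DEFAULT_TERMS = {
    "gut-microbes": [
        DictEntry("Lactobacillus rhamnosus", "Lactobacillus rhamnosus", "species"),
        DictEntry("Lactobacillus casei", "Lactobacillus casei", "species"),
        DictEntry("Bifidobacterium breve", "Bifidobacterium breve", "species"),
        DictEntry("Akkermansia muciniphila", "Akkermansia muciniphila", "species"),
        DictEntry("Lactobacillus", "Lactobacillus", "genus"),
        DictEntry("Bifidobacterium", "Bifidobacterium", "genus"),
        DictEntry("Clostridium difficile", "Clostridium difficile", "species",
                  pathogen=True),
    ],
    "immune-related": [
        DictEntry("immune system", "immune system"),
        DictEntry("cytokine", "cytokine"),
        DictEntry("immunoglobulin", "immunoglobulin"),
    ],
    "infection-disease": [
        DictEntry("diarrhea", "diarrhea"),
        DictEntry("respiratory infection", "respiratory infection"),
        DictEntry("sepsis", "sepsis"),
    ],
    "chemical-related": [
        DictEntry("oligofructose", "oligofructose"),
        DictEntry("butyrate", "butyrate"),
        DictEntry("acetate", "acetate"),
    ],
    "filter-terms": [
        DictEntry("zebrafish", "zebrafish", excluded_animal=True),
        DictEntry("piglet", "piglet", excluded_animal=True),
    ],
}


def default_dictionaries() -> list[Dictionary]:
    """The four concept dictionaries plus filter terms, with tags."""
    return [Dictionary(name=n, entries=list(es)) for n, es in _DEFAULT_TERMS.items()]


_FILLER = "the study reported that supplementation was associated with outcomes"


def generate_corpus(
    planted: Mapping[frozenset, int] | Mapping[tuple, int] | None = None,
    n_filter_victims_per_rule: int = 1,
    dictionaries: list[Dictionary] | None = None,
    base_year: int = 2005,
    rng_seed: int = 0,
) -> tuple[list[DocumentRecord], list[Dictionary], dict]:
    """Corpus with planted dictionary co-mentions and filter victims.

    ``planted`` maps a dictionary-name combination to the number of clean
    sentences containing a term from exactly those dictionaries (default: a
    small grid over all pairs and triples).  For every filter rule,
    ``n_filter_victims_per_rule`` additional microbe+immune sentences are
    planted that violate exactly that rule.  The manifest counts, by direct
    enumeration over the planted structures, pre/post-filter sentences and
    documents for every query combination plus per-rule removals and species
    frequencies.
    """
    dictionaries = dictionaries or default_dictionaries()
    by_name = {d.name: d for d in dictionaries}
    rng = stream_rng(rng_seed, "corpus")

    if planted is None:
        planted = {}
        for r in (2, 3):
            for combo in combinations(CONCEPT_DICTIONARIES, r):
                planted[frozenset(combo)] = 2
    planted = {frozenset(c): int(v) for c, v in planted.items()}

    def clean_term(dname):
        if dname == "gut-microbes":
            species = [e for e in by_name[dname].entries
                       if e.taxonomic_level == "species" and not e.pathogen]
            return species[int(rng.integers(0, len(species)))]
        entries = by_name[dname].entries
        return entries[int(rng.integers(0, len(entries)))]

    # each planted sentence: (dict-set, text, year, section, species concepts,
    # survives_filters, violated_rule)
    sentences = []
    for combo in sorted(planted, key=sorted):
        for _ in range(planted[combo]):
            terms = [(d, clean_term(d)) for d in sorted(combo)]
            text = f"In infants {' and '.join(e.term for _, e in terms)} {_FILLER}."
            species = {e.concept for d, e in terms
                       if d == "gut-microbes" and e.taxonomic_level == "species"}
            sentences.append({"dicts": frozenset(combo), "text": text,
                              "year": base_year, "section": "abstract",
                              "species": species, "rule": None})

    microbe = [e for e in by_name["gut-microbes"].entries
               if e.taxonomic_level == "species" and not e.pathogen][0]
    immune = by_name["immune-related"].entries[0]
    victim_combo = frozenset({"gut-microbes", "immune-related"})

    def victim(text, year, section, species, rule, dicts=victim_combo):
        sentences.append({"dicts": dicts, "text": text, "year": year,
                          "section": section, "species": species, "rule": rule})

    for _ in range(n_filter_victims_per_rule):
        victim(f"{microbe.term} and the {immune.term} {_FILLER}.",
               1999, "abstract", {microbe.concept}, "year")
        victim(f"{microbe.term} and the {immune.term} {_FILLER}.",
               base_year, "title", {microbe.concept}, "title_section")
        victim(f"In zebrafish {microbe.term} altered the {immune.term} {_FILLER}.",
               base_year, "abstract", {microbe.concept}, "excluded_animal")
        victim(f"Lactobacillus modulated the {immune.term} {_FILLER}.",
               base_year, "abstract", set(), "species_level")
        victim(f"Clostridium difficile impaired the {immune.term} {_FILLER}.",
               base_year, "abstract", set(), "species_level")

    # distribute sentences over documents: victims of the year rule need
    # their own pre-2000 documents; others are grouped a few per document
    docs: list[DocumentRecord] = []
    doc_of_sentence = []
    counter = 0
    for s in sentences:
        if s["rule"] == "year" or s["section"] == "title" or rng.random() < 0.5:
            doc_id = f"PM{counter:06d}"
            counter += 1
            docs.append(DocumentRecord(
                doc_id=doc_id, year=s["year"],
                sections=[("title", [s["text"]] if s["section"] == "title" else []),
                          ("abstract", [s["text"]] if s["section"] == "abstract" else [])],
            ))
            doc_of_sentence.append(doc_id)
        else:
            # append to the last same-year non-title document, if any
            target = None
            for d in reversed(docs):
                if d.year == s["year"] and d.sections[0][1] == []:
                    target = d
                    break
            if target is None:
                doc_id = f"PM{counter:06d}"
                counter += 1
                target = DocumentRecord(doc_id=doc_id, year=s["year"],
                                        sections=[("title", []), ("abstract", [])])
                docs.append(target)
            target.sections[1][1].append(s["text"])
            doc_of_sentence.append(target.doc_id)

    # --- manifest by direct enumeration -----------------------------------
    query_combos = [frozenset(c) for r in (2, 3, 4)
                    for c in combinations(CONCEPT_DICTIONARIES, r)]
    per_combo = {}
    for combo in query_combos:
        pre = [i for i, s in enumerate(sentences) if combo <= s["dicts"]]
        post = [i for i in pre if sentences[i]["rule"] is None]
        freq: dict[str, int] = {}
        for i in post:
            for sp in sentences[i]["species"]:
                freq[sp] = freq.get(sp, 0) + 1
        per_combo["|".join(sorted(combo))] = {
            "sentences_prefilter": len(pre),
            "documents_prefilter": len({doc_of_sentence[i] for i in pre}),
            "sentences_postfilter": len(post),
            "documents_postfilter": len({doc_of_sentence[i] for i in post}),
            "species_frequency": freq,
        }
    removed_per_rule: dict[str, int] = {}
    for s in sentences:
        if s["rule"] is not None:
            removed_per_rule[s["rule"]] = removed_per_rule.get(s["rule"], 0) + 1

    manifest = {
        "rng_seed": rng_seed,
        "n_documents": len(docs),
        "n_sentences": len(sentences),
        "per_combo": per_combo,
        "removed_per_rule_in_victim_combo": removed_per_rule,
    }
    return docs, dictionaries, manifest
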