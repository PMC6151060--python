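"""Self-contained synthetic fixture bundle for end-to-end runs.

``write_fixture_bundle`` materializes, under one directory, every input the
pipeline consumes — edge-list models for a five-organism community with
programmed pairwise overlaps, a host model, a 50-food composition table with
planted cascade violations, per-organism pathway annotations with a planted
enriched pathway, a co-mention corpus with planted dictionary placements —
plus a ``config.yaml`` wired to them and a ``manifest.json`` holding every
planted truth.  Regeneration with the same seed is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

from .network_io import write_edge_list
from .synthetic_data import (generate_annotation, generate_community,
                             generate_corpus, generate_food_table)

__all__ = ["write_fixture_bundle", "BUNDLE_DESIGN"]

# the community design: 5 organisms, 10 singleton-confidence seeds each,
# pair-exclusive sharing so every pairwise index is an exact fraction
BUNDLE_DESIGN = {
    "k": 5,
    "seeds_per_organism": 10,
    "overlap": [
        [1.0, 0.4, 0.2, 0.0, 0.0],
        [0.4, 1.0, 0.2, 0.0, 0.0],
        [0.2, 0.2, 1.0, 0.1, 0.0],
        [0.0, 0.0, 0.1, 1.0, 0.3],
        [0.0, 0.0, 0.0, 0.3, 1.0],
    ],
    "complementarity": [
        [0.0, 0.0, 0.0, 0.2, 0.0],
        [0.0, 0.0, 0.0, 0.0, 0.0],
        [0.0, 0.0, 0.0, 0.0, 0.1],
        [0.0, 0.0, 0.0, 0.0, 0.0],
        [0.0, 0.3, 0.0, 0.0, 0.0],
    ],
    "host_support": [0.3, 0.2, 0.4, 0.5, 0.6],
}


def _partition_truth(seed_ids: list[list[str]]) -> dict[str, int]:
    from collections import Counter

    k = len(seed_ids)
    counts = Counter(c for ids in seed_ids for c in set(ids))
    return {
        "universe": len(counts),
        "core": sum(1 for n in counts.values() if n == k),
        "unique": sum(1 for n in counts.values() if n == 1),
        "shared": sum(1 for n in counts.values() if 2 <= n < k),
    }


def write_fixture_bundle(path, rng_seed: int = 0) -> dict:
    """Write the full synthetic input bundle; returns the manifest."""
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)

    def write(name: str, text: str) -> None:
        (out / name).write_text(text, encoding="utf-8", newline="\n")

    design = generate_community(
        k=BUNDLE_DESIGN["k"],
        seeds_per_organism=BUNDLE_DESIGN["seeds_per_organism"],
        overlap_matrix=BUNDLE_DESIGN["overlap"],
        complementarity_matrix=BUNDLE_DESIGN["complementarity"],
        host_support=BUNDLE_DESIGN["host_support"],
        rng_seed=rng_seed,
    )
    models = out / "models"
    models.mkdir(exist_ok=True)
    for seeds, net in design.organisms:
        (models / f"network_{net.organism_id}.tsv").write_text(
            write_edge_list(net), encoding="utf-8", newline="\n")
    write("host.tsv", write_edge_list(design.host))

    # global compound -> KEGG id map over the community seed universe
    universe = sorted({c for ids in design.manifest["seed_ids"] for c in ids})
    kegg_map = {cid: f"C{i + 1:05d}" for i, cid in enumerate(universe)}
    write("kegg_map.tsv", "compound_id\tkegg_id\n" + "".join(
        f"{c}\t{k}\n" for c, k in kegg_map.items()))

    annotation_rows = ["organism\tpathway_id\tpathway_name\tcompound_id\n"]
    annotation_manifest = {}
    for seeds, net in design.organisms:
        ann, seed_list, manifest = generate_annotation(
            n_pathways=12, universe_size=200,
            planted_pathway_size=8, planted_overlap=6,
            organism_id=net.organism_id,
            seed_compounds=[kegg_map[c] for c in sorted(seeds.members())],
            rng_seed=rng_seed,
        )
        for pid in sorted(ann.pathways):
            name, comps = ann.pathways[pid]
            for cid in sorted(comps):
                annotation_rows.append(
                    f"{net.organism_id}\t{pid}\t{name}\t{cid}\n")
        # the TSV carries pathway memberships only, so its consumers see the
        # union-of-pathways universe; restate N and n against that union
        union = frozenset().union(*(c for _, c in ann.pathways.values()))
        mapped = {kegg_map[c] for c in seeds.members()}
        annotation_manifest[net.organism_id] = {
            pid: {"N": len(union), "K": counts["K"],
                  "n": len(mapped & union), "k": counts["k"]}
            for pid, counts in manifest["per_pathway"].items()
        }
    write("annotation.tsv", "".join(annotation_rows))

    table, category_map, food_seed_names, food_manifest = generate_food_table(
        n_foods=50, rng_seed=rng_seed)
    write("food_table.tsv",
          table.to_csv(sep="\t", index=False, lineterminator="\n"))
    write("category_map.tsv", "compound_name\tcategory\n" + "".join(
        f"{n}\t{c}\n" for n, c in sorted(category_map.items())))

    # seed id -> metabolite name: the food generator's names cover part of
    # the universe; the remainder stays unsourced (nomenclature gap)
    names = sorted(food_seed_names)
    name_map = {}
    for i, cid in enumerate(universe):
        name_map[cid] = (names[i] if i < len(names)
                         else f"unsourced metabolite {i:02d}")
    write("seed_name_map.tsv", "compound_id\tname\n" + "".join(
        f"{c}\t{n}\n" for c, n in name_map.items()))

    docs, dictionaries, corpus_manifest = generate_corpus(rng_seed=rng_seed)
    write("corpus.jsonl", "".join(
        json.dumps({
            "doc_id": d.doc_id, "year": d.year,
            "sections": [{"label": lab, "sentences": sents}
                         for lab, sents in d.sections],
        }, sort_keys=True) + "\n" for d in docs))
    dict_entries = {}
    for d in dictionaries:
        lines = ["term\tconcept\tlevel\tpathogen\texcluded_animal\n"]
        for e in d.entries:
            lines.append(
                f"{e.term}\t{e.concept}\t{e.taxonomic_level or ''}\t"
                f"{'true' if e.pathogen else 'false'}\t"
                f"{'true' if e.excluded_animal else 'false'}\n")
        write(f"dict_{d.name}.tsv", "".join(lines))
        dict_entries[d.name] = f"dict_{d.name}.tsv"

    config_lines = [
        "models_dir: models",
        "host_model: host.tsv",
        "food_table: food_table.tsv",
        "category_map: category_map.tsv",
        "annotation: annotation.tsv",
        "kegg_map: kegg_map.tsv",
        "seed_name_map: seed_name_map.tsv",
        "corpus: corpus.jsonl",
        "dictionaries:",
    ] + [f"  {name}: {fname}" for name, fname in sorted(dict_entries.items())]
    write("config.yaml", "\n".join(config_lines) + "\n")

    manifest = {
        "rng_seed": rng_seed,
        "community": design.manifest,
        "partition": _partition_truth(design.manifest["seed_ids"]),
        "annotation": annotation_manifest,
        "food": {
            "cascade": food_manifest["cascade"],
            "survivors": food_manifest["survivors"],
            "ranking": food_manifest["ranking"],
            "matched_count": food_manifest["matched_count"],
        },
        "corpus": corpus_manifest,
    }
    write("manifest.json", json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
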