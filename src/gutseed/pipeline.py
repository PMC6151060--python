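"""End-to-end pipeline orchestration.

Runs the stages in order — optional literature mining, model parsing, seed
detection, community partition, interaction matrices, pathway enrichment,
food sourcing — skipping stages whose inputs are absent, and emits fixed-name
TSV outputs plus a machine-readable ``summary.json``.  The analysis itself is
fully deterministic: identical inputs and configuration yield byte-identical
outputs (no timestamps are written into output files).
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import pandas as pd
import yaml

from . import comention_mining as cm
from . import community_analysis, enrichment, food_sourcing, reverse_ecology
from .network_io import (MetabolicNetwork, ParseOptions, parse_sbml_file,
                         read_edge_list)
from .seed_detection import community_seed_matrix, detect_seeds, seed_report

__all__ = ["RunConfig", "RunSummary", "StageError", "run", "load_config"]

logger = logging.getLogger("gutseed")

_KNOWN_KEYS = {
    "models_dir", "host_model", "food_table", "category_map", "annotation",
    "kegg_map", "seed_name_map", "corpus", "dictionaries", "weights",
    "weighted", "min_confidence", "coverage_threshold", "grouping",
}
_PATH_KEYS = ("models_dir", "host_model", "food_table", "category_map",
              "annotation", "kegg_map", "seed_name_map", "corpus")


class StageError(RuntimeError):
    """A pipeline stage failed; message names the stage and offending file."""


@dataclass
class RunConfig:
    models_dir: str
    host_model: str | None = None
    food_table: str | None = None
    category_map: str | None = None
    annotation: str | None = None
    kegg_map: str | None = None
    seed_name_map: str | None = None
    corpus: str | None = None
    dictionaries: dict[str, str] = field(default_factory=dict)
    weights: dict[str, float] = field(default_factory=dict)
    weighted: bool = True
    min_confidence: float = 0.0
    coverage_threshold: float = 0.7
    grouping: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        for key in _PATH_KEYS:
            val = getattr(self, key)
            if val is not None and not Path(val).exists():
                raise FileNotFoundError(f"config path {key} does not exist: {val}")
        for name, path in self.dictionaries.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"dictionary {name!r} path missing: {path}")

    def semantic_dict(self) -> dict:
        return {
            "models_dir": self.models_dir, "host_model": self.host_model,
            "food_table": self.food_table, "category_map": self.category_map,
            "annotation": self.annotation, "kegg_map": self.kegg_map,
            "seed_name_map": self.seed_name_map, "corpus": self.corpus,
            "dictionaries": dict(sorted(self.dictionaries.items())),
            "weights": dict(sorted(self.weights.items())),
            "weighted": self.weighted, "min_confidence": self.min_confidence,
            "coverage_threshold": self.coverage_threshold,
            "grouping": dict(sorted(self.grouping.items())),
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.semantic_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "models_dir" not in raw:
        raise ValueError("config requires models_dir")
    base = Path(path).parent

    def resolve(v):
        return str((base / v)) if v is not None and not os.path.isabs(v) else v

    for key in _PATH_KEYS:
        if raw.get(key) is not None:
            raw[key] = resolve(raw[key])
    if raw.get("dictionaries"):
        raw["dictionaries"] = {k: resolve(v) for k, v in raw["dictionaries"].items()}
    return RunConfig(**raw)


@dataclass
class RunSummary:
    config_hash: str
    version: str
    stages: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"config_hash": self.config_hash, "version": self.version,
                "stages": self.stages}


def _write_text(path: Path, text: str, written: list[Path]) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text, encoding="utf-8", newline="\n")
    os.replace(tmp, path)
    written.append(path)


def _write_df(path: Path, df: pd.DataFrame, written: list[Path]) -> None:
    _write_text(path, df.to_csv(sep="\t", index=False, lineterminator="\n"),
                written)


def _load_two_column_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def _stage_mining(config, out, written, summary):
    corpus = cm.read_corpus_jsonl(config.corpus)
    dictionaries = [cm.read_dictionary_tsv(p, name)
                    for name, p in sorted(config.dictionaries.items())]
    hits = cm.annotate(corpus, dictionaries)
    concept_names = sorted(d.name for d in dictionaries
                           if not all(e.excluded_animal for e in d.entries))
    count_rows, freq_rows = [], []
    for r in range(2, len(concept_names) + 1):
        mode = "relationship" if r == 2 else "comention"
        for combo in combinations(concept_names, r):
            records = cm.extract_cooccurrences(hits, set(combo), mode=mode)
            pre = cm.combo_counts(records)
            kept, removed = cm.filter_chain(records)
            post = cm.combo_counts(kept)
            combo_key = "|".join(combo)
            count_rows.append({
                "combo": combo_key, "mode": mode,
                "sentences_prefilter": pre["sentences"],
                "documents_prefilter": pre["documents"],
                "sentences": post["sentences"],
                "documents": post["documents"],
                **{f"removed_{rule}": n for rule, n in removed.items()},
            })
            freq = cm.species_frequency(kept)
            freq.insert(0, "combo", combo_key)
            freq_rows.append(freq)
    counts = pd.DataFrame(count_rows)
    _write_df(out / "mining_counts.tsv", counts, written)
    _write_df(out / "species_frequency.tsv",
              pd.concat(freq_rows, ignore_index=True) if freq_rows
              else pd.DataFrame(columns=["combo", "species", "sentence_count",
                                         "total_sentences"]),
              written)
    summary.stages["mining"] = {
        "documents": len(corpus),
        "combos": len(count_rows),
        "per_combo": {
            row["combo"]: {"sentences": row["sentences"],
                           "documents": row["documents"],
                           "sentences_prefilter": row["sentences_prefilter"],
                           "documents_prefilter": row["documents_prefilter"]}
            for row in count_rows
        },
    }


def _stage_parse(config) -> list[MetabolicNetwork]:
    networks = []
    model_dir = Path(config.models_dir)
    for path in sorted(model_dir.iterdir()):
        if path.suffix in (".xml", ".sbml"):
            networks.append(parse_sbml_file(path, ParseOptions(),
                                            organism_id=path.stem))
        elif path.suffix == ".tsv" and path.stem.startswith("network_"):
            with open(path, "r", encoding="utf-8") as fh:
                networks.append(read_edge_list(
                    fh, organism_id=path.stem.removeprefix("network_")))
    if not networks:
        raise FileNotFoundError(
            f"no model files (*.xml, *.sbml, network_*.tsv) in {model_dir}")
    return networks


def run(config: RunConfig, out_dir) -> RunSummary:
    """Execute the pipeline; outputs under ``out_dir``, stage-atomic.

    Stages whose inputs are absent from the config are skipped with a log
    line.  On stage failure, files written by the failing run are removed
    and a :class:`StageError` naming the stage is raised.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from . import __version__
    summary = RunSummary(config_hash=config.config_hash(), version=__version__)
    written: list[Path] = []
    stage = "configure"
    try:
        if config.corpus and config.dictionaries:
            stage = "mining"
            _stage_mining(config, out, written, summary)
        else:
            logger.info("mining stage skipped (no corpus/dictionaries)")

        stage = "parse"
        networks = _stage_parse(config)
        catalogs = {net.organism_id: net.compounds for net in networks}

        stage = "seeds"
        seed_sets = [detect_seeds(net, config.min_confidence) for net in networks]
        for net, ss in zip(networks, seed_sets):
            _write_df(out / f"seeds_{net.organism_id}.tsv",
                      seed_report(ss, net.compounds), written)
        matrix = community_seed_matrix(seed_sets)
        _write_text(out / "seed_matrix.tsv",
                    matrix.to_csv(sep="\t", lineterminator="\n"), written)
        summary.stages["seeds"] = {
            "organisms": len(seed_sets),
            "seed_counts": {s.organism_id: len(s) for s in seed_sets},
        }

        stage = "partition"
        part = community_analysis.partition_seeds(seed_sets)
        _write_df(out / "partition_summary.tsv",
                  pd.DataFrame([part.sizes()]), written)
        summary.stages["partition"] = part.sizes()
        if config.grouping:
            groups = community_analysis.group_summary(seed_sets, config.grouping)
            rows = [{"group": label, **p.sizes()}
                    for label, p in groups.partitions.items()]
            _write_df(out / "group_summary.tsv", pd.DataFrame(rows), written)
            summary.stages["groups"] = {label: p.sizes()
                                        for label, p in groups.partitions.items()}

        if len(networks) >= 2:
            stage = "matrices"
            host = None
            if config.host_model:
                hp = Path(config.host_model)
                if hp.suffix in (".xml", ".sbml"):
                    host = parse_sbml_file(hp, ParseOptions(), organism_id=hp.stem)
                else:
                    with open(hp, "r", encoding="utf-8") as fh:
                        host = read_edge_list(fh, organism_id=hp.stem)
            community = list(zip(seed_sets, networks))
            matrices = reverse_ecology.pairwise_matrices(
                community, host=host, weighted=config.weighted)
            for kind, frame in matrices.items():
                path = out / f"matrix_{kind}.tsv"
                header = (f"# focal=row partner=column "
                          f"weighted={str(config.weighted).lower()}\n")
                _write_text(path, header + frame.to_csv(sep="\t",
                                                        lineterminator="\n"),
                            written)
            summary.stages["matrices"] = {
                "kinds": sorted(matrices), "organisms": len(networks)}
        else:
            logger.info("matrices stage skipped (fewer than 2 organisms)")

        if config.annotation:
            stage = "enrichment"
            annotations = enrichment.read_annotation_tsv(config.annotation)
            kegg_map = (_load_two_column_map(config.kegg_map)
                        if config.kegg_map else None)
            results_by_org, excl = {}, {}
            for ss in seed_sets:
                if ss.organism_id in annotations:
                    res, info = enrichment.enrich_seeds(
                        ss, annotations[ss.organism_id], kegg_map=kegg_map)
                    results_by_org[ss.organism_id] = res
                    excl[ss.organism_id] = info
            if results_by_org:
                summary_df, long = enrichment.community_enrichment_summary(
                    results_by_org)
                _write_df(out / "enrichment.tsv", long, written)
                _write_df(out / "enrichment_summary.tsv", summary_df, written)
                summary.stages["enrichment"] = {
                    "organisms": len(results_by_org),
                    "pathways": int(long["pathway_id"].nunique()),
                    "significant_headline": int(summary_df["headline"].sum()),
                    "exclusions": excl,
                }
        else:
            logger.info("enrichment stage skipped (no annotation)")

        if config.food_table and config.category_map:
            stage = "food_sourcing"
            table = food_sourcing.read_food_table(config.food_table)
            category_map = food_sourcing.read_category_map(config.category_map)
            name_map = (_load_two_column_map(config.seed_name_map)
                        if config.seed_name_map else {})
            universe = sorted(set().union(*(s.members() for s in seed_sets)))
            seed_names = set()
            for cid in universe:
                if cid in name_map:
                    seed_names.add(name_map[cid])
                else:
                    comp = next((catalogs[o].get(cid) for o in catalogs
                                 if cid in catalogs[o]), None)
                    seed_names.add(comp.name if comp is not None and comp.name
                                   else cid)
            matched, unmatched = food_sourcing.match_compounds(seed_names, table)
            survivors, cascade = food_sourcing.filter_foods(
                table, matched, category_map)
            summary.stages["food_sourcing"] = {
                "seed_names": len(seed_names),
                "matched": len(matched),
                "unmatched": len(unmatched),
                "cascade": cascade.as_dict(),
            }
            _write_df(out / "food_cascade.tsv",
                      pd.DataFrame([cascade.as_dict()]), written)
            _write_df(out / "unmatched_compounds.tsv",
                      pd.DataFrame({"seed_name": unmatched}), written)
            if survivors:
                profiles = food_sourcing.category_profiles(
                    table, survivors, matched, category_map)
                names = dict(zip(table["food_id"], table["food_name"]))
                ranking = food_sourcing.normalize_and_score(
                    profiles, weights=config.weights or None, food_names=names)
                _write_df(out / "food_ranking.tsv", ranking, written)
                summary.stages["food_sourcing"]["top_food"] = (
                    ranking.iloc[0]["food_name"])
        else:
            logger.info("food stage skipped (no food table / category map)")

        stage = "summary"
        _write_text(out / "summary.json",
                    json.dumps(summary.as_dict(), indent=2, sort_keys=True) + "\n",
                    written)
    except Exception as exc:
        for path in written:
            try:
                path.unlink()
            except OSError:
                pass
        raise StageError(f"stage {stage!r} failed: {exc}") from exc
    return summary
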