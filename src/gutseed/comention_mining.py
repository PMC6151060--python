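"""Dictionary-driven sentence co-mention mining.

A lightweight literature-mining stage: term dictionaries (gut microbes,
immune-related, infection/disease, chemical-related, plus filter terms) are
matched into a sentence-segmented corpus; sentences containing terms from a
combination of dictionaries are extracted as *relationships* (exactly two
dictionaries) or *co-mentions* (three or more); a fixed filter chain removes
old articles, title sentences, off-topic animal studies and sentences whose
only microbial evidence is a pathogen or a bare genus name; and per-species
sentence frequencies are tabulated.

The relation test between two terms is a pluggable predicate; the default is
same-sentence co-occurrence.  Dependency-parse relation classification is a
deliberate non-goal.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

import pandas as pd

__all__ = [
    "DictEntry",
    "Dictionary",
    "DocumentRecord",
    "Match",
    "SentenceHit",
    "annotate",
    "extract_cooccurrences",
    "filter_chain",
    "species_frequency",
    "read_corpus_jsonl",
    "read_dictionary_tsv",
]

MICROBE_DICTIONARY = "gut-microbes"


@dataclass(frozen=True)
class DictEntry:
    term: str
    concept: str
    taxonomic_level: Optional[str] = None  # genus | species | strain (microbes)
    pathogen: bool = False
    excluded_animal: bool = False


@dataclass
class Dictionary:
    name: str
    entries: list[DictEntry]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError(f"dictionary {self.name!r} has no entries")
        for e in self.entries:
            if not e.term or not e.concept:
                raise ValueError(f"dictionary {self.name!r} has an empty term/concept")


@dataclass
class DocumentRecord:
    doc_id: str
    year: int
    sections: list[tuple[str, list[str]]]  # (section_label, sentences)

    def __post_init__(self) -> None:
        if self.year <= 0:
            raise ValueError(f"document {self.doc_id}: year must be positive")


@dataclass(frozen=True)
class Match:
    dictionary: str
    term: str
    concept: str
    start: int
    end: int
    taxonomic_level: Optional[str] = None
    pathogen: bool = False
    excluded_animal: bool = False


@dataclass
class SentenceHit:
    doc_id: str
    year: int
    section_label: str
    sentence: str
    matches: list[Match] = field(default_factory=list)

    def dictionaries(self) -> set[str]:
        return {m.dictionary for m in self.matches}


def _compile(dictionaries: list[Dictionary]):
    """Longest-first candidate list: (regex, dictionary, entry)."""
    cands = []
    for d in dictionaries:
        for e in d.entries:
            pat = re.compile(r"(?<!\w)" + re.escape(e.term) + r"(?!\w)",
                             re.IGNORECASE)
            cands.append((pat, d.name, e))
    # longer terms first so "Lactobacillus rhamnosus" beats "Lactobacillus";
    # term text then dictionary name for a deterministic total order
    cands.sort(key=lambda c: (-len(c[2].term), c[2].term.casefold(), c[1]))
    return cands


def annotate(corpus: Iterable[DocumentRecord],
             dictionaries: list[Dictionary]) -> list[SentenceHit]:
    """Match dictionary terms into every sentence of the corpus.

    Case-insensitive, word-boundary matching; overlapping candidates are
    resolved longest-match-first, so a species term shadows its genus prefix.
    Sentences with no matches produce no hit.
    """
    if not dictionaries:
        raise ValueError("no dictionaries supplied")
    cands = _compile(dictionaries)
    hits = []
    for doc in corpus:
        for label, sentences in doc.sections:
            for sent in sentences:
                taken: list[tuple[int, int]] = []
                matches: list[Match] = []
                for pat, dname, entry in cands:
                    for m in pat.finditer(sent):
                        span = (m.start(), m.end())
                        if any(span[0] < e and s < span[1] for s, e in taken):
                            continue
                        taken.append(span)
                        matches.append(Match(
                            dictionary=dname, term=entry.term,
                            concept=entry.concept,
                            start=span[0], end=span[1],
                            taxonomic_level=entry.taxonomic_level,
                            pathogen=entry.pathogen,
                            excluded_animal=entry.excluded_animal,
                        ))
                if matches:
                    matches.sort(key=lambda m: m.start)
                    hits.append(SentenceHit(
                        doc_id=doc.doc_id, year=doc.year,
                        section_label=label, sentence=sent, matches=matches,
                    ))
    return hits


RelationPredicate = Callable[[SentenceHit, Match, Match], bool]


def _cooccurrence_predicate(hit: SentenceHit, a: Match, b: Match) -> bool:
    return True


def extract_cooccurrences(
    hits: Iterable[SentenceHit],
    combo: set[str] | frozenset[str],
    mode: str = "relationship",
    predicate: RelationPredicate | None = None,
) -> list[SentenceHit]:
    """Sentences containing at least one match from every dictionary in combo.

    ``mode='relationship'`` requires exactly two dictionaries and applies the
    relation ``predicate`` (default: same-sentence co-occurrence) to at least
    one cross-dictionary term pair; ``mode='comention'`` requires three or
    more dictionaries.
    """
    combo = frozenset(combo)
    if mode == "relationship":
        if len(combo) != 2:
            raise ValueError("relationship mode requires a combo of exactly 2 dictionaries")
    elif mode == "comention":
        if len(combo) < 3:
            raise ValueError("comention mode requires a combo of >= 3 dictionaries")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    predicate = predicate or _cooccurrence_predicate
    records = []
    for hit in hits:
        if not combo <= hit.dictionaries():
            continue
        if mode == "relationship":
            d1, d2 = sorted(combo)
            related = any(
                predicate(hit, a, b)
                for a in hit.matches if a.dictionary == d1
                for b in hit.matches if b.dictionary == d2
            )
            if not related:
                continue
        records.append(hit)
    return records


def combo_counts(records: list[SentenceHit]) -> dict[str, int]:
    """Sentence and distinct-document counts for one combo's records."""
    return {"sentences": len(records),
            "documents": len({r.doc_id for r in records})}


FILTER_RULES = ("year", "title_section", "excluded_animal", "species_level")


def filter_chain(records: list[SentenceHit]) -> tuple[list[SentenceHit], dict[str, int]]:
    """Fixed-order sentence filters with first-matching-rule attribution.

    In order: (1) drop documents published before 2000; (2) drop title
    sentences; (3) drop sentences containing an excluded animal term;
    (4) drop sentences whose microbial matches are all pathogen-tagged or
    genus-level.  Returns the survivors and per-rule removal counts.
    """
    removed = {rule: 0 for rule in FILTER_RULES}
    kept = []
    for rec in records:
        if rec.year <= 1999:
            removed["year"] += 1
            continue
        if rec.section_label == "title":
            removed["title_section"] += 1
            continue
        if any(m.excluded_animal for m in rec.matches):
            removed["excluded_animal"] += 1
            continue
        microbes = [m for m in rec.matches if m.dictionary == MICROBE_DICTIONARY]
        if microbes and all(
            m.pathogen or m.taxonomic_level == "genus" for m in microbes
        ):
            removed["species_level"] += 1
            continue
        kept.append(rec)
    return kept, removed


def species_frequency(records: list[SentenceHit]) -> pd.DataFrame:
    """Per-species sentence counts for a filtered combo.

    A sentence mentioning a species several times counts once.  Columns:
    species (canonical concept), sentence_count, total_sentences; sorted by
    descending count, ties lexicographic.
    """
    total = len(records)
    counts: dict[str, int] = {}
    for rec in records:
        species = {
            m.concept for m in rec.matches
            if m.dictionary == MICROBE_DICTIONARY
            and m.taxonomic_level in ("species", "strain")
        }
        for sp in species:
            counts[sp] = counts.get(sp, 0) + 1
    rows = [{"species": sp, "sentence_count": n, "total_sentences": total}
            for sp, n in counts.items()]
    df = pd.DataFrame(rows, columns=["species", "sentence_count", "total_sentences"])
    if len(df):
        df = df.sort_values(["sentence_count", "species"],
                            ascending=[False, True]).reset_index(drop=True)
    return df


def read_corpus_jsonl(path) -> list[DocumentRecord]:
    """One document per line: `{"doc_id", "year", "sections": [{"label", "sentences"}]}`."""
    docs = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            docs.append(DocumentRecord(
                doc_id=str(obj["doc_id"]), year=int(obj["year"]),
                sections=[(s["label"], list(s["sentences"]))
                          for s in obj["sections"]],
            ))
    return docs


def read_dictionary_tsv(path, name: str) -> Dictionary:
    """Load `term	concept	level	pathogen	excluded_animal` TSV."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    required = ["term", "concept", "level", "pathogen", "excluded_animal"]
    if list(df.columns) != required:
        raise ValueError(f"dictionary TSV must have columns {required}")
    entries = [
        DictEntry(
            term=r.term, concept=r.concept,
            taxonomic_level=r.level or None,
            pathogen=r.pathogen.lower() in ("1", "true", "yes"),
            excluded_animal=r.excluded_animal.lower() in ("1", "true", "yes"),
        )
        for r in df.itertuples()
    ]
    return Dictionary(name=name, entries=entries)
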