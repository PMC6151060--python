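"""Metabolic model input/output.

Genome-scale metabolic models (SBML) are converted into directed *compound
graphs*: nodes are compounds, and every reaction contributes an edge from each
of its substrates to each of its products (both directions for reversible
reactions).  Stoichiometry is deliberately ignored — downstream seed-set
detection is a purely topological method.

A plain-text two-column TSV edge-list dialect is provided so networks can be
stored, diffed and regenerated without an SBML toolchain, together with a
harmonized per-reaction table.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import libsbml
import pandas as pd

__all__ = [
    "Compound",
    "Reaction",
    "MetabolicNetwork",
    "ParseOptions",
    "ParseError",
    "ValidationError",
    "EdgeListFormatError",
    "parse_sbml",
    "parse_sbml_file",
    "read_edge_list",
    "write_edge_list",
    "reaction_table",
    "strip_compartment",
]

# Trailing compartment tags: "glc_D[c]", "glc_D__91__c__93__" (SBML-escaped
# brackets) or "glc_D_c" with a single-letter compartment suffix.
_BRACKET_TAG = re.compile(r"\[[A-Za-z0-9]{1,2}\]$")
_ESCAPED_BRACKET_TAG = re.compile(r"__91__[A-Za-z0-9]{1,2}__93__$")
_UNDERSCORE_TAG = re.compile(r"_[a-z]$")

_KEGG_RE = re.compile(r"C\d{5}")
_CHEBI_RE = re.compile(r"CHEBI:\d+")


class ParseError(ValueError):
    """Raised when an SBML document cannot be parsed."""


class ValidationError(ValueError):
    """Raised when a structurally valid document violates model constraints."""


class EdgeListFormatError(ValueError):
    """Raised for malformed edge-list text."""


def strip_compartment(raw_id: str) -> str:
    """Return the compartment-stripped canonical id of a species id.

    Handles the tag styles seen in genome-scale reconstructions:
    ``glc_D[c]``, ``glc_D__91__c__93__`` and ``glc_D_c``.  Applied once;
    idempotent for single-compartment ids.
    """
    for pat in (_BRACKET_TAG, _ESCAPED_BRACKET_TAG, _UNDERSCORE_TAG):
        stripped = pat.sub("", raw_id)
        if stripped and stripped != raw_id:
            return stripped
    return raw_id


@dataclass(frozen=True)
class Compound:
    raw_id: str
    base_id: str
    name: str = ""
    kegg_id: Optional[str] = None
    chebi_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.base_id:
            raise ValueError(f"empty base_id for raw id {self.raw_id!r}")
        if self.kegg_id is not None and not _KEGG_RE.fullmatch(self.kegg_id):
            raise ValueError(f"malformed KEGG id {self.kegg_id!r}")


@dataclass(frozen=True)
class Reaction:
    id: str
    substrates: frozenset[str]
    products: frozenset[str]
    reversible: bool = False
    enzymes: tuple[str, ...] = ()
    is_exchange: bool = False

    def __post_init__(self) -> None:
        if not self.is_exchange and (not self.substrates or not self.products):
            raise ValueError(
                f"reaction {self.id!r} lacks substrates or products and is "
                "not flagged as exchange"
            )


@dataclass
class ParseOptions:
    """Knobs controlling SBML → compound-graph conversion.

    strip_compartments
        Merge compartment-duplicated species onto a shared base id.  Required
        for cross-organism compound matching; off only for per-compartment
        bookkeeping.
    exclude_reactions
        Case-insensitive regex on reaction ids; matching reactions (exchange
        and biomass pseudo-reactions by default) contribute no edges.  Set to
        ``None`` to retain everything.
    currency_exclude
        Base ids to drop from the graph (e.g. ATP, H2O).  Empty by default:
        small cofactors are genuine exogenous requirements in this analysis.
    """

    strip_compartments: bool = True
    exclude_reactions: Optional[str] = r"^(EX_|R_EX_|biomass|R_biomass)"
    currency_exclude: frozenset[str] = frozenset()


@dataclass
class MetabolicNetwork:
    """Directed compound graph for one organism."""

    organism_id: str
    compounds: dict[str, Compound] = field(default_factory=dict)
    edges: set[tuple[str, str]] = field(default_factory=set)
    provenance: dict = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        return set(self.compounds)

    def add_compound(self, compound: Compound) -> None:
        self.compounds.setdefault(compound.base_id, compound)

    def add_edge(self, u: str, v: str) -> bool:
        """Add edge u→v; self-loops are dropped (returns False)."""
        if u == v:
            return False
        for end in (u, v):
            if end not in self.compounds:
                self.add_compound(Compound(raw_id=end, base_id=end))
        self.edges.add((u, v))
        return True

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.compounds))
        g.add_edges_from(sorted(self.edges))
        return g


def _species_annotations(species) -> tuple[Optional[str], Optional[str]]:
    """Extract KEGG / ChEBI ids from SBML annotation URIs, if any."""
    kegg = chebi = None
    node = species.getAnnotation()
    if node is not None:
        text = node.toXMLString()
        m = _KEGG_RE.search(text)
        if m:
            kegg = m.group(0)
        m = _CHEBI_RE.search(text)
        if m:
            chebi = m.group(0)
    return kegg, chebi


def _reaction_enzymes(reaction) -> tuple[str, ...]:
    """Enzyme/gene labels from notes or fbc gene-product associations."""
    labels: list[str] = []
    fbc = reaction.getPlugin("fbc")
    if fbc is not None and fbc.isSetGeneProductAssociation():
        assoc = fbc.getGeneProductAssociation()
        labels.append(assoc.getAssociation().toInfix())
    notes = reaction.getNotesString() if reaction.isSetNotes() else ""
    for m in re.finditer(r"(?:GENE_ASSOCIATION|EC Number)\s*:\s*([^<\n]+)", notes):
        val = m.group(1).strip()
        if val:
            labels.append(val)
    return tuple(labels)


def parse_sbml(document: str, options: ParseOptions | None = None,
               organism_id: str = "") -> MetabolicNetwork:
    """Parse an SBML document (text) into a directed compound graph.

    One node per (compartment-stripped) species id; every non-excluded
    reaction adds substrate→product edges, and the reverse pairs when
    reversible.  Self-loop edges from reactions listing a compound on both
    sides are dropped and counted in ``provenance['self_loops_dropped']``.
    """
    options = options or ParseOptions()
    doc = libsbml.readSBMLFromString(document)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getError(0)
        raise ParseError(
            f"SBML parse error at line {err.getLine()}: {err.getMessage().strip()}"
        )
    model = doc.getModel()
    if model is None:
        raise ParseError("document contains no SBML model")
    if model.getNumSpecies() < 1 or model.getNumReactions() < 1:
        raise ValidationError("model must declare at least one species and one reaction")

    exclude = (re.compile(options.exclude_reactions, re.IGNORECASE)
               if options.exclude_reactions else None)

    net = MetabolicNetwork(organism_id=organism_id or model.getId() or "model")
    raw_to_base: dict[str, str] = {}
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        raw = sp.getId()
        base = strip_compartment(raw) if options.strip_compartments else raw
        if base in options.currency_exclude:
            raw_to_base[raw] = ""  # marker: excluded currency metabolite
            continue
        raw_to_base[raw] = base
        kegg, chebi = _species_annotations(sp)
        net.add_compound(Compound(raw_id=raw, base_id=base,
                                  name=sp.getName() or "",
                                  kegg_id=kegg, chebi_id=chebi))

    reactions: list[Reaction] = []
    self_loops = 0
    excluded_reactions = []
    for i in range(model.getNumReactions()):
        rxn = model.getReaction(i)
        rid = rxn.getId()
        subs, prods = [], []
        for refs, bucket in ((rxn.getListOfReactants(), subs),
                             (rxn.getListOfProducts(), prods)):
            for ref in refs:
                sid = ref.getSpecies()
                if sid not in raw_to_base:
                    raise ValidationError(
                        f"reaction {rid!r} references undeclared species {sid!r}"
                    )
                bucket.append(sid)
        is_exchange = not subs or not prods
        reactions.append(Reaction(
            id=rid,
            substrates=frozenset(subs),
            products=frozenset(prods),
            reversible=rxn.getReversible(),
            enzymes=_reaction_enzymes(rxn),
            is_exchange=is_exchange,
        ))
        if exclude is not None and exclude.search(rid):
            excluded_reactions.append(rid)
            continue
        sub_bases = sorted({raw_to_base[s] for s in subs} - {""})
        prod_bases = sorted({raw_to_base[p] for p in prods} - {""})
        for u in sub_bases:
            for v in prod_bases:
                if u == v:
                    self_loops += 1
                    continue
                net.add_edge(u, v)
                if rxn.getReversible():
                    net.add_edge(v, u)

    net.provenance = {
        "source": "sbml",
        "sbml_level": doc.getLevel(),
        "strip_compartments": options.strip_compartments,
        "exclude_reactions": options.exclude_reactions,
        "excluded_reaction_ids": sorted(excluded_reactions),
        "self_loops_dropped": self_loops,
        "n_species": model.getNumSpecies(),
        "n_reactions": model.getNumReactions(),
    }
    net.provenance["reactions"] = reactions
    return net


def parse_sbml_file(path, options: ParseOptions | None = None,
                    organism_id: str = "") -> MetabolicNetwork:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_sbml(fh.read(), options, organism_id=organism_id)


def read_edge_list(stream, organism_id: str = "") -> MetabolicNetwork:
    """Read the two-column TSV edge-list dialect.

    One ``source<TAB>target`` edge per line; ``#`` lines and blank lines are
    ignored.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    net = MetabolicNetwork(organism_id=organism_id,
                           provenance={"source": "edge_list"})
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise EdgeListFormatError(
                f"line {lineno}: expected 2 tab-separated columns, got {len(parts)}"
            )
        u, v = parts[0].strip(), parts[1].strip()
        if not u or not v:
            raise EdgeListFormatError(f"line {lineno}: empty node id")
        net.add_edge(u, v)
    return net


def write_edge_list(network: MetabolicNetwork, stream=None) -> str:
    """Write edges in lexicographic order for byte-stable output.

    Returns the text; additionally writes to ``stream`` when given.  Nodes
    without incident edges are not representable in this dialect.
    """
    lines = [f"{u}\t{v}" for u, v in sorted(network.edges)]
    text = "\n".join(lines) + ("\n" if lines else "")
    if stream is not None:
        stream.write(text)
    return text


REACTION_TABLE_COLUMNS = [
    "reaction_id", "substrates", "products", "reversible", "enzymes",
    "substrate_names", "product_names", "kegg_ids",
]


def reaction_table(network: MetabolicNetwork) -> pd.DataFrame:
    """Harmonized per-reaction table of a parsed model.

    One row per reaction of the source model (exchange reactions included),
    with compound names and external ids flattened into `;`-joined fields;
    missing annotations yield empty fields, never dropped rows.
    """
    reactions: Iterable[Reaction] = network.provenance.get("reactions", [])
    raw_lookup: Mapping[str, Compound] = {
        c.raw_id: c for c in network.compounds.values()
    }

    def _names(ids: frozenset[str]) -> str:
        return ";".join(
            raw_lookup[i].name if i in raw_lookup else ""
            for i in sorted(ids)
        )

    def _keggs(ids: frozenset[str]) -> str:
        vals = []
        for i in sorted(ids):
            c = raw_lookup.get(i)
            vals.append(c.kegg_id if c is not None and c.kegg_id else "")
        return ";".join(vals)

    rows = []
    for rxn in reactions:
        rows.append({
            "reaction_id": rxn.id,
            "substrates": ";".join(sorted(rxn.substrates)),
            "products": ";".join(sorted(rxn.products)),
            "reversible": rxn.reversible,
            "enzymes": ";".join(rxn.enzymes),
            "substrate_names": _names(rxn.substrates),
            "product_names": _names(rxn.products),
            "kegg_ids": _keggs(rxn.substrates | rxn.products),
        })
    return pd.DataFrame(rows, columns=REACTION_TABLE_COLUMNS)
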