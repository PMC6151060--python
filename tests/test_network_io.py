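import io

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutseed.network_io import (EdgeListFormatError, ParseError, ParseOptions,
                                ValidationError, parse_sbml, reaction_table,
                                read_edge_list, strip_compartment,
                                write_edge_list)
from gutseed.synthetic_data import generate_network

SBML_HEADER = (
    '<?xml version="1.0" encoding="UTF-8"?>\n'
    '<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" '
    'level="3" version="1">\n<model id="m">\n'
    '<listOfCompartments><compartment id="c" constant="true"/>'
    "</listOfCompartments>\n"
)


def make_sbml(species, reactions):
    """Minimal SBML L3 text: reactions = [(id, subs, prods, reversible)]."""
    parts = [SBML_HEADER, "<listOfSpecies>"]
    for s in species:
        parts.append(
            f'<species id="{s}" compartment="c" hasOnlySubstanceUnits="false"'
            ' boundaryCondition="false" constant="false"/>')
    parts.append("</listOfSpecies>\n<listOfReactions>")
    for rid, subs, prods, rev in reactions:
        parts.append(f'<reaction id="{rid}" reversible="{str(rev).lower()}" '
                     'fast="false">')
        if subs:
            parts.append("<listOfReactants>")
            parts.extend(f'<speciesReference species="{s}" stoichiometry="1" '
                         'constant="true"/>' for s in subs)
            parts.append("</listOfReactants>")
        if prods:
            parts.append("<listOfProducts>")
            parts.extend(f'<speciesReference species="{p}" stoichiometry="1" '
                         'constant="true"/>' for p in prods)
            parts.append("</listOfProducts>")
        parts.append("</reaction>")
    parts.append("</listOfReactions>\n</model>\n</sbml>\n")
    return "".join(parts)


class TestParseSbml:
    def test_irreversible_chain(self):
        doc = make_sbml("ABC", [("r1", "A", "B", False), ("r2", "B", "C", False)])
        net = parse_sbml(doc)
        assert net.edges == {("A", "B"), ("B", "C")}

    def test_reversible_reaction_contributes_both_directions(self):
        doc = make_sbml("ABC", [("r1", "AB", "C", True)])
        net = parse_sbml(doc)
        assert net.edges == {("A", "C"), ("B", "C"), ("C", "A"), ("C", "B")}

    def test_malformed_xml_names_line(self):
        with pytest.raises(ParseError, match=r"line \d+"):
            parse_sbml("<sbml><model></sbml>")

    def test_undeclared_species_names_reaction(self):
        doc = make_sbml("AB", [("rx", "A", "Z", False)])
        with pytest.raises(ValidationError, match="rx"):
            parse_sbml(doc)

    def test_self_loop_dropped_and_counted(self):
        doc = make_sbml("AB", [("r1", "A", "AB", False)])
        net = parse_sbml(doc)
        assert net.edges == {("A", "B")}
        assert net.provenance["self_loops_dropped"] == 1

    def test_exchange_reactions_excluded_by_default(self):
        doc = make_sbml("AB", [("EX_a", "A", "B", False), ("r1", "A", "B", False)])
        net = parse_sbml(doc)
        assert net.provenance["excluded_reaction_ids"] == ["EX_a"]
        assert net.edges == {("A", "B")}
        retained = parse_sbml(doc, ParseOptions(exclude_reactions=None))
        assert retained.provenance["excluded_reaction_ids"] == []

    def test_compartment_merging_cannot_add_nodes(self):
        doc = make_sbml(["glc_c", "glc_e", "pyr_c"],
                        [("r1", ["glc_c"], ["pyr_c"], False),
                         ("t1", ["glc_e"], ["glc_c"], False)])
        net = parse_sbml(doc)
        assert net.nodes == {"glc", "pyr"}
        assert len(net.nodes) <= 3
        # the transport reaction collapses onto a self-loop and is dropped
        assert net.edges == {("glc", "pyr")}

    def test_edge_set_invariant_under_reaction_permutation(self):
        rxns = [("r1", "A", "B", False), ("r2", "B", "C", True),
                ("r3", "AC", "D", False)]
        a = parse_sbml(make_sbml("ABCD", rxns))
        b = parse_sbml(make_sbml("ABCD", rxns[::-1]))
        assert a.edges == b.edges and a.nodes == b.nodes

    def test_synthetic_roundtrip_through_sbml(self):
        net, _, _ = generate_network(8, (1, 5), 3, rng_seed=11)
        rxns = [(f"r{i:03d}", [u], [v], False)
                for i, (u, v) in enumerate(sorted(net.edges))]
        doc = make_sbml(sorted(net.nodes), rxns)
        parsed = parse_sbml(doc, ParseOptions(strip_compartments=False))
        assert parsed.edges == net.edges


@pytest.mark.parametrize("raw,base", [
    ("glc_D[c]", "glc_D"),
    ("ala_L_c", "ala_L"),
    ("h2o__91__e__93__", "h2o"),
    ("nadph", "nadph"),
    ("o2", "o2"),
])
def test_strip_compartment(raw, base):
    assert strip_compartment(raw) == base


class TestEdgeList:
    def test_read_simple(self):
        net = read_edge_list("A\tB\nB\tC\n")
        assert net.edges == {("A", "B"), ("B", "C")}

    def test_empty_file(self):
        net = read_edge_list("")
        assert net.nodes == set() and net.edges == set()

    def test_comments_and_blanks_ignored(self):
        net = read_edge_list("# header\n\nA\tB\n")
        assert net.edges == {("A", "B")}

    def test_bad_column_count_names_line(self):
        with pytest.raises(EdgeListFormatError, match="line 2"):
            read_edge_list("A\tB\nA\tB\tC\n")

    def test_write_is_sorted_and_stable(self):
        net = read_edge_list("B\tC\nA\tB\n")
        assert write_edge_list(net) == "A\tB\nB\tC\n"
        assert write_edge_list(net) == write_edge_list(net)

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(st.sets(st.tuples(st.integers(0, 40), st.integers(0, 40))
                   .filter(lambda e: e[0] != e[1]), max_size=200))
    def test_roundtrip_identity_on_edge_set(self, int_edges):
        edges = {(f"n{u}", f"n{v}") for u, v in int_edges}
        net = read_edge_list("".join(f"{u}\t{v}\n" for u, v in edges))
        assert net.edges == edges
        again = read_edge_list(write_edge_list(net))
        assert again.edges == edges


class TestReactionTable:
    def test_row_per_reaction(self):
        doc = make_sbml("ABC", [("r1", "A", "B", False), ("r2", "B", "C", True),
                                ("EX_a", "A", "", False)])
        net = parse_sbml(doc)
        table = reaction_table(net)
        assert len(table) == 3  # exchange reactions are tabulated too
        assert list(table.columns[:5]) == [
            "reaction_id", "substrates", "products", "reversible", "enzymes"]

    def test_missing_enzyme_annotation_gives_empty_field(self):
        doc = make_sbml("AB", [("r1", "A", "B", False)])
        table = reaction_table(parse_sbml(doc))
        assert table.loc[0, "enzymes"] == ""

    def test_synthetic_manifest_rowcount(self):
        net, _, manifest = generate_network(6, (1, 4), 2, rng_seed=5)
        rxns = [(f"r{i:03d}", [u], [v], False)
                for i, (u, v) in enumerate(sorted(net.edges))]
        doc = make_sbml(sorted(net.nodes), rxns)
        table = reaction_table(parse_sbml(doc, ParseOptions(strip_compartments=False)))
        assert len(table) == len(net.edges)
        assert set(table["reaction_id"]) == {r[0] for r in rxns}
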