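import pytest

from gutseed.comention_mining import (DictEntry, Dictionary, DocumentRecord,
                                      annotate, combo_counts,
                                      extract_cooccurrences, filter_chain,
                                      species_frequency)
from gutseed.synthetic_data import (CONCEPT_DICTIONARIES, default_dictionaries,
                                    generate_corpus)


def doc(doc_id, year, sentences, section="abstract"):
    return DocumentRecord(doc_id=doc_id, year=year,
                          sections=[("title", []), (section, sentences)])


@pytest.fixture
def dicts():
    return default_dictionaries()


class TestAnnotate:
    def test_longest_match_wins_over_genus(self, dicts):
        hits = annotate([doc("d1", 2010,
                             ["Lactobacillus rhamnosus reduced diarrhea"])],
                        dicts)
        assert len(hits) == 1
        microbe = [m for m in hits[0].matches
                   if m.dictionary == "gut-microbes"]
        assert len(microbe) == 1
        assert microbe[0].term == "Lactobacillus rhamnosus"
        assert microbe[0].taxonomic_level == "species"

    def test_sentence_without_terms_produces_no_hit(self, dicts):
        assert annotate([doc("d1", 2010, ["nothing to see here"])], dicts) == []

    def test_case_insensitive_word_boundary(self, dicts):
        hits = annotate([doc("d1", 2010, ["CYTOKINE levels rose;"
                                          " pseudocytokine did not"])], dicts)
        assert len(hits[0].matches) == 1
        assert hits[0].matches[0].concept == "cytokine"

    def test_spans_are_nonoverlapping_and_in_bounds(self, dicts):
        sent = "Lactobacillus and Lactobacillus casei with butyrate"
        hits = annotate([doc("d1", 2010, [sent])], dicts)
        spans = sorted((m.start, m.end) for m in hits[0].matches)
        assert all(0 <= s < e <= len(sent) for s, e in spans)
        assert all(spans[i][1] <= spans[i + 1][0] for i in range(len(spans) - 1))

    def test_invariant_under_document_order(self, dicts):
        docs = [doc("d1", 2010, ["butyrate and cytokine"]),
                doc("d2", 2011, ["sepsis and acetate"])]
        a = annotate(docs, dicts)
        b = annotate(docs[::-1], dicts)
        key = lambda h: (h.doc_id, h.sentence)
        assert sorted((key(h) for h in a)) == sorted((key(h) for h in b))


class TestExtractCooccurrences:
    def test_two_dict_sentence_is_relationship(self, dicts):
        hits = annotate([doc("d1", 2010,
                             ["Lactobacillus rhamnosus raised cytokine levels"])],
                        dicts)
        recs = extract_cooccurrences(hits, {"gut-microbes", "immune-related"})
        assert combo_counts(recs) == {"sentences": 1, "documents": 1}

    def test_single_dict_sentence_excluded(self, dicts):
        hits = annotate([doc("d1", 2010, ["butyrate is produced"])], dicts)
        assert extract_cooccurrences(
            hits, {"gut-microbes", "chemical-related"}) == []

    def test_mode_size_contract(self, dicts):
        with pytest.raises(ValueError):
            extract_cooccurrences([], {"a", "b", "c"}, mode="relationship")
        with pytest.raises(ValueError):
            extract_cooccurrences([], {"a", "b"}, mode="comention")

    def test_four_dict_sentence_subsumes_all_combos(self, dicts):
        sent = ("Lactobacillus rhamnosus altered cytokine response to "
                "sepsis via butyrate")
        hits = annotate([doc("d1", 2010, [sent])], dicts)
        from itertools import combinations

        for r in (2, 3, 4):
            for combo in combinations(CONCEPT_DICTIONARIES, r):
                mode = "relationship" if r == 2 else "comention"
                assert len(extract_cooccurrences(hits, set(combo), mode)) == 1

    def test_restrictive_predicate_drops_pairs(self, dicts):
        hits = annotate([doc("d1", 2010,
                             ["Lactobacillus rhamnosus raised cytokine levels"])],
                        dicts)
        never = lambda hit, a, b: False
        assert extract_cooccurrences(hits, {"gut-microbes", "immune-related"},
                                     predicate=never) == []

    def test_added_constraint_never_adds_sentences(self, dicts):
        docs, _, _ = generate_corpus(rng_seed=31)
        hits = annotate(docs, dicts)
        pair = extract_cooccurrences(hits, {"gut-microbes", "immune-related"})
        triple = extract_cooccurrences(
            hits, {"gut-microbes", "immune-related", "chemical-related"},
            mode="comention")
        pair_keys = {(h.doc_id, h.sentence) for h in pair}
        assert {(h.doc_id, h.sentence) for h in triple} <= pair_keys


class TestFilterChain:
    def _hits(self, dicts):
        docs = [
            doc("old", 1999, ["Lactobacillus rhamnosus raised cytokine levels"]),
            doc("titled", 2010, ["Lactobacillus rhamnosus and cytokine"],
                section="title"),
            doc("animal", 2010,
                ["In zebrafish Lactobacillus rhamnosus altered cytokine"]),
            doc("genus", 2010, ["Lactobacillus modulates cytokine"]),
            doc("pathogen", 2010, ["Clostridium difficile suppressed cytokine"]),
            doc("clean", 2010, ["Lactobacillus casei boosts cytokine output"]),
        ]
        hits = annotate(docs, dicts)
        return extract_cooccurrences(hits, {"gut-microbes", "immune-related"})

    def test_each_rule_attributed_once(self, dicts):
        # the title-section doc puts its sentence in the title list
        docs = [DocumentRecord("titled", 2010,
                               [("title", ["Lactobacillus casei and cytokine"]),
                                ("abstract", [])])]
        hits = annotate(docs, dicts)
        recs = extract_cooccurrences(hits, {"gut-microbes", "immune-related"})
        kept, removed = filter_chain(recs)
        assert kept == [] and removed["title_section"] == 1

    def test_filter_order_and_counts(self, dicts):
        recs = self._hits(dicts)
        kept, removed = filter_chain(recs)
        assert removed == {"year": 1, "title_section": 1, "excluded_animal": 1,
                           "species_level": 2}
        assert [r.doc_id for r in kept] == ["clean"]

    def test_idempotent(self, dicts):
        kept, _ = filter_chain(self._hits(dicts))
        again, removed = filter_chain(kept)
        assert again == kept
        assert all(v == 0 for v in removed.values())

    def test_total_removed_is_sum_of_rules(self, dicts):
        recs = self._hits(dicts)
        kept, removed = filter_chain(recs)
        assert len(recs) - len(kept) == sum(removed.values())


class TestSpeciesFrequency:
    def test_double_mention_counts_once(self, dicts):
        hits = annotate(
            [doc("d1", 2010, ["Lactobacillus casei with Lactobacillus casei "
                              "and cytokine"])], dicts)
        recs = extract_cooccurrences(hits, {"gut-microbes", "immune-related"})
        freq = species_frequency(recs)
        assert freq.iloc[0]["sentence_count"] == 1

    def test_empty_records_empty_table(self):
        assert species_frequency([]).empty

    def test_planted_frequencies(self, dicts):
        docs, _, manifest = generate_corpus(rng_seed=41)
        hits = annotate(docs, dicts)
        combo = "gut-microbes|immune-related"
        recs = extract_cooccurrences(hits, set(combo.split("|")))
        kept, _ = filter_chain(recs)
        freq = species_frequency(kept)
        want = manifest["per_combo"][combo]["species_frequency"]
        got = dict(zip(freq["species"], freq["sentence_count"]))
        assert got == want
        assert (freq["total_sentences"] ==
                manifest["per_combo"][combo]["sentences_postfilter"]).all()


class TestPlantedCorpusCounts:
    def test_table_shaped_counts_match_manifest(self, dicts):
        from itertools import combinations

        docs, _, manifest = generate_corpus(rng_seed=51)
        hits = annotate(docs, dicts)
        for r in (2, 3, 4):
            mode = "relationship" if r == 2 else "comention"
            for combo in combinations(CONCEPT_DICTIONARIES, r):
                recs = extract_cooccurrences(hits, set(combo), mode)
                kept, _ = filter_chain(recs)
                key = "|".join(sorted(combo))
                want = manifest["per_combo"][key]
                assert combo_counts(recs) == {
                    "sentences": want["sentences_prefilter"],
                    "documents": want["documents_prefilter"]}
                assert combo_counts(kept) == {
                    "sentences": want["sentences_postfilter"],
                    "documents": want["documents_postfilter"]}
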