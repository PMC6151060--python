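import numpy as np
import pandas as pd
import pytest

from gutseed.food_sourcing import (CATEGORIES, DEFAULT_WEIGHTS,
                                   category_profile, category_profiles,
                                   community_food_tables, filter_foods,
                                   match_compounds, normalize_and_score,
                                   normalize_name)
from gutseed.synthetic_data import generate_food_table


def make_table(rows):
    return pd.DataFrame(rows, columns=[
        "food_id", "food_name", "food_class", "compound_name",
        "concentration_mg_per_100g", "detection"])


class TestMatchCompounds:
    def test_case_fold_match(self):
        table = make_table([("f1", "F1", "regular", "d-glucose", 1.0, "quantified")])
        matched, unmatched = match_compounds({"D-Glucose"}, table)
        assert matched == {"d-glucose"} and unmatched == []

    def test_unmatched_is_reported(self):
        table = make_table([("f1", "F1", "regular", "x", 1.0, "quantified")])
        matched, unmatched = match_compounds({"VMH-internal-xyz"}, table)
        assert matched == set() and unmatched == ["VMH-internal-xyz"]

    def test_whitespace_and_unicode_normalization(self):
        table = make_table(
            [("f1", "F1", "regular", "beta  carotene", 1.0, "quantified")])
        matched, _ = match_compounds({"Beta Carotene"}, table)
        assert matched == {normalize_name("beta carotene")}

    def test_generator_planted_match_counts(self):
        table, cmap, seed_names, manifest = generate_food_table(rng_seed=17)
        matched, unmatched = match_compounds(seed_names, table)
        assert len(matched) == manifest["matched_count"]
        assert len(unmatched) == manifest["unmatched_count"]


def cascade_fixture():
    """Hand-built table with one violator per stage."""
    cmap = {"vit a": "vitamins", "aa a": "amino_acids",
            "oligo a": "oligosaccharides", "mono a": "monosaccharides",
            "nsn a": "NSN"}
    full = lambda fid, cls, det="quantified": [
        (fid, fid, cls, "vit a", 1.0, det),
        (fid, fid, cls, "aa a", 1.0, det),
        (fid, fid, cls, "oligo a", 1.0, det),
        (fid, fid, cls, "mono a", 1.0, det),
    ]
    rows = (full("good", "regular")
            + full("booze", "alcohol")
            + full("faint", "regular", det="below_LOQ")
            + [("nsn_only", "nsn_only", "regular", "nsn a", 9.0, "quantified")]
            + full("control", "baby-food", det="below_LOQ"))
    return make_table(rows), cmap


class TestFilterFoods:
    def test_cascade_order_and_counts(self):
        table, cmap = cascade_fixture()
        matched = {normalize_name(c) for c in cmap}
        survivors, counts = filter_foods(table, matched, cmap)
        assert counts.as_dict() == {
            "stage1_contains_matched": 5,
            "stage2_above_loq": 4,      # 'faint' all below LOQ (control kept)
            "stage3_allowed_class": 3,  # 'booze' dropped
            "stage4_growth_factors_detected": 2,  # 'nsn_only' dropped
        }
        assert survivors == {"good", "control"}

    def test_missing_category_raises(self):
        table, cmap = cascade_fixture()
        del cmap["nsn a"]
        with pytest.raises(ValueError, match="nsn a"):
            filter_foods(table, {normalize_name(c) for c in cmap} | {"nsn a"},
                         cmap)

    def test_idempotent_and_monotone(self):
        table, cmap = generate_food_table(rng_seed=23)[:2]
        matched, _ = match_compounds(set(cmap), table)
        survivors, counts = filter_foods(table, matched, cmap)
        vals = list(counts.as_dict().values())
        assert vals == sorted(vals, reverse=True)
        sub = table[table["food_id"].isin(survivors)]
        again, counts2 = filter_foods(sub, matched, cmap)
        assert again == survivors

    def test_golden_fixture_matches_manifest(self):
        table, cmap, seed_names, manifest = generate_food_table(rng_seed=0)
        matched, _ = match_compounds(seed_names, table)
        survivors, counts = filter_foods(table, matched, cmap)
        assert counts.as_dict() == manifest["cascade"]
        assert sorted(survivors) == manifest["survivors"]


# printed top-of-table honey composition used verbatim as fixture input:
# vitamins 0.38, amino acids 7.92, oligosaccharides 426.39, bioactive
# substances 1361.06, N-compounds 0.00, monosaccharides 9352.92, NSN 0.00
HONEY_PROFILE = {
    "vitamins": 0.38, "amino_acids": 7.92, "oligosaccharides": 426.39,
    "bioactive_substances": 1361.06, "nitrogenous_compounds": 0.0,
    "monosaccharides": 9352.92, "NSN": 0.0,
}


def honey_fixture():
    cmap = {
        "vit x": "vitamins", "aa x": "amino_acids", "aa y": "amino_acids",
        "oligo x": "oligosaccharides", "bio x": "bioactive_substances",
        "mono x": "monosaccharides", "n x": "nitrogenous_compounds",
        "nsn x": "NSN",
    }
    rows = [
        ("honey", "Honey", "regular", "vit x", 0.38, "quantified"),
        # the amino-acid mean aggregates two quantified compounds
        ("honey", "Honey", "regular", "aa x", 3.92, "quantified"),
        ("honey", "Honey", "regular", "aa y", 11.92, "quantified"),
        ("honey", "Honey", "regular", "oligo x", 426.39, "quantified"),
        ("honey", "Honey", "regular", "bio x", 1361.06, "quantified"),
        ("honey", "Honey", "regular", "mono x", 9352.92, "quantified"),
        ("honey", "Honey", "regular", "n x", None, "not_detected"),
    ]
    return make_table(rows), cmap


class TestCategoryProfile:
    def test_mean_of_two_compounds(self):
        table, cmap = honey_fixture()
        prof = category_profile(table, "honey", set(cmap), cmap)
        assert prof["amino_acids"] == pytest.approx(7.92)

    def test_absent_category_is_zero(self):
        table, cmap = honey_fixture()
        prof = category_profile(table, "honey", set(cmap), cmap)
        assert prof["NSN"] == 0.0

    def test_honey_row_roundtrips_verbatim(self):
        table, cmap = honey_fixture()
        prof = category_profile(table, "honey", set(cmap), cmap)
        for cat, want in HONEY_PROFILE.items():
            assert prof[cat] == pytest.approx(want, abs=1e-9)


class TestNormalizeAndScore:
    def test_single_food_degenerate_cohort(self):
        profiles = pd.DataFrame(
            {c: [5.0] for c in CATEGORIES}, index=["only"])
        scored = normalize_and_score(profiles)
        assert scored.iloc[0]["score"] == 0.0

    def test_dominant_food_ranks_first(self):
        profiles = pd.DataFrame(
            [[10, 10, 10, 10, 10, 10, 0], [1, 1, 1, 1, 1, 1, 5]],
            columns=list(CATEGORIES), index=["hero", "dud"])
        scored = normalize_and_score(profiles)
        assert scored.iloc[0]["food_id"] == "hero"

    def test_matches_independent_spreadsheet_oracle(self, rng):
        foods = [f"f{i:02d}" for i in range(20)]
        raw = pd.DataFrame(rng.lognormal(1, 1, size=(20, 7)),
                           columns=list(CATEGORIES), index=foods)
        scored = normalize_and_score(raw)
        # oracle: plain numpy arithmetic over the same definition
        arr = raw.values
        span = arr.max(0) - arr.min(0)
        norm = np.where(span == 0, 0.0, (arr - arr.min(0)) / np.where(span == 0, 1, span))
        w = np.array([DEFAULT_WEIGHTS[c] for c in CATEGORIES])
        expected = norm @ w
        got = scored.set_index("food_id").loc[foods, "score"].values
        assert np.allclose(got, expected, atol=1e-12)

    def test_rank_invariant_under_category_rescaling(self, rng):
        raw = pd.DataFrame(rng.lognormal(0, 1, size=(15, 7)),
                           columns=list(CATEGORIES),
                           index=[f"f{i:02d}" for i in range(15)])
        base = list(normalize_and_score(raw)["food_id"])
        scaled = raw.copy()
        scaled["vitamins"] *= 137.5
        assert list(normalize_and_score(scaled)["food_id"]) == base

    def test_raising_nsn_never_improves_rank(self, rng):
        raw = pd.DataFrame(rng.lognormal(0, 1, size=(10, 7)),
                           columns=list(CATEGORIES),
                           index=[f"f{i:02d}" for i in range(10)])
        raw["NSN"] = rng.uniform(0, 1, 10)
        raw.loc["f00", "NSN"] = 0.2
        base_rank = normalize_and_score(raw).set_index("food_id").loc["f00", "rank"]
        bumped = raw.copy()
        bumped.loc["f00", "NSN"] = 0.9  # below the cohort max of ~1
        new_rank = normalize_and_score(bumped).set_index("food_id").loc["f00", "rank"]
        assert new_rank >= base_rank

    def test_single_category_weight_orders_by_that_mean(self, rng):
        raw = pd.DataFrame(rng.lognormal(0, 1, size=(8, 7)),
                           columns=list(CATEGORIES),
                           index=[f"f{i}" for i in range(8)])
        weights = {c: 0.0 for c in CATEGORIES}
        weights["amino_acids"] = 1.0
        scored = normalize_and_score(raw, weights=weights)
        want = list(raw.sort_values("amino_acids", ascending=False).index)
        assert list(scored["food_id"]) == want

    def test_golden_ranking_matches_manifest(self):
        table, cmap, seed_names, manifest = generate_food_table(rng_seed=0)
        matched, _ = match_compounds(seed_names, table)
        survivors, _ = filter_foods(table, matched, cmap)
        profiles = category_profiles(table, survivors, matched, cmap)
        names = dict(zip(table["food_id"], table["food_name"]))
        scored = normalize_and_score(profiles, food_names=names)
        assert list(scored["food_id"]) == manifest["ranking"]
        for fid in survivors:
            assert scored.set_index("food_id").loc[fid, "score"] == \
                pytest.approx(manifest["scores"][fid], abs=1e-9)


class TestCommunityFoodTables:
    def _fixture(self):
        mets = [f"met {i:02d}" for i in range(10)]
        cmap = {m: CATEGORIES[i % 7] for i, m in enumerate(mets)}
        rows = []
        rng = np.random.default_rng(3)
        presence = {}
        for f in range(15):
            fid = f"f{f:02d}"
            have = [m for m in mets if rng.random() < 0.75]
            presence[fid] = set(have)
            for m in have:
                rows.append((fid, fid, "regular", m,
                             float(rng.lognormal(0, 1)), "quantified"))
        return make_table(rows), cmap, set(mets), presence

    def test_full_coverage_food_retained_at_any_threshold(self):
        table, cmap, mets, presence = self._fixture()
        full = {f for f, have in presence.items() if have == mets}
        if not full:
            pytest.skip("no fully covered food in fixture draw")
        cat_df, met_df = community_food_tables(
            table, mets, set(presence), cmap, coverage=0.99)
        assert full <= set(met_df["food_id"])

    def test_impossible_threshold_empties_table(self):
        table, cmap, mets, presence = self._fixture()
        mets = mets | {"never present"}
        cmap["never present"] = "NSN"
        cat_df, met_df = community_food_tables(
            table, mets, set(presence), cmap, coverage=1.0)
        assert met_df.empty and cat_df.empty

    def test_retained_equal_bruteforce_count(self):
        table, cmap, mets, presence = self._fixture()
        cat_df, met_df = community_food_tables(
            table, mets, set(presence), cmap, coverage=0.7)
        want = {f for f, have in presence.items() if len(have) > 7}
        assert set(met_df["food_id"]) == want
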