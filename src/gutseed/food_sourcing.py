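"""Sourcing exogenous metabolites from whole foods.

Seed metabolite names are matched (exact, after normalization) into a
food-composition table; foods then pass a four-stage filter cascade; per-food
category concentration profiles are min-max normalized across the retained
cohort; and a weighted sum over seven compound categories ranks foods by
prebiotic potential.

Categories and default weights: vitamins 10, amino acids 8, oligosaccharides
6, bioactive substances 4, nitrogenous compounds 2, monosaccharides 1, and
non-standard nutritive compounds (NSN: trace metals, ethanol-like small
organics) penalized at -100.

Filter cascade, in order:
  1. keep foods containing at least one matched compound;
  2. drop foods whose matched compounds are all below the limit of
     quantification (no quantified value);
  3. drop processed foods, alcohol, and entries that are not clearly
     defined ("other-undefined");
  4. drop foods where any growth-factor category (amino acids, vitamins,
     oligosaccharides, monosaccharides) has no detected compound (LOD).
Baby-food rows are an annotated control class and are never filtered.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "CATEGORIES",
    "GROWTH_FACTOR_CATEGORIES",
    "DEFAULT_WEIGHTS",
    "FOOD_TABLE_COLUMNS",
    "CascadeCounts",
    "normalize_name",
    "match_compounds",
    "filter_foods",
    "category_profile",
    "category_profiles",
    "normalize_and_score",
    "community_food_tables",
    "read_food_table",
    "read_category_map",
]

CATEGORIES = (
    "oligosaccharides",
    "monosaccharides",
    "amino_acids",
    "vitamins",
    "nitrogenous_compounds",
    "bioactive_substances",
    "NSN",
)

GROWTH_FACTOR_CATEGORIES = (
    "amino_acids", "vitamins", "oligosaccharides", "monosaccharides",
)

DEFAULT_WEIGHTS = {
    "vitamins": 10.0,
    "amino_acids": 8.0,
    "oligosaccharides": 6.0,
    "bioactive_substances": 4.0,
    "nitrogenous_compounds": 2.0,
    "monosaccharides": 1.0,
    "NSN": -100.0,
}

FOOD_TABLE_COLUMNS = [
    "food_id", "food_name", "food_class", "compound_name",
    "concentration_mg_per_100g", "detection",
]

#: detection statuses that count as "detected" for the LOD rule
DETECTED_STATUSES = frozenset({"quantified", "below_LOQ", "detected_below_LOQ"})
QUANTIFIED = "quantified"

#: food classes removed at cascade stage 3
EXCLUDED_CLASSES = frozenset({"processed", "alcohol", "other-undefined"})
CONTROL_CLASS = "baby-food"


def normalize_name(name: str) -> str:
    """Canonical compound-name form: NFC, case-folded, whitespace-collapsed."""
    return " ".join(unicodedata.normalize("NFC", name).casefold().split())


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in FOOD_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"food table missing columns: {missing}")
    return table


def match_compounds(seed_names: set[str],
                    table: pd.DataFrame) -> tuple[set[str], list[str]]:
    """Exact-name match of seed metabolites into the food table.

    Names are compared after Unicode NFC normalization, case folding and
    whitespace collapse; no fuzzy matching.  Returns the matched canonical
    names and the sorted list of unmatched seed names (nomenclature gaps are
    surfaced, not hidden).
    """
    if not seed_names:
        raise ValueError("empty seed metabolite name list")
    _validate_table(table)
    table_names = {normalize_name(n) for n in table["compound_name"]}
    matched, unmatched = set(), []
    for name in seed_names:
        if normalize_name(name) in table_names:
            matched.add(normalize_name(name))
        else:
            unmatched.append(name)
    return matched, sorted(unmatched)


@dataclass
class CascadeCounts:
    """Surviving food counts after each cascade stage."""

    contains_matched: int = 0
    above_loq: int = 0
    allowed_class: int = 0
    growth_factors_detected: int = 0
    survivors: set[str] = field(default_factory=set)

    def as_dict(self) -> dict[str, int]:
        return {
            "stage1_contains_matched": self.contains_matched,
            "stage2_above_loq": self.above_loq,
            "stage3_allowed_class": self.allowed_class,
            "stage4_growth_factors_detected": self.growth_factors_detected,
        }


def _matched_rows(table: pd.DataFrame, matched: set[str]) -> pd.DataFrame:
    norm = table["compound_name"].map(normalize_name)
    return table.assign(_norm_name=norm)[norm.isin(matched)]


def _norm_map(category_map: dict[str, str]) -> dict[str, str]:
    return {normalize_name(k): v for k, v in category_map.items()}


def filter_foods(table: pd.DataFrame, matched: set[str],
                 category_map: dict[str, str]) -> tuple[set[str], CascadeCounts]:
    """Apply the four-stage food filter cascade.

    Returns the surviving food_id set and the per-stage surviving counts.
    Control-class (baby-food) foods bypass stages 2-4 once they contain a
    matched compound.
    """
    _validate_table(table)
    category_map = _norm_map(category_map)
    rows = _matched_rows(table, matched)
    for name in sorted(set(rows["_norm_name"])):
        if name not in category_map:
            raise ValueError(f"matched compound without category: {name!r}")

    by_food = dict(tuple(rows.groupby("food_id", sort=True)))

    stage1 = set(by_food)
    counts = CascadeCounts(contains_matched=len(stage1))

    def is_control(fid: str) -> bool:
        return (by_food[fid]["food_class"] == CONTROL_CLASS).any()

    # stage 2: at least one quantified matched compound
    stage2 = {
        fid for fid in stage1
        if is_control(fid) or (by_food[fid]["detection"] == QUANTIFIED).any()
    }
    counts.above_loq = len(stage2)

    # stage 3: drop excluded food classes
    stage3 = {
        fid for fid in stage2
        if is_control(fid)
        or not by_food[fid]["food_class"].isin(EXCLUDED_CLASSES).any()
    }
    counts.allowed_class = len(stage3)

    # stage 4: every growth-factor category has a detected compound
    stage4 = set()
    for fid in stage3:
        if is_control(fid):
            stage4.add(fid)
            continue
        sub = by_food[fid]
        detected_cats = {
            category_map[n]
            for n, det in zip(sub["_norm_name"], sub["detection"])
            if det in DETECTED_STATUSES
        }
        if all(c in detected_cats for c in GROWTH_FACTOR_CATEGORIES):
            stage4.add(fid)
    counts.growth_factors_detected = len(stage4)
    counts.survivors = stage4
    return stage4, counts


def category_profile(table: pd.DataFrame, food_id: str, matched: set[str],
                     category_map: dict[str, str]) -> dict[str, float]:
    """Per-category mean concentration (mg/100 g) of one food.

    Mean over matched compounds of the category that have quantified values
    in this food; a category with no quantified compound scores 0.
    """
    category_map = _norm_map(category_map)
    rows = _matched_rows(table, matched)
    rows = rows[(rows["food_id"] == food_id) & (rows["detection"] == QUANTIFIED)]
    profile = {c: 0.0 for c in CATEGORIES}
    sums: dict[str, list[float]] = {}
    for name, conc in zip(rows["_norm_name"], rows["concentration_mg_per_100g"]):
        cat = category_map[name]
        sums.setdefault(cat, []).append(float(conc))
    for cat, vals in sums.items():
        profile[cat] = sum(vals) / len(vals)
    return profile


def category_profiles(table: pd.DataFrame, food_ids: set[str], matched: set[str],
                      category_map: dict[str, str]) -> pd.DataFrame:
    """Profiles for a food cohort: foods × categories DataFrame."""
    data = {
        fid: category_profile(table, fid, matched, category_map)
        for fid in sorted(food_ids)
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=list(CATEGORIES))


def normalize_and_score(profiles: pd.DataFrame,
                        weights: dict[str, float] | None = None,
                        food_names: dict[str, str] | None = None) -> pd.DataFrame:
    """Min-max normalize category means across the cohort and rank foods.

    Each category is scaled (x - min)/(max - min) over the retained foods
    (max = min gives 0 for all); the prebiotic food score is the weighted
    sum over categories.  Ranking is by descending score, ties broken by
    food name.  Returns a frame with rank, food, score, raw means and
    normalized values.
    """
    if profiles.empty:
        raise ValueError("no retained foods to score")
    weights = dict(DEFAULT_WEIGHTS, **(weights or {}))
    missing = set(CATEGORIES) - set(weights)
    if missing:
        raise ValueError(f"weights missing categories: {sorted(missing)}")
    normalized = profiles.copy()
    for cat in CATEGORIES:
        col = profiles[cat]
        span = col.max() - col.min()
        normalized[cat] = 0.0 if span == 0 else (col - col.min()) / span
    score = sum(weights[cat] * normalized[cat] for cat in CATEGORIES)

    out = pd.DataFrame({"food_id": profiles.index, "score": score})
    out["food_name"] = [
        (food_names or {}).get(fid, fid) for fid in out["food_id"]
    ]
    for cat in CATEGORIES:
        out[f"mean_{cat}"] = profiles[cat].values
    for cat in CATEGORIES:
        out[f"norm_{cat}"] = normalized[cat].values
    out = out.sort_values(["score", "food_name"],
                          ascending=[False, True]).reset_index(drop=True)
    out.insert(0, "rank", range(1, len(out) + 1))
    cols = (["rank", "food_id", "food_name", "score"]
            + [f"mean_{c}" for c in CATEGORIES]
            + [f"norm_{c}" for c in CATEGORIES])
    return out[cols]


def community_food_tables(table: pd.DataFrame, shared_metabolites: set[str],
                          retained_foods: set[str],
                          category_map: dict[str, str],
                          coverage: float = 0.7) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format category↔food and metabolite↔food relation tables.

    Only foods covering more than ``coverage`` (fraction) of the
    community-shared metabolites are retained (default 0.7).  Concentrations
    are mean mg/100 g over the food's quantified rows of each metabolite /
    category.  Ready for circular (Circos-style) plotting; plotting itself
    is out of scope.
    """
    if not shared_metabolites:
        raise ValueError("no shared metabolites supplied")
    shared = {normalize_name(m) for m in shared_metabolites}
    category_map = _norm_map(category_map)
    rows = _matched_rows(table, shared)
    rows = rows[rows["food_id"].isin(retained_foods)
                & (rows["detection"] == QUANTIFIED)]
    met_rows, cat_rows = [], []
    for fid, sub in rows.groupby("food_id", sort=True):
        present = set(sub["_norm_name"])
        if len(present) <= coverage * len(shared):
            continue
        for met, msub in sub.groupby("_norm_name", sort=True):
            met_rows.append({
                "food_id": fid, "metabolite": met,
                "mean_concentration": msub["concentration_mg_per_100g"].mean(),
            })
        cats = sub.assign(_cat=sub["_norm_name"].map(category_map))
        for cat, csub in cats.groupby("_cat", sort=True):
            cat_rows.append({
                "food_id": fid, "category": cat,
                "mean_concentration": csub["concentration_mg_per_100g"].mean(),
            })
    met_df = pd.DataFrame(met_rows, columns=["food_id", "metabolite",
                                             "mean_concentration"])
    cat_df = pd.DataFrame(cat_rows, columns=["food_id", "category",
                                             "mean_concentration"])
    return cat_df, met_df


def read_food_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={c: str for c in FOOD_TABLE_COLUMNS
                            if c != "concentration_mg_per_100g"})
    _validate_table(df)
    df["concentration_mg_per_100g"] = pd.to_numeric(
        df["concentration_mg_per_100g"], errors="coerce")
    return df


def read_category_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if list(df.columns) != ["compound_name", "category"]:
        raise ValueError("category map TSV must have columns compound_name, category")
    bad = set(df["category"]) - set(CATEGORIES)
    if bad:
        raise ValueError(f"unknown categories: {sorted(bad)}")
    return {normalize_name(n): c for n, c in zip(df["compound_name"], df["category"])}
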