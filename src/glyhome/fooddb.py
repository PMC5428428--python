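"""Food composition table and tiered glycemic-index assignment.

Every carbohydrate-bearing food receives a glycemic index (GI, glucose = 100
reference) through a fixed resolution order:

1. ``direct`` — a published GI recorded for the food itself;
2. ``close_match`` — the GI of an explicitly aliased close match
   (an alias column, not fuzzy matching, so assignments are reproducible);
3. ``recipe`` — the carbohydrate-weighted mean GI of the food's ingredients;
4. ``zero_rule`` — foods that are mainly fat or protein, with less than
   5 g carbohydrate per 100 g, are assigned GI 0.

The zero rule dominates: a food below the carbohydrate threshold is assigned
GI 0 whatever else is recorded for it.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .errors import (
    IntegrityError,
    ParseError,
    SchemaError,
    UndefinedGIError,
    UnresolvedGIError,
)

GI_TIERS = ("direct", "close_match", "recipe", "zero_rule")

#: Foods with less than this much carbohydrate per 100 g get GI 0.
ZERO_RULE_CHO_G = 5.0

#: Recipe ingredient masses may overshoot 100 g per 100 g of recipe by this
#: factor, absorbing water loss during cooking.
RECIPE_MASS_TOLERANCE = 1.05

#: Nested recipes are resolved iteratively up to this depth.
MAX_RECIPE_DEPTH = 5

MANDATORY_COLUMNS = ("food_id", "name", "cho_per_100g", "fiber_per_100g", "is_cereal")
NUMERIC_COLUMNS = (
    "cho_per_100g",
    "fiber_per_100g",
    "gi",
    "energy_kcal_per_100g",
    "protein_per_100g",
    "fat_per_100g",
)


@dataclass(frozen=True)
class FoodEntry:
    """One food with its composition per 100 g and GI provenance."""

    food_id: str
    name: str
    cho_per_100g: float
    fiber_per_100g: float
    is_cereal: bool
    energy_kcal_per_100g: float = 0.0
    protein_per_100g: float = 0.0
    fat_per_100g: float = 0.0
    gi: float | None = None
    gi_tier: str | None = None
    close_match: str | None = None
    #: (ingredient food_id, grams per 100 g of recipe)
    ingredients: tuple[tuple[str, float], ...] | None = None

    def __post_init__(self):
        if self.cho_per_100g < 0:
            raise ValueError(f"{self.food_id}: negative carbohydrate content")
        if not 0 <= self.fiber_per_100g <= 100:
            raise ValueError(f"{self.food_id}: fiber_per_100g outside [0, 100]")
        if self.gi is not None and not 0 <= self.gi <= 110:
            raise ValueError(f"{self.food_id}: GI {self.gi} outside [0, 110]")
        if self.ingredients:
            total = sum(g for _, g in self.ingredients)
            if total > 100.0 * RECIPE_MASS_TOLERANCE:
                raise ValueError(
                    f"{self.food_id}: recipe ingredient grams sum to {total:.1f} "
                    f"per 100 g (tolerance {100 * RECIPE_MASS_TOLERANCE:.0f})"
                )


@dataclass(frozen=True)
class GIAssignment:
    """Resolved GI for one food, with its provenance tier."""

    food_id: str
    gi: float
    tier: str
    source_note: str = ""

    def __post_init__(self):
        if self.tier not in GI_TIERS:
            raise ValueError(f"unknown GI tier {self.tier!r}")
        if self.gi < 0:
            raise ValueError("GI must be non-negative")


class FoodTable:
    """Collection of :class:`FoodEntry`, indexed by ``food_id``."""

    def __init__(self, foods: Iterable[FoodEntry]):
        self._foods: dict[str, FoodEntry] = {}
        for food in foods:
            if food.food_id in self._foods:
                raise IntegrityError(f"duplicate food_id {food.food_id!r}")
            self._foods[food.food_id] = food
        self._gi_cache: dict[str, GIAssignment] = {}

    def __len__(self) -> int:
        return len(self._foods)

    def __iter__(self) -> Iterator[FoodEntry]:
        return iter(self._foods.values())

    def __contains__(self, food_id: str) -> bool:
        return food_id in self._foods

    def get(self, food_id: str) -> FoodEntry:
        try:
            return self._foods[food_id]
        except KeyError:
            raise KeyError(f"unknown food_id {food_id!r}") from None

    def gi_of(self, food_id: str) -> GIAssignment:
        """Resolved (cached) GI assignment for one food."""
        if food_id not in self._gi_cache:
            self._gi_cache[food_id] = assign_gi(self.get(food_id), self)
        return self._gi_cache[food_id]

    def assign_all(self) -> pd.DataFrame:
        """GI assignments for every food, as a table."""
        rows = [
            {"food_id": a.food_id, "gi": a.gi, "tier": a.tier, "source_note": a.source_note}
            for a in (self.gi_of(fid) for fid in self._foods)
        ]
        return pd.DataFrame(rows)

    def composition_frame(self) -> pd.DataFrame:
        """Per-100 g composition with resolved GI, indexed by food_id."""
        rows = []
        for food in self:
            a = self.gi_of(food.food_id)
            rows.append(
                {
                    "food_id": food.food_id,
                    "cho_per_100g": food.cho_per_100g,
                    "fiber_per_100g": food.fiber_per_100g,
                    "is_cereal": food.is_cereal,
                    "energy_kcal_per_100g": food.energy_kcal_per_100g,
                    "protein_per_100g": food.protein_per_100g,
                    "fat_per_100g": food.fat_per_100g,
                    "gi": a.gi,
                    "gi_tier": a.tier,
                }
            )
        return pd.DataFrame(rows).set_index("food_id")


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in {"1", "true", "yes", "y"}:
        return True
    if text in {"0", "false", "no", "n"}:
        return False
    raise ValueError(f"cannot parse boolean {value!r}")


def _parse_ingredients(text: str) -> tuple[tuple[str, float], ...]:
    """Parse ``"id:grams;id:grams"`` ingredient encoding."""
    pairs = []
    for chunk in str(text).split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        food_id, _, grams = chunk.partition(":")
        pairs.append((food_id.strip(), float(grams)))
    return tuple(pairs)


def load_food_table(path: str | Path | io.StringIO) -> FoodTable:
    """Load a delimited (tab or comma) food table.

    Mandatory columns: food_id, name, cho_per_100g, fiber_per_100g, is_cereal.
    Optional: gi, close_match, ingredients ("id:grams;id:grams"), and
    energy/protein/fat per 100 g (required later for diet scoring).
    """
    raw = pd.read_csv(path, sep=None, engine="python", dtype=str)
    missing = [c for c in MANDATORY_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"food table missing mandatory column(s): {', '.join(missing)}")

    foods = []
    for i, row in raw.iterrows():
        kwargs: dict = {"food_id": str(row["food_id"]).strip(), "name": str(row["name"]).strip()}
        for col in NUMERIC_COLUMNS:
            if col not in raw.columns:
                continue
            cell = row[col]
            if pd.isna(cell) or str(cell).strip() == "":
                continue
            try:
                kwargs[col] = float(cell)
            except ValueError:
                raise ParseError(
                    f"row {i}: cannot parse {col}={cell!r} for food "
                    f"{row['food_id']!r}",
                    row=int(i),
                ) from None
        try:
            kwargs["is_cereal"] = _parse_bool(row["is_cereal"])
        except ValueError:
            raise ParseError(
                f"row {i}: cannot parse is_cereal={row['is_cereal']!r}", row=int(i)
            ) from None
        if "close_match" in raw.columns and not pd.isna(row["close_match"]):
            text = str(row["close_match"]).strip()
            if text:
                kwargs["close_match"] = text
        if "ingredients" in raw.columns and not pd.isna(row["ingredients"]):
            text = str(row["ingredients"]).strip()
            if text:
                try:
                    kwargs["ingredients"] = _parse_ingredients(text)
                except ValueError:
                    raise ParseError(
                        f"row {i}: cannot parse ingredients={row['ingredients']!r}",
                        row=int(i),
                    ) from None
        if "cho_per_100g" not in kwargs:
            raise ParseError(f"row {i}: missing cho_per_100g", row=int(i))
        kwargs.setdefault("fiber_per_100g", 0.0)
        foods.append(FoodEntry(**kwargs))
    return FoodTable(foods)


def recipe_gi(ingredients: Iterable[tuple[float, float]]) -> float:
    """Carbohydrate-weighted mean GI of recipe ingredients.

    ``ingredients`` is an iterable of (carbohydrate grams, GI). The result is
    sum(cho * gi) / sum(cho), so it always lies within [min GI, max GI] of the
    ingredients (convexity).
    """
    pairs = [(float(c), float(g)) for c, g in ingredients]
    total_cho = sum(c for c, _ in pairs)
    if total_cho <= 0:
        raise UndefinedGIError("recipe has zero total carbohydrate; GI undefined")
    return sum(c * g for c, g in pairs) / total_cho


def assign_gi(food: FoodEntry, table: FoodTable, _depth: int = 0) -> GIAssignment:
    """Resolve a GI for ``food`` using the tiered procedure.

    Resolution order is direct -> close_match -> recipe -> zero_rule, except
    that the zero rule (carbohydrate below 5 g/100 g) dominates everything.
    """
    if _depth > MAX_RECIPE_DEPTH:
        raise UnresolvedGIError(
            f"{food.food_id}: recipe/alias nesting exceeds depth {MAX_RECIPE_DEPTH} "
            "(possible cycle)"
        )
    if food.cho_per_100g < ZERO_RULE_CHO_G:
        return GIAssignment(
            food.food_id, 0.0, "zero_rule", f"CHO {food.cho_per_100g:g} g/100g < {ZERO_RULE_CHO_G:g}"
        )
    if food.gi is not None:
        return GIAssignment(food.food_id, float(food.gi), "direct", "published GI")
    if food.close_match is not None:
        match = table.get(food.close_match)
        resolved = assign_gi(match, table, _depth=_depth + 1)
        return GIAssignment(
            food.food_id, resolved.gi, "close_match", f"close match to {match.food_id}"
        )
    if food.ingredients:
        pairs = []
        for ing_id, grams in food.ingredients:
            ing = table.get(ing_id)
            ing_assignment = assign_gi(ing, table, _depth=_depth + 1)
            pairs.append((grams * ing.cho_per_100g / 100.0, ing_assignment.gi))
        gi = recipe_gi(pairs)
        return GIAssignment(
            food.food_id, gi, "recipe", f"{len(pairs)} ingredient(s), CHO-weighted"
        )
    raise UnresolvedGIError(
        f"{food.food_id} ({food.name}): CHO >= {ZERO_RULE_CHO_G:g} g/100g but no "
        "published GI, close match or recipe"
    )


def demo_catalog() -> FoodTable:
    """Small demonstration catalog of common south-Chinese foods.

    GI values are published glucose-scale figures for these foods (high-GI
    rice varieties 72-83, steamed bread 88, rice porridge 69, lower-GI rice
    42-69, wheat noodles 46, apple 28, mung-bean noodles 39, black-rice
    porridge 42); composition per 100 g (cooked where applicable) is
    typical-food-table level. Includes one recipe food and one close-match
    alias so every assignment tier is exercised.
    """
    entries = [
        # staples, high-GI pool
        FoodEntry("rice_sticky", "sticky rice, cooked", 28.0, 1.35, True, 130, 2.7, 0.3, gi=83),
        FoodEntry("rice_high", "high-GI long rice, cooked", 28.0, 1.3, True, 130, 2.7, 0.3, gi=72),
        FoodEntry("steamed_bread", "steamed wheat bread", 47.0, 2.2, True, 233, 7.0, 1.0, gi=88),
        FoodEntry("rice_porridge", "rice porridge", 12.0, 0.3, True, 55, 1.1, 0.1, gi=69),
        # staples, lower-GI pool
        FoodEntry("rice_low", "lower-GI rice variety, cooked", 28.0, 1.2, True, 130, 2.7, 0.3, gi=62),
        FoodEntry("rice_low_b", "parboiled rice, cooked", 28.0, 1.3, True, 130, 2.7, 0.3, gi=55),
        FoodEntry("wheat_noodles", "wheat noodles, cooked", 25.0, 1.3, True, 138, 4.5, 0.7, gi=46),
        FoodEntry("mung_noodles", "mung bean noodles, cooked", 21.0, 0.9, True, 90, 0.2, 0.1, gi=39),
        FoodEntry("black_porridge", "black-rice porridge", 14.0, 0.8, True, 62, 1.4, 0.2, gi=42),
        FoodEntry("apple", "apple, raw", 14.0, 2.4, False, 52, 0.3, 0.2, gi=28),
        # close-match alias: millet porridge scored like rice porridge
        FoodEntry(
            "millet_porridge", "millet porridge", 13.0, 0.4, True, 58, 1.2, 0.2,
            close_match="rice_porridge",
        ),
        # recipe food: rice cooked with mung-bean noodles
        FoodEntry(
            "rice_mung_bowl", "rice and mung-noodle bowl", 26.0, 1.0, True, 118, 2.2, 0.3,
            ingredients=(("rice_sticky", 70.0), ("mung_noodles", 30.0)),
        ),
        # sides, mostly zero-rule
        FoodEntry("vegetables", "leafy vegetables, stir-fried", 4.0, 1.8, False, 35, 1.8, 1.5),
        FoodEntry("pork", "pork, cooked", 0.7, 0.0, False, 290, 17.0, 24.0),
        FoodEntry("egg", "chicken egg, cooked", 1.1, 0.0, False, 155, 13.0, 11.0),
        FoodEntry("tofu", "tofu", 1.9, 0.3, False, 76, 8.0, 4.8),
        FoodEntry("oil", "cooking oil", 0.0, 0.0, False, 884, 0.0, 100.0),
    ]
    return FoodTable(entries)
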