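"""Food categorization and energy-adjusted intake aggregation.

Each food is assigned, from its per-100 g composition, to exactly one of 13
categories, each labelled healthy or unhealthy. The thresholds implement
nutrient-profile rules of the kind used in paediatric dietary-quality
scoring: a cereal is healthy when sugar < 15 g/100 g, fat < 15 g/100 g and
fiber >= 5 g/100 g (unhealthy cereals are the complement); fats & oils are
healthy when of plant origin with sauces below 40% fat; fresh meat is
healthy below 10% fat and processed meat products below 20% fat; dairy is
healthy when low-fat and unsweetened; mixed dishes are healthy when
plant-based; sugar & sweets are always unhealthy and meat alternatives and
fruits & vegetables always healthy. Daily intakes are expressed as energy
(kcal), macronutrient percentages of energy (Atwater 9/4/4 kcal per g) and
category grams per 1000 kcal; category densities sum to healthy and
unhealthy totals.

The thresholds live in an editable rule table (`default_rules`, YAML
round-trip via `load_rules`/`dump_rules`) because the printed rules are
examples rather than complete predicates for some groups.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

KCAL_PER_G = {"fat": 9.0, "carbohydrate": 4.0, "protein": 4.0, "sugar": 4.0}

COARSE_GROUPS = (
    "cereals", "sweets", "fats_oils", "fruits_vegetables",
    "meat", "meat_alternatives", "milk_dairy", "mixed_dishes",
)

HEALTHY_CATEGORIES = (
    "healthy_cereals", "healthy_fats_oils", "fruits_vegetables",
    "healthy_meat", "healthy_milk_dairy", "healthy_meat_alternatives",
    "healthy_mixed_dishes",
)
UNHEALTHY_CATEGORIES = (
    "unhealthy_cereals", "sugar_sweets", "unhealthy_fats_oils",
    "unhealthy_meat", "unhealthy_milk_dairy", "unhealthy_mixed_dishes",
)
ALL_CATEGORIES = HEALTHY_CATEGORIES + UNHEALTHY_CATEGORIES


class ClassificationError(ValueError):
    pass


@dataclass
class CategoryRules:
    """Editable thresholds behind the 13-category classification (g/100 g)."""

    cereal_sugar_max: float = 15.0
    cereal_fat_max: float = 15.0
    cereal_fiber_min: float = 5.0
    sauce_fat_max: float = 40.0
    meat_fat_max: float = 10.0
    meat_product_fat_max: float = 20.0
    dairy_fat_max: float = 3.5
    dairy_sugar_max: float = 10.0


def default_rules() -> CategoryRules:
    return CategoryRules()


def load_rules(path: str | Path) -> CategoryRules:
    return CategoryRules(**yaml.safe_load(Path(path).read_text()))


def dump_rules(rules: CategoryRules, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(vars(rules), sort_keys=False))


def classify_food(food: Mapping, rules: CategoryRules | None = None) -> str:
    """Assign one food-composition record to one of the 13 categories.

    ``food`` must expose per-100 g ``sugar_g``, ``fat_g``, ``fiber_g``, a
    ``coarse_group`` (one of COARSE_GROUPS), an ``origin`` flag
    (plant | animal | processed) and a boolean ``is_sauce``.
    """
    r = rules or default_rules()
    group = food["coarse_group"]
    sugar, fat, fiber = food["sugar_g"], food["fat_g"], food["fiber_g"]
    origin = food.get("origin", "plant")
    is_sauce = bool(food.get("is_sauce", False))

    if group == "cereals":
        healthy = (
            sugar < r.cereal_sugar_max
            and fat < r.cereal_fat_max
            and fiber >= r.cereal_fiber_min
        )
        return "healthy_cereals" if healthy else "unhealthy_cereals"
    if group == "sweets":
        return "sugar_sweets"
    if group == "fats_oils":
        healthy = origin == "plant" and (not is_sauce or fat < r.sauce_fat_max)
        return "healthy_fats_oils" if healthy else "unhealthy_fats_oils"
    if group == "fruits_vegetables":
        return "fruits_vegetables"
    if group == "meat":
        if origin == "processed":  # meat products
            healthy = fat < r.meat_product_fat_max
        else:
            healthy = fat < r.meat_fat_max
        return "healthy_meat" if healthy else "unhealthy_meat"
    if group == "meat_alternatives":
        return "healthy_meat_alternatives"
    if group == "milk_dairy":
        healthy = fat < r.dairy_fat_max and sugar < r.dairy_sugar_max
        return "healthy_milk_dairy" if healthy else "unhealthy_milk_dairy"
    if group == "mixed_dishes":
        healthy = origin == "plant"
        return "healthy_mixed_dishes" if healthy else "unhealthy_mixed_dishes"
    raise ClassificationError(f"unknown coarse group {group!r} in record {dict(food)!r}")


def classify_composition(
    composition: pd.DataFrame, rules: CategoryRules | None = None
) -> pd.Series:
    """Category label for every row of a composition table, indexed by food_id."""
    out = {
        row["food_id"]: classify_food(row, rules)
        for _, row in composition.iterrows()
    }
    return pd.Series(out, name="category")


@dataclass
class DailyTotals:
    """One person-day of intake, aggregated and energy-adjusted."""

    energy_kcal: float
    macronutrient_g: dict[str, float]
    macronutrient_pct_energy: dict[str, float]
    category_g: dict[str, float]
    category_density: dict[str, float]     # grams per 1000 kcal
    healthy_sum: float                     # g/1000 kcal over healthy categories
    unhealthy_sum: float


def daily_totals(
    day_records: pd.DataFrame,
    composition: pd.DataFrame,
    rules: CategoryRules | None = None,
) -> DailyTotals:
    """Aggregate one recall day (columns food_id, amount_g) against a
    composition table (per-100 g nutrient columns)."""
    comp = composition.set_index("food_id")
    merged = day_records.join(comp, on="food_id", how="left")
    if merged["energy_kcal"].isna().any():
        missing = merged.loc[merged["energy_kcal"].isna(), "food_id"].tolist()
        raise ClassificationError(f"foods missing from composition table: {missing}")

    scale = merged["amount_g"] / 100.0
    energy = float((scale * merged["energy_kcal"]).sum())
    if energy <= 0:
        raise ClassificationError("zero-energy day: densities undefined")

    macro_g = {
        n: float((scale * merged[f"{n}_g"]).sum())
        for n in ("fat", "carbohydrate", "protein", "sugar")
    }
    macro_pct = {
        n: 100.0 * macro_g[n] * KCAL_PER_G[n] / energy for n in macro_g
    }

    categories = merged.apply(lambda row: classify_food(row, rules), axis=1)
    cat_g = {c: 0.0 for c in ALL_CATEGORIES}
    for cat, amount in zip(categories, merged["amount_g"]):
        cat_g[cat] += float(amount)
    density = {c: 1000.0 * g / energy for c, g in cat_g.items()}
    healthy = sum(density[c] for c in HEALTHY_CATEGORIES)
    unhealthy = sum(density[c] for c in UNHEALTHY_CATEGORIES)
    return DailyTotals(
        energy_kcal=energy,
        macronutrient_g=macro_g,
        macronutrient_pct_energy=macro_pct,
        category_g=cat_g,
        category_density=density,
        healthy_sum=healthy,
        unhealthy_sum=unhealthy,
    )


def sum_health_groups(totals: DailyTotals) -> tuple[float, float]:
    """(healthy_sum, unhealthy_sum) in g/1000 kcal, re-derived from densities."""
    healthy = sum(totals.category_density[c] for c in HEALTHY_CATEGORIES)
    unhealthy = sum(totals.category_density[c] for c in UNHEALTHY_CATEGORIES)
    return healthy, unhealthy


def person_day_table(
    recalls: pd.DataFrame,
    composition: pd.DataFrame,
    rules: CategoryRules | None = None,
    variables: Iterable[str] = ("energy_kcal", "healthy_sum", "unhealthy_sum"),
) -> pd.DataFrame:
    """Per person-day aggregates for the whole recall table.

    ``recalls`` needs columns person_id, day_index, day_type, food_id,
    amount_g. Returns one row per (person_id, day_index) with day_type,
    energy, macronutrient %, per-category densities and healthy/unhealthy
    sums — the long-format input of the usual-intake stage.
    """
    rows = []
    for (pid, day), group in recalls.groupby(["person_id", "day_index"], sort=True):
        totals = daily_totals(group[["food_id", "amount_g"]], composition, rules)
        row = {
            "person_id": pid,
            "day_index": day,
            "day_type": group["day_type"].iloc[0],
            "energy_kcal": totals.energy_kcal,
            "healthy_sum": totals.healthy_sum,
            "unhealthy_sum": totals.unhealthy_sum,
        }
        row.update({f"pct_{k}": v for k, v in totals.macronutrient_pct_energy.items()})
        row.update({f"dens_{c}": v for c, v in totals.category_density.items()})
        rows.append(row)
    return pd.DataFrame(rows)
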