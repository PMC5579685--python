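"""Classify foods into the 13 healthy/unhealthy categories and aggregate
one recall day into energy, macronutrient shares, and food-group densities.
"""
import pandas as pd

from famdiet import classify_food, daily_totals, sum_health_groups
from famdiet.simulate import default_composition

composition = default_composition()
composition["category"] = [classify_food(row) for _, row in composition.iterrows()]
print(composition[["food_id", "coarse_group", "category"]].to_string(index=False))

day = pd.DataFrame(
    {"food_id": ["oat_porridge", "apple", "chicken_breast", "chocolate", "french_fries"],
     "amount_g": [200.0, 150.0, 120.0, 40.0, 150.0]}
)
totals = daily_totals(day, composition)
healthy, unhealthy = sum_health_groups(totals)
print(f"\nday energy: {totals.energy_kcal:.0f} kcal")
print("macronutrients (% of energy): "
      + ", ".join(f"{k} {v:.1f}%" for k, v in totals.macronutrient_pct_energy.items()))
print(f"healthy foods:   {healthy:.0f} g/1000 kcal")
print(f"unhealthy foods: {unhealthy:.0f} g/1000 kcal")
print("\nDensities are energy-adjusted (grams per 1000 kcal), so they compare")
print("food-group composition across people with different energy needs.")
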