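"""Synthetic nuclear-family dietary data generator.

Generates the full input bundle of the analysis with the statistical
structure the downstream stages assume: nuclear families drawn from a
reference family-type mix, a latent familial dietary-quality trait built
from additive genetic (mid-parent transmission, sibling genetic
correlation exactly 0.5), shared-household and unique components, repeated
24-h recall days whose healthy/unhealthy food split follows the trait with
multiplicative (lognormal) day-to-day noise and a weekend effect, a
configurable fraction of energy under-reporters, and FFQ frequency levels
that are a monotone noisy discretization of usual intake.

A single seed drives everything; per-family substreams are spawned from it
hierarchically so any family's draw is reproducible in isolation.
"""
from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .config import ConfigurationError, SimulationConfig, dump_config, family_type_size
from .foods import ALL_CATEGORIES, HEALTHY_CATEGORIES, classify_composition
from .intake import reference_bmr_kcal
from .pedigree import Family, Person

TRAIT_VARIABLES = ("energy_kcal", "healthy_sum", "unhealthy_sum")


def default_composition() -> pd.DataFrame:
    """Small built-in food-composition table (per 100 g edible portion)
    covering all 13 categories; synthetic, not a real national database."""
    cols = (
        "food_id", "coarse_group", "origin", "is_sauce",
        "energy_kcal", "fat_g", "carbohydrate_g", "sugar_g", "fiber_g", "protein_g",
    )
    rows = [
        ("oat_porridge",   "cereals",           "plant",     False, 370, 7.0, 60.0, 1.0, 10.0, 13.0),
        ("white_bread",    "cereals",           "plant",     False, 265, 3.0, 50.0, 4.0, 3.0, 9.0),
        ("sweet_biscuits", "cereals",           "processed", False, 450, 18.0, 65.0, 25.0, 2.0, 6.0),
        ("chocolate",      "sweets",            "processed", False, 530, 30.0, 58.0, 50.0, 4.0, 6.0),
        ("olive_oil",      "fats_oils",         "plant",     False, 900, 100.0, 0.0, 0.0, 0.0, 0.0),
        ("tomato_dressing","fats_oils",         "plant",     True,  225, 20.0, 8.0, 5.0, 1.0, 2.0),
        ("butter",         "fats_oils",         "animal",    False, 745, 82.0, 1.0, 1.0, 0.0, 1.0),
        ("mayonnaise",     "fats_oils",         "processed", True,  690, 75.0, 2.0, 1.0, 0.0, 1.0),
        ("apple",          "fruits_vegetables", "plant",     False, 55, 0.2, 14.0, 10.0, 2.0, 0.3),
        ("broccoli",       "fruits_vegetables", "plant",     False, 40, 0.4, 7.0, 1.7, 2.6, 2.8),
        ("chicken_breast", "meat",              "animal",    False, 110, 3.0, 0.0, 0.0, 0.0, 23.0),
        ("pork_belly",     "meat",              "animal",    False, 290, 25.0, 0.0, 0.0, 0.0, 17.0),
        ("salami",         "meat",              "processed", False, 375, 33.0, 1.0, 0.5, 0.0, 22.0),
        ("tofu",           "meat_alternatives", "plant",     False, 120, 7.0, 2.0, 1.0, 1.0, 12.0),
        ("skim_milk",      "milk_dairy",        "animal",    False, 35, 0.3, 5.0, 5.0, 0.0, 3.4),
        ("chocolate_milk", "milk_dairy",        "processed", False, 90, 3.5, 12.0, 12.0, 0.0, 3.3),
        ("vegetable_stew", "mixed_dishes",      "plant",     False, 90, 3.0, 12.0, 3.0, 3.0, 4.0),
        ("french_fries",   "mixed_dishes",      "processed", False, 310, 15.0, 41.0, 0.5, 3.5, 3.5),
    ]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Family structures
# ---------------------------------------------------------------------------

def sample_family_structures(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> list[Family]:
    """Draw family compositions, member sexes and integer ages.

    Parent ages are uniform on the configured parent range, child ages on
    the child range; every family forms one household.
    """
    config.validate()
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    types = list(config.family_type_probs)
    probs = np.array([config.family_type_probs[t] for t in types])
    countries = list(config.country_probs)
    cprobs = np.array([config.country_probs[c] for c in countries])

    type_idx = rng.choice(len(types), size=config.n_families, p=probs)
    country_idx = rng.choice(len(countries), size=config.n_families, p=cprobs)
    p_lo, p_hi = config.parent_age_range
    c_lo, c_hi = config.child_age_range

    families = []
    for f in range(config.n_families):
        parents, n_children = types[type_idx[f]]
        fid = f"F{f:05d}"
        country = countries[country_idx[f]]
        members: list[Person] = []
        if parents in ("mother", "both"):
            members.append(Person(f"{fid}.M", fid, fid, "mother", "F",
                                  int(rng.integers(p_lo, p_hi + 1)), country))
        if parents in ("father", "both"):
            members.append(Person(f"{fid}.F", fid, fid, "father", "M",
                                  int(rng.integers(p_lo, p_hi + 1)), country))
        for c in range(n_children):
            sex = "F" if rng.random() < 0.5 else "M"
            members.append(Person(f"{fid}.C{c}", fid, fid, "child", sex,
                                  int(rng.integers(c_lo, c_hi + 1)), country))
        if len(members) < 2:
            raise ConfigurationError(f"family type {types[type_idx[f]]} has fewer than 2 members")
        families.append(Family(fid, members))
    return families


# ---------------------------------------------------------------------------
# Latent familial trait
# ---------------------------------------------------------------------------

def simulate_latent_traits(
    families: list[Family],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """One latent trait value per person: trait = g + c + e.

    Parents draw independent (optionally spouse-correlated) genetic values
    g ~ N(0, sigma2_g); children receive the mid-parent value plus a
    segregation deviation N(0, sigma2_g/2), so parent-offspring and
    full-sibling genetic correlations are exactly 0.5. Parents absent from
    the family record are drawn latently so sibling structure is preserved.
    One household value c ~ N(0, sigma2_c) is shared by all members;
    e ~ N(0, sigma2_e) is independent.
    """
    config.validate()
    s2g, s2c, s2e = config.sigma2_g, config.sigma2_c, config.sigma2_e
    rho = config.spouse_trait_corr
    sg = math.sqrt(s2g)
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])

    values: dict[str, float] = {}
    for fam in families:
        # spouse-correlated parental genetic values (latent when absent)
        gm = rng.normal(0.0, sg)
        gf = rho * gm + math.sqrt(max(1.0 - rho**2, 0.0)) * rng.normal(0.0, sg)
        c = rng.normal(0.0, math.sqrt(s2c))
        for m in fam.members:
            if m.role == "mother":
                g = gm
            elif m.role == "father":
                g = gf
            else:
                g = 0.5 * (gm + gf) + rng.normal(0.0, math.sqrt(s2g / 2.0))
            values[m.person_id] = g + c + rng.normal(0.0, math.sqrt(s2e))
    return pd.Series(values, name="trait")


# ---------------------------------------------------------------------------
# Recall days
# ---------------------------------------------------------------------------

def _reference_energy(role: str, age: int) -> float:
    """Typical daily energy (kcal) by role/age, anchoring the generator."""
    if role == "mother":
        return 1700.0
    if role == "father":
        return 2250.0
    return 1300.0 + 45.0 * age


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _healthy_share(z: float) -> float:
    # mean share ~0.61 at trait 0, matching healthy:unhealthy density ratios
    # seen in family dietary studies; slope sets the trait's leverage.
    return _sigmoid(0.45 + 0.5 * z)


def _category_weights(h: float) -> dict[str, float]:
    w = {}
    for c in ALL_CATEGORIES:
        if c in HEALTHY_CATEGORIES:
            w[c] = h / len(HEALTHY_CATEGORIES)
        else:
            w[c] = (1.0 - h) / (len(ALL_CATEGORIES) - len(HEALTHY_CATEGORIES))
    return w


def simulate_recall_days(
    families: list[Family],
    traits: pd.Series,
    composition: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-person recall records plus the true usual intakes.

    Each person gets 1-4 recall days per the configured availability mix.
    A day's energy is the person's reference energy times the weekend
    factor (weekend days occur with probability 2/7) times mean-one
    lognormal noise at the configured CV; food amounts are drawn so the
    healthy/unhealthy category split follows the person's trait. A flagged
    ``underreport_fraction`` of persons has every day's amounts scaled so
    reported energy falls below the Goldberg lower plausibility cutoff.

    Returns (recalls, truth): recalls with columns person_id, day_index,
    day_type, food_id, amount_g, complete; truth with one row per person
    holding the trait, healthy share, underreport flag and the true usual
    energy/healthy/unhealthy values the recalls fluctuate around.
    """
    if len(composition) == 0:
        raise ConfigurationError("empty composition fixture")
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])

    categories = classify_composition(composition)
    comp = composition.set_index("food_id")
    by_cat: dict[str, list[str]] = {}
    for fid, cat in categories.items():
        by_cat.setdefault(cat, []).append(fid)
    missing = set(ALL_CATEGORIES) - set(by_cat)
    if missing:
        raise ConfigurationError(f"composition fixture lacks categories {sorted(missing)}")
    energy_density = comp["energy_kcal"] / 100.0  # kcal per gram

    sd_total = math.sqrt(max(config.total_variance, 1e-12))
    cv = config.within_person_cv
    sigma_ln = math.sqrt(math.log(1.0 + cv**2)) if cv > 0 else 0.0
    n_day_choices = np.arange(1, len(config.recall_day_probs) + 1)

    from .config import GoldbergParams  # default cutoffs for the underreport target

    lower_cutoff = GoldbergParams().cutoffs()[0]

    recall_rows = []
    truth_rows = []
    for fam in families:
        for person in fam.members:
            z = traits[person.person_id] / sd_total
            h = _healthy_share(z)
            e_ref = _reference_energy(person.role, person.age)
            foods = {c: by_cat[c][rng.integers(len(by_cat[c]))] for c in ALL_CATEGORIES}
            under = rng.random() < config.underreport_fraction
            n_days = int(rng.choice(n_day_choices, p=config.recall_day_probs))

            # true usual values: 5/7-2/7 day-type mixture at the person's
            # trait-driven split, with mean-one day noise
            w_true = _category_weights(h)
            kcal_per_unit = sum(
                w_true[c] * energy_density[foods[c]] for c in ALL_CATEGORIES
            )
            usual_energy = e_ref * (
                (1.0 - config.weekend_prob) + config.weekend_prob * config.weekend_effect
            )
            # total grams per 1000 kcal split h : (1-h) over the two health groups
            total_density = 1000.0 * sum(w_true.values()) / kcal_per_unit
            healthy_density = h * total_density
            unhealthy_density = (1.0 - h) * total_density

            for d in range(n_days):
                weekend = rng.random() < config.weekend_prob
                noise = (
                    math.exp(rng.normal(-0.5 * sigma_ln**2, sigma_ln))
                    if sigma_ln > 0
                    else 1.0
                )
                e_day = e_ref * (config.weekend_effect if weekend else 1.0) * noise
                if sigma_ln > 0:
                    eta = rng.normal(0.0, 0.5 * cv)
                    h_day = _sigmoid(math.log(h / (1.0 - h)) + eta)
                else:
                    h_day = h
                w = _category_weights(h_day)
                kcal_unit = sum(w[c] * energy_density[foods[c]] for c in ALL_CATEGORIES)
                scale = e_day / kcal_unit
                if under:
                    target = 0.8 * lower_cutoff * reference_bmr_kcal(person.sex, person.age)
                    if e_day > target:
                        scale *= target / e_day
                for c in ALL_CATEGORIES:
                    recall_rows.append(
                        (
                            person.person_id,
                            d,
                            "weekend" if weekend else "weekday",
                            foods[c],
                            w[c] * scale,
                            True,
                        )
                    )
            truth_rows.append(
                {
                    "person_id": person.person_id,
                    "trait": traits[person.person_id],
                    "healthy_share": h,
                    "underreport": under,
                    "n_days": n_days,
                    "energy_kcal": usual_energy,
                    "healthy_sum": healthy_density,
                    "unhealthy_sum": unhealthy_density,
                }
            )
    recalls = pd.DataFrame(
        recall_rows,
        columns=["person_id", "day_index", "day_type", "food_id", "amount_g", "complete"],
    )
    truth = pd.DataFrame(truth_rows)
    return recalls, truth


# ---------------------------------------------------------------------------
# FFQ
# ---------------------------------------------------------------------------

def simulate_ffq(
    true_usual: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    items: tuple[str, ...] = TRAIT_VARIABLES,
) -> pd.DataFrame:
    """FFQ frequency levels (codes 0-6) per person and item.

    Each item's level is a monotone discretization of a noisy copy of the
    person's true usual intake, calibrated so the Spearman correlation
    between level and usual intake is close to ``config.ffq_rank_corr``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(4)[3])
    rho = config.ffq_rank_corr
    n = len(true_usual)
    rows = []
    from scipy import stats

    for item in items:
        v = true_usual[item].to_numpy(float)
        ranks = stats.rankdata(v)
        z = stats.norm.ppf((ranks - 0.5) / n)
        if rho >= 1.0:
            latent = z
        else:
            latent = rho * z + math.sqrt(1.0 - rho**2) * rng.standard_normal(n)
        codes = np.floor(7.0 * (stats.rankdata(latent) - 0.5) / n).astype(int)
        for pid, code in zip(true_usual["person_id"], codes):
            rows.append({"person_id": pid, "item_id": item, "frequency_code": int(code)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Dataset bundle
# ---------------------------------------------------------------------------

def generate_dataset(config: SimulationConfig) -> dict[str, pd.DataFrame]:
    """Generate the full input bundle: persons, recalls, ffq, composition,
    plus the latent truth table for oracle checks."""
    from .pedigree import families_to_frame

    seqs = np.random.SeedSequence(config.seed).spawn(4)
    families = sample_family_structures(config, np.random.default_rng(seqs[0]))
    traits = simulate_latent_traits(families, config, np.random.default_rng(seqs[1]))
    composition = default_composition()
    recalls, truth = simulate_recall_days(
        families, traits, composition, config, np.random.default_rng(seqs[2])
    )
    ffq = simulate_ffq(truth, config, np.random.default_rng(seqs[3]))
    persons = families_to_frame(families)
    return {
        "persons": persons,
        "recalls": recalls,
        "ffq": ffq,
        "composition": composition,
        "truth": truth,
    }


def write_dataset(data: Mapping[str, pd.DataFrame], out_dir: str | Path,
                  config: SimulationConfig | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("persons", "recalls", "ffq", "composition", "truth"):
        data[name].to_csv(out / f"{name}.csv", index=False)
    if config is not None:
        dump_config(config, out / "simulation_config.yaml")
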