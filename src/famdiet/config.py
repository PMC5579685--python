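"""Configuration objects and reference tables for the famdiet pipeline.

Every analysis constant used anywhere in the pipeline (outlier SD cutoff,
child age split, weekend day weighting, imputation limit, food-category
thresholds, Goldberg parameters, Box-Cox grid) lives here so that nothing
is hard-coded inline in the analysis stages.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml


class ConfigurationError(ValueError):
    """Raised when a configuration object violates its invariants."""


# ---------------------------------------------------------------------------
# Reference family-type distribution.
#
# Default mix of nuclear-family compositions, taken from a large European
# multi-centre family dietary study of 1435 nuclear families (3560
# individuals).  Keys are (parents-present, number of children); values are
# family counts.  "both" = mother and father both participate; "none" =
# sibling-only families with no participating parent.
# ---------------------------------------------------------------------------
STUDY_FAMILY_TYPE_COUNTS: dict[tuple[str, int], int] = {
    ("mother", 1): 536,
    ("mother", 2): 195,
    ("mother", 3): 10,
    ("mother", 4): 2,
    ("father", 1): 129,
    ("father", 2): 38,
    ("father", 3): 6,
    ("father", 4): 1,
    ("both", 1): 154,
    ("both", 2): 89,
    ("both", 3): 18,
    ("both", 4): 3,
    ("none", 2): 236,
    ("none", 3): 18,
}

#: Family counts per study country (same study; used only as a covariate mix).
STUDY_COUNTRY_COUNTS: dict[str, int] = {
    "IT": 277, "EE": 229, "CY": 137, "BE": 67,
    "SE": 300, "DE": 262, "HU": 107, "ES": 56,
}

#: Share of persons with 1, 2, 3 and 4 recall days.
RECALL_DAY_MIX: tuple[float, ...] = (0.46, 0.25, 0.26, 0.03)


def family_type_probs_from_counts(
    counts: Mapping[tuple[str, int], int],
) -> dict[tuple[str, int], float]:
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


def family_type_size(family_type: tuple[str, int]) -> int:
    parents, n_children = family_type
    n_parents = {"mother": 1, "father": 1, "both": 2, "none": 0}[parents]
    return n_parents + n_children


@dataclass
class SimulationConfig:
    """Parameters of the synthetic nuclear-family dietary data generator.

    The defaults reproduce the study conditions of the reference family
    sample: the family-type mix above, parent ages uniform on 25-65 and
    child ages on 2-19 (integer years), a familial trait built from additive
    genetic + shared household + unique components, 1-4 recall days per
    person in a 46/25/26/3 mix, multiplicative day-to-day noise with a
    weekend effect, and a fraction of energy under-reporters.
    """

    n_families: int = 1435
    family_type_probs: dict[tuple[str, int], float] = field(
        default_factory=lambda: family_type_probs_from_counts(STUDY_FAMILY_TYPE_COUNTS)
    )
    country_probs: dict[str, float] = field(
        default_factory=lambda: {
            k: v / sum(STUDY_COUNTRY_COUNTS.values())
            for k, v in STUDY_COUNTRY_COUNTS.items()
        }
    )
    sigma2_g: float = 0.40      # additive genetic variance
    sigma2_c: float = 0.21      # shared household variance
    sigma2_e: float = 0.39      # unique environment variance
    spouse_trait_corr: float = 0.0   # assortative-mating option; 0 = none
    recall_day_probs: tuple[float, ...] = RECALL_DAY_MIX
    within_person_cv: float = 0.30   # day-to-day CV of intake
    weekend_effect: float = 1.10     # multiplicative weekend factor
    weekend_prob: float = 2.0 / 7.0  # calendar share of weekend days
    underreport_fraction: float = 0.20
    ffq_rank_corr: float = 0.60      # target Spearman(FFQ level, usual intake)
    parent_age_range: tuple[int, int] = (25, 65)
    child_age_range: tuple[int, int] = (2, 19)
    seed: int = 0

    def validate(self) -> None:
        p = sum(self.family_type_probs.values())
        if abs(p - 1.0) > 1e-8 or any(v < 0 for v in self.family_type_probs.values()):
            raise ConfigurationError(
                f"family_type_probs must be a probability vector (sum={p!r})"
            )
        for name in ("sigma2_g", "sigma2_c", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if not 0.0 <= self.spouse_trait_corr < 1.0:
            raise ConfigurationError("spouse_trait_corr must be in [0, 1)")
        if abs(sum(self.recall_day_probs) - 1.0) > 1e-8:
            raise ConfigurationError("recall_day_probs must sum to 1")
        if not 0.0 <= self.underreport_fraction <= 1.0:
            raise ConfigurationError("underreport_fraction must be in [0, 1]")
        if self.within_person_cv < 0:
            raise ConfigurationError("within_person_cv must be non-negative")

    @property
    def total_variance(self) -> float:
        return self.sigma2_g + self.sigma2_c + self.sigma2_e


@dataclass
class GoldbergParams:
    """Goldberg energy-misreporting screen parameters.

    The screen compares the ratio of reported energy intake to basal
    metabolic rate (EI/BMR) against plausibility bounds
    ``PAL * exp(+/- multiplier * S)`` where ``S`` combines the component
    coefficients of variation for a record of ``n_days`` days:
    ``S = sqrt(cv_within**2 / n_days + cv_bmr**2 + cv_pal**2) / 100``.
    BMR comes from Schofield-type weight equations evaluated at shipped
    age- and sex-specific reference weights, so no measured weight is
    required. All constants are conventional defaults and configurable.
    """

    pal: float = 1.55
    cv_within: float = 23.0   # within-person CV of energy intake, percent
    cv_bmr: float = 8.5       # CV of BMR estimation, percent
    cv_pal: float = 15.0      # CV of PAL, percent
    multiplier: float = 1.96
    n_days: int = 1

    def s_factor(self) -> float:
        return (
            (self.cv_within**2 / self.n_days + self.cv_bmr**2 + self.cv_pal**2) ** 0.5
            / 100.0
        )

    def cutoffs(self) -> tuple[float, float]:
        import math

        s = self.s_factor()
        lo = self.pal * math.exp(-self.multiplier * s)
        hi = self.pal * math.exp(self.multiplier * s)
        if not lo < self.pal < hi:
            raise ConfigurationError("Goldberg cutoffs must bracket the PAL")
        return lo, hi


@dataclass
class AnalysisConfig:
    """Constants of the statistical analysis stages."""

    outlier_sd: float = 3.0            # exclude |x - mean| > k*SD within group
    skewness_threshold: float = 1.0    # log-transform if skewness exceeds this
    stepwise_entry_p: float = 0.05     # forward-entry p for age polynomial terms
    age_cutoff: int = 11               # children < cutoff are "younger"
    max_imputed: int = 4               # recalls with more imputed items excluded
    weekday_weight: float = 5.0 / 7.0  # usual-intake day-type weighting
    weekend_weight: float = 2.0 / 7.0
    boxcox_grid: tuple[float, ...] = (-1.0, -0.5, 0.0, 1.0 / 3.0, 0.5, 1.0)
    child_age_group_edges: tuple[int, ...] = (2, 6, 9, 12, 15, 20)
    goldberg: GoldbergParams = field(default_factory=GoldbergParams)
    ci_level: float = 0.95
    ci_method: str = "profile"         # or "delta"
    seed: int = 0


@dataclass
class PipelineConfig:
    """Top-level configuration: where to read/write plus stage parameters."""

    out_dir: str = "famdiet_out"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    simulate: bool = True              # generate inputs rather than read them
    input_dir: str | None = None       # used when simulate is False


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {
            ("|".join(map(str, k)) if isinstance(k, tuple) else k): _to_plain(v)
            for k, v in obj.items()
        }
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def dump_config(config, path: str | Path) -> None:
    """Write a config dataclass to YAML (tuple keys flattened with '|')."""
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=False))


def _parse_family_type_key(key: str) -> tuple[str, int]:
    parents, n = key.split("|")
    return parents, int(n)


def load_simulation_config(path: str | Path) -> SimulationConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if "family_type_probs" in raw:
        raw["family_type_probs"] = {
            _parse_family_type_key(k): v for k, v in raw["family_type_probs"].items()
        }
    for name in ("recall_day_probs", "parent_age_range", "child_age_range"):
        if name in raw:
            raw[name] = tuple(raw[name])
    cfg = SimulationConfig(**raw)
    cfg.validate()
    return cfg


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    sim = raw.pop("simulation", None)
    ana = raw.pop("analysis", None)
    cfg = PipelineConfig(**raw)
    if sim is not None:
        if "family_type_probs" in sim:
            sim["family_type_probs"] = {
                _parse_family_type_key(k): v
                for k, v in sim["family_type_probs"].items()
            }
        for name in ("recall_day_probs", "parent_age_range", "child_age_range"):
            if name in sim:
                sim[name] = tuple(sim[name])
        cfg.simulation = SimulationConfig(**sim)
    if ana is not None:
        gold = ana.pop("goldberg", None)
        for name in ("boxcox_grid", "child_age_group_edges"):
            if name in ana:
                ana[name] = tuple(ana[name])
        cfg.analysis = AnalysisConfig(**ana)
        if gold is not None:
            cfg.analysis.goldberg = GoldbergParams(**gold)
    return cfg


def model_params_to_json(params: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_to_plain(dict(params)), indent=2, default=float))
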