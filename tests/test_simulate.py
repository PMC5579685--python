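import numpy as np
import pandas as pd
import pytest
from scipy import stats

from famdiet.config import (
    ConfigurationError,
    SimulationConfig,
    STUDY_FAMILY_TYPE_COUNTS,
    family_type_probs_from_counts,
    family_type_size,
)
from famdiet.foods import person_day_table
from famdiet.intake import goldberg_classify
from famdiet.simulate import (
    default_composition,
    generate_dataset,
    sample_family_structures,
    simulate_ffq,
    simulate_latent_traits,
    simulate_recall_days,
)


def pair_corr(fams, traits, main_type):
    a, b = [], []
    from famdiet.pedigree import enumerate_relative_pairs

    for fam in fams:
        for p in enumerate_relative_pairs(fam):
            if p.main_type == main_type:
                a.append(traits[p.person_a.person_id])
                b.append(traits[p.person_b.person_id])
    return float(np.corrcoef(a, b)[0, 1]), len(a)


class TestFamilyStructures:
    def test_point_mass_distribution(self):
        cfg = SimulationConfig(
            n_families=10, family_type_probs={("mother", 1): 1.0}, seed=1
        )
        fams = sample_family_structures(cfg)
        assert len(fams) == 10
        assert all(f.size == 2 for f in fams)
        assert all(f.family_type == ("mother", 1) for f in fams)

    def test_empty_request(self):
        cfg = SimulationConfig(n_families=0, seed=1)
        assert sample_family_structures(cfg) == []

    def test_invalid_probability_vector_rejected(self):
        cfg = SimulationConfig(family_type_probs={("mother", 1): 0.5})
        with pytest.raises(ConfigurationError, match="probability"):
            cfg.validate()

    def test_mean_family_size_matches_expectation(self):
        probs = family_type_probs_from_counts(STUDY_FAMILY_TYPE_COUNTS)
        expected = sum(p * family_type_size(t) for t, p in probs.items())
        cfg = SimulationConfig(n_families=1435, seed=2)
        fams = sample_family_structures(cfg)
        mean_size = np.mean([f.size for f in fams])
        assert abs(mean_size - expected) < 0.1
        assert abs(expected - 2.48) < 0.01  # sanity on the reference table

    def test_ages_in_range_and_one_household(self):
        cfg = SimulationConfig(n_families=200, seed=3)
        for fam in sample_family_structures(cfg):
            assert len({m.household_id for m in fam.members}) == 1
            for m in fam.members:
                lo, hi = (2, 19) if m.role == "child" else (25, 65)
                assert lo <= m.age <= hi

    def test_family_type_frequencies_match_probabilities(self, big_sim):
        cfg, fams, _ = big_sim
        counts = {}
        for f in fams:
            counts[f.family_type] = counts.get(f.family_type, 0) + 1
        types = list(cfg.family_type_probs)
        observed = np.array([counts.get(t, 0) for t in types])
        expected = np.array([cfg.family_type_probs[t] * len(fams) for t in types])
        stat, p = stats.chisquare(observed, expected)
        assert p > 0.001

    def test_seed_reproducibility(self):
        cfg = SimulationConfig(n_families=50, seed=9)
        a = sample_family_structures(cfg)
        b = sample_family_structures(cfg)
        assert [(m.person_id, m.age, m.sex) for f in a for m in f.members] == [
            (m.person_id, m.age, m.sex) for f in b for m in f.members
        ]


class TestLatentTraits:
    def test_pure_unique_component_uncorrelated(self):
        cfg = SimulationConfig(
            n_families=10_000, sigma2_g=0.0, sigma2_c=0.0, sigma2_e=1.0, seed=4
        )
        fams = sample_family_structures(cfg)
        traits = simulate_latent_traits(fams, cfg)
        for main in ("parent_offspring", "sibling", "spouse"):
            r, _ = pair_corr(fams, traits, main)
            assert abs(r) < 0.05

    def test_pure_household_makes_members_identical(self):
        cfg = SimulationConfig(
            n_families=100, sigma2_g=0.0, sigma2_c=1.0, sigma2_e=0.0, seed=5
        )
        fams = sample_family_structures(cfg)
        traits = simulate_latent_traits(fams, cfg)
        for fam in fams:
            vals = [traits[m.person_id] for m in fam.members]
            assert np.ptp(vals) < 1e-12

    def test_pair_covariances_match_generating_model(self, big_sim):
        """Parent-offspring and sibling cov -> 0.5*s2g + s2c; spouse -> s2c
        (within 3 Monte Carlo SEs at 10^4 families)."""
        cfg, fams, traits = big_sim
        expect = {
            "parent_offspring": 0.5 * cfg.sigma2_g + cfg.sigma2_c,
            "sibling": 0.5 * cfg.sigma2_g + cfg.sigma2_c,
            "spouse": cfg.sigma2_c,
        }
        total = cfg.total_variance
        for main, exp_cov in expect.items():
            r, n = pair_corr(fams, traits, main)
            rho = exp_cov / total
            mc_se = (1 - rho**2) / np.sqrt(n)
            assert abs(r - rho) < 3 * mc_se, (main, r, rho, n)

    def test_negative_variance_rejected(self):
        cfg = SimulationConfig(sigma2_g=-0.1)
        with pytest.raises(ConfigurationError, match="sigma2_g"):
            cfg.validate()

    def test_spouse_correlation_option(self):
        cfg = SimulationConfig(
            n_families=4000, sigma2_g=1.0, sigma2_c=0.0, sigma2_e=0.0,
            spouse_trait_corr=0.5, seed=6,
        )
        fams = sample_family_structures(cfg)
        traits = simulate_latent_traits(fams, cfg)
        r, n = pair_corr(fams, traits, "spouse")
        assert abs(r - 0.5) < 3 / np.sqrt(n) + 0.05


class TestRecallDays:
    def _small(self, **kw):
        cfg = SimulationConfig(n_families=60, seed=7, **kw)
        fams = sample_family_structures(cfg)
        traits = simulate_latent_traits(fams, cfg)
        comp = default_composition()
        recalls, truth = simulate_recall_days(fams, traits, comp, cfg)
        return cfg, fams, comp, recalls, truth

    def test_noise_free_days_equal_usual_intake(self):
        cfg, fams, comp, recalls, truth = self._small(
            within_person_cv=0.0, weekend_effect=1.0, underreport_fraction=0.0
        )
        days = person_day_table(recalls, comp)
        merged = days.merge(truth, on="person_id", suffixes=("", "_true"))
        assert np.allclose(merged["energy_kcal"], merged["energy_kcal_true"])
        assert np.allclose(merged["healthy_sum"], merged["healthy_sum_true"])

    def test_all_underreporters_flagged_downstream(self):
        cfg, fams, comp, recalls, truth = self._small(underreport_fraction=1.0)
        days = person_day_table(recalls, comp)
        info = {m.person_id: m for fam in fams for m in fam.members}
        for row in days.itertuples(index=False):
            m = info[row.person_id]
            assert goldberg_classify(row.energy_kcal, m.sex, m.age) == "under"

    def test_day_count_availability_mix(self):
        cfg = SimulationConfig(n_families=4000, seed=8)
        fams = sample_family_structures(cfg)
        traits = simulate_latent_traits(fams, cfg)
        recalls, truth = simulate_recall_days(fams, traits, default_composition(), cfg)
        frac3 = float((truth["n_days"] == 3).mean())
        assert abs(frac3 - 0.26) < 0.01
        counts = recalls.groupby("person_id")["day_index"].nunique()
        assert counts.min() >= 1 and counts.max() <= 4

    def test_empty_composition_rejected(self):
        cfg = SimulationConfig(n_families=5, seed=9)
        fams = sample_family_structures(cfg)
        traits = simulate_latent_traits(fams, cfg)
        with pytest.raises(ConfigurationError, match="composition"):
            simulate_recall_days(fams, traits, default_composition().iloc[:0], cfg)

    def test_healthy_split_follows_trait(self):
        """Persons with higher latent traits eat relatively more healthy
        food in their generated recalls."""
        cfg, fams, comp, recalls, truth = self._small(underreport_fraction=0.0)
        days = person_day_table(recalls, comp)
        share = days.groupby("person_id").apply(
            lambda g: (g["healthy_sum"] / (g["healthy_sum"] + g["unhealthy_sum"])).mean(),
            include_groups=False,
        )
        merged = truth.set_index("person_id").join(share.rename("obs_share"))
        rho = stats.spearmanr(merged["trait"], merged["obs_share"]).statistic
        assert rho > 0.8


class TestFFQ:
    def test_noise_free_is_deterministic_monotone_binning(self):
        truth = pd.DataFrame(
            {"person_id": [f"p{i}" for i in range(700)],
             "energy_kcal": np.linspace(1000, 3000, 700)}
        )
        cfg = SimulationConfig(ffq_rank_corr=1.0, seed=1)
        ffq = simulate_ffq(truth, cfg, items=("energy_kcal",))
        codes = ffq["frequency_code"].to_numpy()
        assert np.all(np.diff(codes) >= 0)  # monotone in usual intake
        assert set(codes) == set(range(7))

    def test_permuted_intakes_give_zero_rank_correlation(self, rng):
        values = rng.lognormal(7, 0.5, 2000)
        truth = pd.DataFrame(
            {"person_id": [f"p{i}" for i in range(2000)], "energy_kcal": values}
        )
        cfg = SimulationConfig(ffq_rank_corr=0.6, seed=2)
        ffq = simulate_ffq(truth, cfg, items=("energy_kcal",))
        permuted = rng.permutation(values)
        rho = stats.spearmanr(ffq["frequency_code"], permuted).statistic
        assert abs(rho) < 0.06

    def test_default_noise_hits_configured_rank_correlation(self):
        rng = np.random.default_rng(11)
        truth = pd.DataFrame(
            {"person_id": [f"p{i}" for i in range(2000)],
             "energy_kcal": rng.lognormal(7, 0.5, 2000)}
        )
        cfg = SimulationConfig(ffq_rank_corr=0.6, seed=3)
        ffq = simulate_ffq(truth, cfg, items=("energy_kcal",))
        rho = stats.spearmanr(
            ffq["frequency_code"], truth["energy_kcal"]
        ).statistic
        assert abs(rho - 0.6) < 0.05


class TestDatasetBundle:
    def test_fixed_seed_reproduces_every_table(self):
        cfg = SimulationConfig(n_families=40, seed=123)
        a = generate_dataset(cfg)
        b = generate_dataset(cfg)
        for name in a:
            pd.testing.assert_frame_equal(a[name], b[name])

    def test_roundtrip_to_disk(self, tmp_path):
        from famdiet.simulate import write_dataset

        cfg = SimulationConfig(n_families=10, seed=5)
        data = generate_dataset(cfg)
        write_dataset(data, tmp_path, cfg)
        for name in ("persons", "recalls", "ffq", "composition", "truth"):
            assert (tmp_path / f"{name}.csv").exists()
        assert (tmp_path / "simulation_config.yaml").exists()
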