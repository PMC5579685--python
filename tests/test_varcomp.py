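import numpy as np
import pandas as pd
import pytest
from scipy import stats

from famdiet.config import SimulationConfig
from famdiet.simulate import sample_family_structures, simulate_latent_traits
from famdiet.varcomp import (
    FamilyTraitData,
    VarCompError,
    family_covariance,
    familiality_ci,
    fit_variance_components,
    log_likelihood,
)

from conftest import make_family, random_family


def random_traits(fams, rng):
    return pd.Series(
        {m.person_id: rng.standard_normal() for f in fams for m in f.members}
    )


class TestFamilyCovariance:
    def test_pure_error_is_identity(self, trio):
        assert np.allclose(family_covariance(trio, (0, 0, 1)), np.eye(3))

    def test_trio_entries(self, trio):
        sigma = family_covariance(trio, (0.4, 0.2, 0.4))
        # members ordered mother, father, child
        assert sigma[0, 1] == pytest.approx(0.2)          # spouse
        assert sigma[0, 2] == pytest.approx(0.4)          # 0.5*0.4 + 0.2
        assert np.allclose(np.diag(sigma), 1.0)

    def test_matches_per_entry_bruteforce(self, rng):
        from famdiet.pedigree import kinship_and_household

        for i in range(50):
            fam = random_family(f"r{i}", rng)
            comps = rng.uniform(0.05, 1.0, 3)
            sigma = family_covariance(fam, tuple(comps))
            phi2, hh = kinship_and_household(fam)
            k = len(fam.members)
            for a in range(k):
                for b in range(k):
                    expect = (
                        comps[0] * phi2[a, b]
                        + comps[1] * hh[a, b]
                        + (comps[2] if a == b else 0.0)
                    )
                    assert sigma[a, b] == pytest.approx(expect, abs=1e-12)

    def test_negative_component_rejected(self, trio):
        with pytest.raises(VarCompError):
            family_covariance(trio, (-0.1, 0.2, 0.9))


class TestLogLikelihood:
    def test_pure_error_equals_sum_of_univariate_densities(self, rng):
        fams = [random_family(f"r{i}", rng) for i in range(20)]
        traits = random_traits(fams, rng)
        data = FamilyTraitData.from_families(fams, traits)
        ll = log_likelihood((0.0, 0.0, 1.0), data)
        expect = stats.norm.logpdf(traits.to_numpy()).sum()
        assert ll == pytest.approx(expect, abs=1e-10)

    def test_duplicating_data_doubles_loglik(self, rng):
        fams = [random_family(f"r{i}", rng) for i in range(10)]
        traits = random_traits(fams, rng)
        data1 = FamilyTraitData.from_families(fams, traits)
        fams2 = fams + [
            make_family(f"c{i}", [(m.role, m.sex, m.age) for m in f.members])
            for i, f in enumerate(fams)
        ]
        traits2 = dict(traits)
        for i, f in enumerate(fams):
            for j, m in enumerate(f.members):
                traits2[f"c{i}.{j}"] = traits[m.person_id]
        data2 = FamilyTraitData.from_families(fams2, traits2)
        comps = (0.3, 0.25, 0.45)
        assert log_likelihood(comps, data2) == pytest.approx(
            2 * log_likelihood(comps, data1), rel=1e-12
        )

    def test_matches_generic_mvn_density(self, rng):
        """Against scipy's multivariate normal on 100 random families."""
        for i in range(100):
            fam = random_family(f"r{i}", rng)
            y = rng.standard_normal(len(fam.members))
            traits = {m.person_id: y[j] for j, m in enumerate(fam.members)}
            data = FamilyTraitData.from_families([fam], traits)
            comps = tuple(rng.uniform(0.05, 0.8, 3))
            sigma = family_covariance(fam, comps)
            expect = stats.multivariate_normal.logpdf(
                y, mean=np.zeros(len(y)), cov=sigma
            )
            assert log_likelihood(comps, data) == pytest.approx(expect, abs=1e-10)

    def test_missing_members_dropped(self, trio, rng):
        traits = {"T.0": 0.5, "T.2": -0.3}  # father unobserved
        data = FamilyTraitData.from_families([trio], traits)
        comps = (0.4, 0.2, 0.4)
        sigma = family_covariance(trio, comps)[np.ix_([0, 2], [0, 2])]
        expect = stats.multivariate_normal.logpdf([0.5, -0.3], cov=sigma)
        assert log_likelihood(comps, data) == pytest.approx(expect, abs=1e-10)


class TestFit:
    def test_null_model_recovered(self):
        cfg = SimulationConfig(n_families=800, sigma2_g=0, sigma2_c=0,
                               sigma2_e=1.0, seed=21)
        fams = sample_family_structures(cfg)
        traits = simulate_latent_traits(fams, cfg)
        fit = fit_variance_components(fams, traits, ci=False)
        assert fit.familiality <= 0.05

    def test_moderate_scale_recovery(self):
        cfg = SimulationConfig(n_families=2000, seed=22)  # (0.40, 0.21, 0.39)
        fams = sample_family_structures(cfg)
        traits = simulate_latent_traits(fams, cfg)
        fit = fit_variance_components(fams, traits, ci=False)
        assert fit.familiality == pytest.approx(0.61, abs=0.12)
        assert fit.total == pytest.approx(1.0, abs=0.1)

    def test_spouse_only_data_puts_genetic_at_boundary(self, rng):
        """Spouses share household but no kinship, so sigma2_g has no
        signal and must be reported at 0, with sigma2_c near the
        generating share."""
        L = np.linalg.cholesky([[1.0, 0.3], [0.3, 1.0]])
        fams, traits = [], {}
        for i in range(600):
            fam = make_family(f"s{i}", [("mother", "F", 40), ("father", "M", 42)])
            fams.append(fam)
            y = rng.standard_normal(2) @ L.T
            traits[f"s{i}.0"], traits[f"s{i}.1"] = y
        fit = fit_variance_components(fams, traits, ci=False)
        assert fit.sigma2_g == 0.0
        assert fit.sigma2_c == pytest.approx(0.3, abs=0.08)

    def test_ridge_detected_without_spouse_pairs(self, rng):
        """Single-parent families only: g and c are confounded; the fit
        must flag the ridge and report the reduced familial model."""
        cfg = SimulationConfig(
            n_families=400,
            family_type_probs={("mother", 1): 0.6, ("mother", 2): 0.4},
            seed=23,
        )
        fams = sample_family_structures(cfg)
        traits = simulate_latent_traits(fams, cfg)
        fit = fit_variance_components(fams, traits, ci=False)
        assert fit.ridge
        assert fit.model == "fe"
        # familial share ~ 0.5*s2g + s2c = 0.41 of total 1.0
        assert fit.familiality == pytest.approx(0.41, abs=0.1)

    def test_familiality_invariant_to_trait_rescaling(self):
        cfg = SimulationConfig(n_families=500, seed=24)
        fams = sample_family_structures(cfg)
        traits = simulate_latent_traits(fams, cfg)
        f1 = fit_variance_components(fams, traits, ci=False).familiality
        f2 = fit_variance_components(fams, traits * 3.0, ci=False).familiality
        assert f1 == pytest.approx(f2, abs=1e-4)

    def test_solution_is_local_maximum(self):
        cfg = SimulationConfig(n_families=400, seed=25)
        fams = sample_family_structures(cfg)
        traits = simulate_latent_traits(fams, cfg)
        fit = fit_variance_components(fams, traits, ci=False)
        data = FamilyTraitData.from_families(fams, traits)
        base = log_likelihood((fit.sigma2_g, fit.sigma2_c, fit.sigma2_e), data)
        h = 1e-4
        for j in range(3):
            comps = [fit.sigma2_g, fit.sigma2_c, fit.sigma2_e]
            if comps[j] < h:  # boundary component: only inward moves exist
                comps[j] += h
                assert log_likelihood(tuple(comps), data) <= base + 1e-6
                continue
            up, dn = comps.copy(), comps.copy()
            up[j] += h
            dn[j] -= h
            grad = (log_likelihood(tuple(up), data) -
                    log_likelihood(tuple(dn), data)) / (2 * h)
            assert abs(grad * comps[j]) < 0.05  # ~zero gradient in log-scale units

    def test_reduced_model_option(self):
        cfg = SimulationConfig(n_families=400, seed=26)
        fams = sample_family_structures(cfg)
        traits = simulate_latent_traits(fams, cfg)
        fit = fit_variance_components(fams, traits, model="fe", ci=False)
        assert fit.model == "fe" and fit.sigma2_g == 0.0
        assert 0.0 <= fit.familiality <= 1.0

    def test_few_families_warns(self, rng):
        fams = [random_family(f"r{i}", rng) for i in range(10)]
        traits = random_traits(fams, rng)
        with pytest.warns(UserWarning, match="families"):
            fit_variance_components(fams, traits, ci=False)


class TestFamilialityCI:
    def test_ci_narrows_with_sample_size(self):
        widths = []
        for n in (300, 3000):
            cfg = SimulationConfig(n_families=n, seed=27)
            fams = sample_family_structures(cfg)
            traits = simulate_latent_traits(fams, cfg)
            fit = fit_variance_components(fams, traits)
            widths.append(fit.ci[1] - fit.ci[0])
        assert widths[1] < widths[0]

    def test_boundary_F_zero_gives_lo_zero(self):
        cfg = SimulationConfig(n_families=400, sigma2_g=0, sigma2_c=0,
                               sigma2_e=1.0, seed=28)
        fams = sample_family_structures(cfg)
        traits = simulate_latent_traits(fams, cfg)
        fit = fit_variance_components(fams, traits)
        assert fit.ci[0] == 0.0
        assert fit.ci[1] < 0.2

    def test_profile_and_delta_agree_away_from_boundary(self):
        cfg = SimulationConfig(n_families=1500, seed=29)
        fams = sample_family_structures(cfg)
        traits = simulate_latent_traits(fams, cfg)
        fit = fit_variance_components(fams, traits, ci_method="profile")
        data = FamilyTraitData.from_families(fams, traits)
        lo_d, hi_d = familiality_ci(data, fit, method="delta")
        lo_p, hi_p = fit.ci
        assert lo_p == pytest.approx(lo_d, abs=0.04)
        assert hi_p == pytest.approx(hi_d, abs=0.04)


class TestStratified:
    def test_all_children_younger_raises_for_older_stratum(self):
        from famdiet.varcomp import stratified_familiality

        fams = [
            make_family(f"f{i}", [("mother", "F", 40), ("child", "F", 5),
                                  ("child", "M", 7)])
            for i in range(60)
        ]
        traits = pd.Series(
            {m.person_id: 0.1 * i for i, m in
             enumerate(m for f in fams for m in f.members)}
        )
        with pytest.raises(VarCompError, match="older"):
            stratified_familiality(fams, traits)

    def test_distinct_strata_recovered(self):
        """Generate younger-child families with high familiality and
        older-child families with low: the recovered difference is
        positive."""
        from famdiet.varcomp import stratified_familiality

        diffs = []
        for seed in range(3):
            fams_all, traits_all = [], {}
            for stratum, (s2f, ages) in {
                "y": (0.71, (2, 10)), "o": (0.48, (11, 19)),
            }.items():
                cfg = SimulationConfig(
                    n_families=700,
                    sigma2_g=0.0, sigma2_c=s2f, sigma2_e=1 - s2f,
                    child_age_range=ages, seed=100 + seed,
                )
                fams = sample_family_structures(cfg)
                fams = [
                    make_family(f"{stratum}{f.family_id}",
                                [(m.role, m.sex, m.age) for m in f.members])
                    for f in fams
                ]
                traits = simulate_latent_traits(fams, cfg)
                fams_all.extend(fams)
                traits_all.update(traits)
            out = stratified_familiality(fams_all, pd.Series(traits_all))
            diffs.append(out["younger"].familiality - out["older"].familiality)
        assert all(d > 0 for d in diffs)

    def test_identical_strata_rarely_flag_nonoverlap(self):
        from famdiet.varcomp import stratified_familiality

        flags = []
        for seed in range(5):
            cfg = SimulationConfig(n_families=800, seed=300 + seed)
            fams = sample_family_structures(cfg)
            traits = simulate_latent_traits(fams, cfg)
            out = stratified_familiality(fams, traits)
            flags.append(out["nonoverlap"])
        assert sum(flags) <= 1
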