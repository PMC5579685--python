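"""Familial correlations by relative-pair subtype, with homogeneity tests
and Fisher-z comparisons between groups.
"""
import numpy as np

from famdiet import (
    SimulationConfig,
    compare_independent,
    fisher_ci,
    sample_family_structures,
    simulate_latent_traits,
)
from famdiet.correlations import (
    interclass_correlation,
    intraclass_correlation,
)
from famdiet.pedigree import enumerate_relative_pairs

config = SimulationConfig(n_families=2000, seed=3)   # (g, c, e) = (0.40, 0.21, 0.39)
families = sample_family_structures(config)
traits = simulate_latent_traits(families, config)

pairs = {}
for fam in families:
    for p in enumerate_relative_pairs(fam):
        pairs.setdefault(p.subtype, []).append(
            (traits[p.person_a.person_id], traits[p.person_b.person_id])
        )

print("subtype            r       95% CI          n   (expected 0.41 rel / 0.21 spouse)")
for subtype, vals in sorted(pairs.items()):
    arr = np.array(vals)
    est = (intraclass_correlation if subtype in ("sister-sister", "brother-brother")
           else interclass_correlation)(arr, subtype)
    lo, hi = fisher_ci(est.r, est.n_pairs)
    print(f"{subtype:<18} {est.r:+.3f}  ({lo:+.3f}, {hi:+.3f})  {est.n_pairs:4d}")

md = np.array(pairs["mother-daughter"])
mf = np.array(pairs["mother-father"])
r1 = interclass_correlation(md).r
r2 = interclass_correlation(mf).r
res = compare_independent(r1, len(md), r2, len(mf))
print(f"\nmother-daughter vs spouse: z = {res.statistic:.2f}, p = {res.p:.3f}")
print("Relative pairs share genes (r ~ 0.5*s2_g + s2_c = 0.41) while spouses")
print("share only the household (r ~ s2_c = 0.21); the z test quantifies that gap.")
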