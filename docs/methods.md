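# Methods

This note documents the statistical models behind famdiet, the choices
made where the design was genuinely open, and what the synthetic-data
generator does and does not emulate.

## The familial model

Each person's prepared dietary trait (a standardized residual, see
"Trait preparation") is modelled as

    y = g + c + e,

with additive genetic value `g`, shared-household value `c`, and unique
environment `e` (which also absorbs measurement error). Within a nuclear
family the implied covariance is

    Σ_f = 2Φ σ²_g + H σ²_c + I σ²_e,

where the kinship matrix 2Φ has 1 on the diagonal, 0.5 for
parent–offspring and full-sibling entries, and 0 for spouses (random
mating for the trait), and the household matrix H is all ones (everyone
co-resides). **Familiality** is

    F = (σ²_g + σ²_c) / (σ²_g + σ²_c + σ²_e),

the share of phenotypic variance attributable to everything family
members share. With nuclear families only, genetic and household sources
cannot be separated substantively; F is the quantity of interest and the
σ²_g/σ²_c split is reported but weakly identified (the only contrast is
the spouse pair, which shares H but not Φ). F is *not* a heritability in
the twin/GWAS sense.

Identifiability edge cases the fit detects explicitly:

- **No spouse pairs at all** (no family with both parents): the
  likelihood is flat along 0.5σ²_g + σ²_c = const. The fit flags this
  ridge and reports the reduced familial model Σ = σ²_f H + σ²_e I
  instead of an arbitrary split.
- **No genetically related pairs** (spouse-only data): σ²_g appears only
  on the diagonal and is confounded with σ²_e; it is pinned at 0 with a
  message.

### Estimation

Maximum likelihood, with families independent and members missing a trait
value dropped from their family's block. Families sharing an identical
(2Φ, H) structure are grouped so each likelihood evaluation does one
Cholesky per distinct structure with the data stacked. Non-negativity is
enforced by a softplus reparameterization; optimization is multi-start
(3 starts) L-BFGS-B, followed by explicit refits with near-zero
components pinned at the 0 boundary (the boundary solution is kept
whenever its likelihood is not worse). Convergence tolerance is 1e-12 on
the relative objective.

The familiality CI is profile likelihood by default: the model is
reparameterized as (F, a, v) with σ²_g = aFv, σ²_c = (1−a)Fv,
σ²_e = (1−F)v, the inner (a, v) maximization done by bounded
quasi-Newton with warm starts, and the F bounds located by Brent root
finding on the profile deviance at the χ²₁ 95% cutoff. If the profile
fails to bracket, a delta-method CI on the logit of F is substituted with
a warning. At a boundary estimate F = 0 the lower limit is 0 by
construction.

Age-stratified familiality refits the model on stratum-specific family
structures: both parents plus only the children of the age band
(< 11 / ≥ 11 years by default); families losing all children drop out of
that stratum. The "non-overlap" flag compares the two profile CIs.

### Precision of F in this design

In the default family mix only ~18% of families include both parents, so
σ²_c is informed by roughly 260 spouse pairs per 1435 families and F
behaves approximately like 2·r_relatives − r_spouse. Its sampling SD at
the default generating values (0.40, 0.21, 0.39) is ≈ 0.05–0.06 and the
honest 95% CI width is ≈ 0.21 — materially wider than CIs obtained on
real cohort data with more informative structures. Parameter-recovery
tests therefore check unbiasedness (mean F̂ near 0.61) rather than
per-replicate pinpoint accuracy.

## Familial correlations

Interclass correlations (parent–offspring, spouse, opposite-sex sibling
pairs) are product-moment correlations over ordered pairs (parent first;
mother first for spouses; sister first for brother–sister pairs).
Same-sex sibling pairs are exchangeable and use double entry: each dyad
enters in both orders, making the Pearson formula an intraclass
estimator; on balanced data it matches the one-way ANOVA ICC up to the
usual finite-sample factor, which the tests verify against an independent
ANOVA oracle.

SEs and CIs use Fisher's r-to-z transform with variance 1/(n−3), n
counting distinct dyads. These SEs treat pairs as independent, ignoring
that a parent appears in one pair per child; `family_bootstrap_se`
(resampling whole families) is provided for when that dependence matters.
The subtype homogeneity test is the weighted Fisher-z chi-square
Σ wᵢ(zᵢ − z̄_w)² with wᵢ = nᵢ−3 and k−1 degrees of freedom. Comparisons
between independent groups use the standard z on the Fisher scale;
comparisons of two dependent, non-overlapping correlations (e.g.
parent–offspring r for healthy vs unhealthy foods on the same dyads) use
a Pearson–Filon-type z whose covariance kernel is validated in the tests
against a simulation oracle and by its exact reduction to the independent
test when all cross-correlations vanish. p-values are reported to 3
decimals and are never adjusted for multiple testing; read them with that
caution.

## Usual-intake model

A one-part (amount-only) measurement-error model for repeated 24-h
recalls, fitted per sex-by-generation stratum and dietary variable:

    g(Y_ij; λ) = β′x_ij + u_i + ε_ij

with Box-Cox transform g, person effect u_i ~ N(0, σ²_u), independent
day errors ε_ij ~ N(0, σ²_ε[k(i)]) whose variance is specific to the
person's age group (children [2,6), [6,9), [9,12), [12,15), [15,20);
adults one group), and covariates intercept, age, FFQ frequency code and
a weekend indicator. λ is selected from the ladder
{−1, −½, 0, ⅓, ½, 1} by profile maximum likelihood including the
transform Jacobian; given λ, β is profiled out in closed form (GLS via
the Woodbury identity) and the variances are maximized by L-BFGS-B on
the log scale, bounded below at 1e-8. Constant covariate columns (e.g.
an FFQ item that was never asked) are dropped from the design.

A person's usual intake is

    (5/7)·T(m_weekday) + (2/7)·T(m_weekend),

where m is the person's predicted transformed mean including the
empirical-Bayes u_i (shrinkage n σ²_u / (σ²_ε + n σ²_u) of the mean
residual) and T is the back-transform with second-order bias correction
g⁻¹(m) + ½σ²_ε g⁻¹''(m) (exactly exp(m + σ²_ε/2) at λ = 0). This
removes the variance inflation that day-to-day variation adds to single
recalls: predicted usual intakes are always less variable than single
days.

When every person has a single recall day, σ²_u and σ²_ε are not
separable; the model falls back to an OLS fit on the covariates
(FFQ-informed), splits the residual variance evenly, and flags reduced
identifiability.

**Misreporting screen.** Goldberg cutoffs classify each day by
EI/BMR against PAL·exp(±1.96·S), S = √(CV²_within/d + CV²_BMR +
CV²_PAL)/100 with d = 1 day and CVs 23/8.5/15%. BMR uses Schofield-type
weight equations evaluated at shipped age–sex reference weights, so no
measured weight is needed; all constants are configuration, not facts,
since the underlying method is conventionally applied with
study-specific values. The interval is closed: boundary ratios count as
plausible.

**Cleaning rules.** Missing or non-positive single-item amounts are
imputed by country × food-group × age-group medians; recalls flagged
incomplete, or with more than 4 imputed items, are excluded (4 exactly
is retained).

## Trait preparation

Within each sex-by-generation group (optionally younger/older × sex for
children): a single-pass exclusion of values more than 3 SD from the
group mean (moments from the full group; deliberately not iterated), a
log transform when sample skewness exceeds 1.0 (raising an error rather
than silently shifting non-positive values), residualization on country
indicators (always included) plus a forward-stepwise hierarchical cubic
age polynomial (entry p < 0.05; age² only after age), and
z-standardization. Forward-p entry was chosen over information criteria
as the simplest defensible reading of "stepwise"; it is configurable.
The pipeline is idempotent on its own output whenever the second pass
finds no new outliers.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
at the scale of a large European multi-centre family study:

- **Family types** from a reference distribution of 14 compositions
  (mother+1 child most common, 37.4%; mean family size 2.48, mean
  sibship 1.47), parent ages uniform 25–65, child ages uniform 2–19,
  one household per family, and a family-level country label drawn from
  an 8-country mix (a pure covariate; no country effect on traits).
- **Latent trait**: parents draw g ~ N(0, σ²_g) (optionally
  spouse-correlated for an assortative-mating scenario, default off);
  children get the mid-parent value plus N(0, σ²_g/2) so sibling and
  parent–offspring genetic correlations are exactly 0.5. Parents absent
  from the record are drawn latently, keeping sibling structure intact
  regardless of who participates. Defaults (0.40, 0.21, 0.39) give
  relative-pair correlation 0.41, spouse correlation 0.21, F = 0.61.
- **Recalls**: 1–4 days per person (46/25/26/3% mix), weekend days with
  calendar probability 2/7 and a multiplicative weekend factor (default
  1.10), mean-one lognormal day noise at CV 0.30, and per-day food
  amounts allocated so the healthy/unhealthy split follows a logistic
  function of the trait (share ≈ 0.61 at trait 0, matching observed
  healthy:unhealthy density ratios). A flagged 20% of persons have all
  days scaled below the Goldberg lower cutoff. Reference daily energies
  (mothers 1700, fathers 2250, children 1300 + 45·age kcal) anchor the
  scale.
- **FFQ**: levels 0–6 as a monotone discretization of a noisy copy of
  usual intake, calibrated to Spearman ρ ≈ 0.6.
- **Determinism**: one seed drives everything through hierarchically
  spawned substreams; a fixed seed reproduces every table byte for byte.

What it does **not** emulate — and hence what passing tests do not show
about real data: seasonality, country-specific food supplies, real FFQ
item lists, energy-intake familial aggregation (only the diet-quality
trait is familial, so simulated energy correlations are null by design),
correlated misreporting within families, and selective participation.
Parameter-recovery results demonstrate the estimators, not the field
validity of any instrument.

## Problem sizes in the checks

The test-suite and the acceptance script choose problem sizes that make
Monte Carlo noise negligible relative to each assertion: 10⁴ families
for generator covariance checks, 1435 families × 100 replicates (tests)
or 30 replicates (acceptance script) for familiality recovery, 2000
null contrasts for test calibration, and 2000 persons × 3 days for
usual-intake recovery. All seeds are fixed or derived from the script's
`--seed`.

## Known limitations

- FCOR-style multivariate asymptotic SEs are not reproduced; pairwise
  Fisher SEs (plus the family bootstrap) are used instead.
- The NCI two-part model for episodically consumed foods is out of
  scope; analyzed food groups are broad enough to be consumed
  near-daily.
- Sugar thresholds are interpreted as total sugar per 100 g; added
  sugar is not distinguished.
- The genetic/household split in the variance decomposition is weakly
  identified in nuclear families; only the familial sum is stable.
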