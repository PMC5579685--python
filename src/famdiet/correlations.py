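"""Familial correlations and correlation comparisons.

Interclass correlations (parent-offspring, spouse, opposite-sex sibling
pairs: members play distinguishable roles) are plain product-moment
correlations over ordered pairs. Intraclass correlations for exchangeable
same-sex sibling pairs use double entry: each dyad is entered in both
orders, which makes the Pearson formula an intraclass estimator; on
balanced data it coincides with the one-way ANOVA ICC.

Standard errors and confidence intervals use Fisher's r-to-z
transformation with variance 1/(n-3), where n counts distinct dyads.
These SEs treat pairs as independent and therefore ignore the dependence
among pairs sharing an individual (a parent appears in one pair per
child); `family_bootstrap_se` resamples whole families to quantify that
dependence when wanted.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class CorrelationError(ValueError):
    pass


@dataclass
class CorrelationEstimate:
    subtype: str
    r: float
    se: float              # asymptotic SE on the r scale (delta from Fisher z)
    n_pairs: int           # distinct dyads
    method: str            # 'interclass' | 'intraclass-double-entry'


@dataclass
class TestResult:
    statistic: float
    p: float
    df: int | None = None
    kind: str = "z"


def _fisher_se_r(r: float, n: int) -> float:
    # delta-method back-mapping of the 1/sqrt(n-3) Fisher-scale SE
    return (1.0 - r**2) / math.sqrt(n - 3)


def interclass_correlation(
    pairs: np.ndarray | pd.DataFrame, subtype: str = ""
) -> CorrelationEstimate:
    """Product-moment correlation over ordered (a, b) pairs."""
    arr = np.asarray(pairs, float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise CorrelationError("pairs must be an (n, 2) array")
    n = arr.shape[0]
    if n < 3:
        raise CorrelationError(f"need at least 3 pairs, got {n}")
    r = float(np.corrcoef(arr[:, 0], arr[:, 1])[0, 1])
    se = _fisher_se_r(r, n) if n > 3 else float("nan")
    return CorrelationEstimate(subtype, r, se, n, "interclass")


def intraclass_correlation(
    pairs: np.ndarray | pd.DataFrame, subtype: str = ""
) -> CorrelationEstimate:
    """Double-entry correlation for exchangeable pairs.

    Each dyad enters in both orders; n_pairs reports distinct dyads."""
    arr = np.asarray(pairs, float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise CorrelationError("pairs must be an (n, 2) array")
    n = arr.shape[0]
    if n < 3:
        raise CorrelationError(f"need at least 3 pairs, got {n}")
    a = np.concatenate([arr[:, 0], arr[:, 1]])
    b = np.concatenate([arr[:, 1], arr[:, 0]])
    r = float(np.corrcoef(a, b)[0, 1])
    se = _fisher_se_r(r, n) if n > 3 else float("nan")
    return CorrelationEstimate(subtype, r, se, n, "intraclass-double-entry")


def family_bootstrap_se(
    pairs_by_family: dict[str, np.ndarray],
    *,
    intraclass: bool = False,
    n_boot: int = 500,
    seed: int = 0,
) -> float:
    """Bootstrap SE of a pair correlation resampling whole families,
    honouring the dependence among pairs sharing an individual."""
    rng = np.random.default_rng(seed)
    keys = list(pairs_by_family)
    est = intraclass_correlation if intraclass else interclass_correlation
    reps = []
    for _ in range(n_boot):
        take = rng.integers(len(keys), size=len(keys))
        stacked = np.concatenate([pairs_by_family[keys[i]] for i in take], axis=0)
        if stacked.shape[0] >= 3:
            reps.append(est(stacked).r)
    return float(np.std(reps, ddof=1))


def homogeneity_test(estimates: list[CorrelationEstimate]) -> TestResult:
    """Test that all subtype correlations within a main type are equal.

    Weighted Fisher-z chi-square: sum of w_i (z_i - weighted mean)^2 with
    w_i = n_i - 3, df = k - 1."""
    if len(estimates) < 2:
        raise CorrelationError("need at least 2 subtypes")
    if any(e.n_pairs <= 3 for e in estimates):
        raise CorrelationError("all subtypes need more than 3 pairs")
    z = np.array([math.atanh(e.r) for e in estimates])
    w = np.array([e.n_pairs - 3 for e in estimates], float)
    zbar = float((w * z).sum() / w.sum())
    chi2 = float((w * (z - zbar) ** 2).sum())
    df = len(estimates) - 1
    p = float(stats.chi2.sf(chi2, df))
    return TestResult(chi2, p, df=df, kind="chi2")


def compare_independent(r1: float, n1: int, r2: float, n2: int) -> TestResult:
    """Two-sided z test for two correlations from independent samples
    (Fisher z difference over its standard error)."""
    for r in (r1, r2):
        if abs(r) >= 1.0:
            raise CorrelationError("|r| must be < 1")
    if n1 <= 3 or n2 <= 3:
        raise CorrelationError("need n > 3 in both samples")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    return TestResult(z, float(2.0 * stats.norm.sf(abs(z))), kind="z")


def compare_dependent_nonoverlapping(
    corr: np.ndarray | pd.DataFrame, n: int
) -> TestResult:
    """Two-sided z test for two dependent correlations with no variable in
    common (Pearson-Filon covariance on the Fisher-z scale).

    ``corr`` is the 4x4 correlation matrix over variables ordered
    (a1, a2, b1, b2); the compared correlations are r_a = corr[0,1] and
    r_b = corr[2,3]."""
    R = np.asarray(corr, float)
    if R.shape != (4, 4):
        raise CorrelationError("need the full 4x4 correlation matrix")
    if not np.allclose(R, R.T) or np.linalg.eigvalsh(R).min() < -1e-10:
        raise CorrelationError("correlation matrix must be symmetric positive semidefinite")
    if n <= 3:
        raise CorrelationError("need n > 3")
    r_a, r_b = R[0, 1], R[2, 3]
    r13, r14, r23, r24 = R[0, 2], R[0, 3], R[1, 2], R[1, 3]
    # Pearson-Filon covariance kernel for non-overlapping correlations
    psi = (
        0.5 * r_a * r_b * (r13**2 + r14**2 + r23**2 + r24**2)
        + r13 * r24
        + r14 * r23
        - (r_a * (r13 * r14 + r23 * r24) + r_b * (r13 * r23 + r14 * r24))
    )
    c = psi / ((1.0 - r_a**2) * (1.0 - r_b**2))
    denom = math.sqrt(max(2.0 - 2.0 * c, 1e-12) / (n - 3))
    z = (math.atanh(r_a) - math.atanh(r_b)) / denom
    return TestResult(z, float(2.0 * stats.norm.sf(abs(z))), kind="z")


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher r-to-z confidence interval: tanh(atanh r +/- z* / sqrt(n-3))."""
    if n <= 3:
        raise CorrelationError("need n > 3")
    zcrit = stats.norm.ppf(0.5 + level / 2.0)
    half = zcrit / math.sqrt(n - 3)
    z = math.atanh(r)
    return math.tanh(z - half), math.tanh(z + half)


# ---------------------------------------------------------------------------
# Pair extraction from traits + pedigree
# ---------------------------------------------------------------------------

def pair_values(
    families, traits: pd.DataFrame, variable: str
) -> dict[str, np.ndarray]:
    """Trait value pairs per subtype for one variable.

    ``traits`` is the prepared long table (person_id, variable, value).
    Pairs whose members fall in different preparation groups still pair up
    (values are standardized within group first). Pairs with a missing
    member (e.g. excluded outlier) are skipped. Interclass ordering
    conventions: parent first, mother first for spouses, sister first for
    opposite-sex siblings."""
    from .pedigree import enumerate_relative_pairs

    tv = traits[traits["variable"] == variable].set_index("person_id")["value"]
    out: dict[str, list[tuple[float, float]]] = {}
    for fam in families:
        for pair in enumerate_relative_pairs(fam):
            a, b = pair.person_a.person_id, pair.person_b.person_id
            if a not in tv.index or b not in tv.index:
                continue
            out.setdefault(pair.subtype, []).append((float(tv[a]), float(tv[b])))
    return {k: np.array(v) for k, v in out.items()}


def paired_pair_values(
    families, traits: pd.DataFrame, var_x: str, var_y: str, subtypes: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray]:
    """Aligned pair-value arrays for two variables over the same dyads.

    Only dyads with both members observed for both variables are kept, so
    row i of the two returned (n, 2) arrays refers to the same dyad."""
    from .pedigree import enumerate_relative_pairs

    tx = traits[traits["variable"] == var_x].set_index("person_id")["value"]
    ty = traits[traits["variable"] == var_y].set_index("person_id")["value"]
    xs, ys = [], []
    for fam in families:
        for pair in enumerate_relative_pairs(fam):
            if pair.subtype not in subtypes:
                continue
            a, b = pair.person_a.person_id, pair.person_b.person_id
            if all(p in tv.index for p in (a, b) for tv in (tx, ty)):
                xs.append((float(tx[a]), float(tx[b])))
                ys.append((float(ty[a]), float(ty[b])))
    return np.array(xs), np.array(ys)


MAIN_TYPE_SUBTYPES = {
    "parent_offspring": (
        "mother-daughter", "mother-son", "father-daughter", "father-son",
    ),
    "sibling": ("sister-sister", "sister-brother", "brother-brother"),
    "spouse": ("mother-father",),
}
_EXCHANGEABLE = {"sister-sister", "brother-brother"}


def correlation_table(
    families, traits: pd.DataFrame, variable: str
) -> pd.DataFrame:
    """Correlations per subtype and pooled per main type for one variable.

    Same-sex sibling subtypes (and the pooled sibling main type) use the
    double-entry intraclass estimator; other rows are interclass. Rows
    with fewer than 3 pairs are skipped."""
    by_subtype = pair_values(families, traits, variable)
    rows = []
    for main, subtypes in MAIN_TYPE_SUBTYPES.items():
        pooled = []
        pooled_exchangeable = main == "sibling"
        for sub in subtypes:
            arr = by_subtype.get(sub)
            if arr is None or len(arr) == 0:
                continue
            pooled.append(arr)
            if len(arr) < 3:
                continue
            est = (
                intraclass_correlation(arr, sub)
                if sub in _EXCHANGEABLE
                else interclass_correlation(arr, sub)
            )
            lo, hi = fisher_ci(est.r, est.n_pairs) if est.n_pairs > 3 else (np.nan, np.nan)
            rows.append(
                {
                    "variable": variable,
                    "main_type": main,
                    "subtype": sub,
                    "r": est.r,
                    "se": est.se,
                    "n_pairs": est.n_pairs,
                    "ci_lo": lo,
                    "ci_hi": hi,
                    "method": est.method,
                }
            )
        if pooled:
            arr = np.concatenate(pooled, axis=0)
            if len(arr) >= 3:
                est = (
                    intraclass_correlation(arr, main)
                    if pooled_exchangeable
                    else interclass_correlation(arr, main)
                )
                lo, hi = fisher_ci(est.r, est.n_pairs) if est.n_pairs > 3 else (np.nan, np.nan)
                rows.append(
                    {
                        "variable": variable,
                        "main_type": main,
                        "subtype": "all",
                        "r": est.r,
                        "se": est.se,
                        "n_pairs": est.n_pairs,
                        "ci_lo": lo,
                        "ci_hi": hi,
                        "method": est.method,
                    }
                )
    return pd.DataFrame(rows)
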