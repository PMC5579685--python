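"""Trait preparation: from usual intakes to standardized residuals.

Within each sex-by-generation group (mothers, fathers, daughters, sons —
optionally split further into younger/older children), each dietary
variable is prepared for the familial analysis in four steps: a single
pass excluding values more than k standard deviations from the group mean
(default k = 3), a log transform when the sample skewness exceeds a
threshold (default 1.0), residualization on country indicators plus a
forward-stepwise cubic age polynomial, and z-standardization of the
residuals.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .config import AnalysisConfig


class TraitError(ValueError):
    pass


@dataclass
class PreparationLog:
    group: str = ""
    variable: str = ""
    n_outliers: int = 0
    transform: str = "identity"
    age_terms: list[str] = field(default_factory=list)


def exclude_outliers(
    values: np.ndarray, k: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass exclusion of |value - mean| > k*SD (moments from the
    full group). Returns (kept mask, excluded mask)."""
    values = np.asarray(values, float)
    sd = values.std(ddof=1) if len(values) > 1 else 0.0
    if sd == 0.0:
        warnings.warn("degenerate group (SD 0): no outliers excluded", stacklevel=2)
        keep = np.ones(len(values), dtype=bool)
        return keep, ~keep
    keep = np.abs(values - values.mean()) <= k * sd
    return keep, ~keep


def select_transform(values: np.ndarray, threshold: float = 1.0) -> str:
    """'log' when sample skewness exceeds the threshold, else 'identity'.

    Raises if log is selected but values are not strictly positive (no
    silent shifting)."""
    values = np.asarray(values, float)
    skew = float(stats.skew(values, bias=False)) if len(values) > 2 else 0.0
    if skew > threshold:
        if np.any(values <= 0):
            raise TraitError(
                "log transform selected but values are not strictly positive"
            )
        return "log"
    return "identity"


def residualize(
    values: np.ndarray,
    age: np.ndarray,
    country: np.ndarray | None = None,
    *,
    entry_p: float = 0.05,
) -> tuple[np.ndarray, list[str]]:
    """Residuals after country adjustment and a forward-stepwise cubic age
    polynomial.

    Country indicators are always included; age, age^2, age^3 are entered
    forward hierarchically (a higher power only on top of the lower ones)
    while the entering term's p-value is below ``entry_p``. Degenerate
    (collinear) higher powers are dropped with a log entry. Returns
    (residuals, selected age terms)."""
    values = np.asarray(values, float)
    age = np.asarray(age, float)
    n = len(values)
    base = [np.ones(n)]
    if country is not None:
        codes, levels = pd.factorize(np.asarray(country))
        for lvl in range(1, len(levels)):
            base.append((codes == lvl).astype(float))

    candidates = [("age", age), ("age^2", age**2), ("age^3", age**3)]
    selected: list[str] = []
    cols = list(base)
    for name, col in candidates:  # hierarchical forward entry
        X_try = np.column_stack(cols + [col])
        if np.linalg.matrix_rank(X_try) < X_try.shape[1]:
            break  # collinear/degenerate ages: drop this and higher powers
        fit = sm.OLS(values, X_try).fit()
        if fit.pvalues[-1] < entry_p:
            cols.append(col)
            selected.append(name)
        else:
            break
    final = sm.OLS(values, np.column_stack(cols)).fit()
    return np.asarray(final.resid), selected


def standardize(residuals: np.ndarray) -> np.ndarray:
    """Mean 0, SD 1 (ddof=0 so the postcondition is exact)."""
    residuals = np.asarray(residuals, float)
    sd = residuals.std()
    if sd == 0.0:
        raise TraitError("cannot standardize: residual SD is 0")
    return (residuals - residuals.mean()) / sd


def _group_label(role: str, sex: str, age: int | None = None,
                 cutoff: int | None = None) -> str:
    if role == "mother":
        return "mothers"
    if role == "father":
        return "fathers"
    base = "daughters" if sex == "F" else "sons"
    if cutoff is None or age is None:
        return base
    return f"{'younger' if age < cutoff else 'older'}_{base}"


def prepare_traits(
    usual: pd.DataFrame,
    persons: pd.DataFrame,
    *,
    config: AnalysisConfig | None = None,
    age_split: bool = False,
) -> tuple[pd.DataFrame, list[PreparationLog]]:
    """Standardized residual traits per sex-by-generation group.

    ``usual`` is long-format (person_id, variable, value); ``persons``
    supplies role/sex/age/country. With ``age_split`` the four groups
    become six (mothers, fathers, younger/older x daughters/sons). Returns
    (traits with columns person_id, family_id, variable, group, value,
    logs)."""
    config = config or AnalysisConfig()
    info = persons.set_index("person_id")
    df = usual.merge(
        persons[["person_id", "role", "sex", "age", "country", "family_id"]
                if "family_id" in persons.columns else
                ["person_id", "role", "sex", "age", "country"]],
        on="person_id",
    )
    cutoff = config.age_cutoff if age_split else None
    df["group"] = [
        _group_label(r, s, a, cutoff)
        for r, s, a in zip(df["role"], df["sex"], df["age"])
    ]

    out_rows = []
    logs: list[PreparationLog] = []
    for (variable, group), grp in df.groupby(["variable", "group"], sort=True):
        values = grp["value"].to_numpy(float)
        if len(values) < 10:
            warnings.warn(f"group {group}/{variable} has fewer than 10 members", stacklevel=2)
        keep, _ = exclude_outliers(values, config.outlier_sd)
        grp = grp.iloc[np.flatnonzero(keep)]
        values = grp["value"].to_numpy(float)
        transform = select_transform(values, config.skewness_threshold)
        work = np.log(values) if transform == "log" else values
        resid, terms = residualize(
            work,
            grp["age"].to_numpy(float),
            grp["country"].to_numpy(),
            entry_p=config.stepwise_entry_p,
        )
        z = standardize(resid)
        logs.append(
            PreparationLog(
                group=group,
                variable=variable,
                n_outliers=int((~keep).sum()),
                transform=transform,
                age_terms=terms,
            )
        )
        for pid, val in zip(grp["person_id"], z):
            out_rows.append(
                {
                    "person_id": pid,
                    "family_id": info.loc[pid, "family_id"]
                    if "family_id" in info.columns
                    else "",
                    "variable": variable,
                    "group": group,
                    "value": val,
                }
            )
    return pd.DataFrame(out_rows), logs
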