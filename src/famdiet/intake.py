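"""Recall cleaning, energy-misreporting screen, and usual-intake estimation.

The usual-intake model is a one-part measurement-error model for repeated
24-h recalls: a Box-Cox transform g(y; lambda) of the daily amount is
modelled as

    g(Y_ij; lambda) = beta' x_ij + u_i + eps_ij,

with person random effect u_i ~ N(0, sigma2_u), independent within-person
day-to-day error eps_ij ~ N(0, sigma2_eps[k(i)]) whose variance is specific
to the person's age group, and covariates x_ij = (1, age, FFQ frequency,
weekend indicator). lambda is chosen by profile maximum likelihood over a
fixed grid; given lambda, (beta, sigma2_u, sigma2_eps) are fitted by
maximum likelihood with beta profiled out in closed form. A person's usual
intake is the 5/7-2/7 weekday/weekend mixture of the back-transformed
empirical-Bayes person mean with a second-order bias correction, which
removes the variance inflation that day-to-day variation adds to a single
recall.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .config import AnalysisConfig, GoldbergParams


class IntakeError(ValueError):
    pass


class FittingError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Goldberg misreporting screen
# ---------------------------------------------------------------------------

#: Reference body weights (kg) by sex and integer age, used for a
#: weight-free BMR approximation; adult values beyond the table use the
#: last entry. Values follow conventional growth-reference medians.
REFERENCE_WEIGHTS: dict[str, dict[int, float]] = {
    "M": {2: 12.5, 3: 14.5, 4: 16.5, 5: 18.5, 6: 21.0, 7: 23.5, 8: 26.0,
          9: 29.0, 10: 32.0, 11: 36.0, 12: 41.0, 13: 46.0, 14: 51.0,
          15: 56.0, 16: 60.0, 17: 63.0, 18: 66.0, 19: 68.0, 20: 75.0},
    "F": {2: 12.0, 3: 14.0, 4: 16.0, 5: 18.0, 6: 20.0, 7: 22.5, 8: 25.5,
          9: 28.5, 10: 32.0, 11: 36.5, 12: 41.5, 13: 45.5, 14: 49.0,
          15: 52.0, 16: 54.0, 17: 55.0, 18: 56.0, 19: 57.0, 20: 65.0},
}

_MJ_TO_KCAL = 239.006

#: Schofield weight-equation coefficients (MJ/day): age band -> sex -> (a, b)
_SCHOFIELD = [
    (0, 3, {"M": (0.249, -0.127), "F": (0.244, -0.130)}),
    (3, 10, {"M": (0.095, 2.110), "F": (0.085, 2.033)}),
    (10, 18, {"M": (0.074, 2.754), "F": (0.056, 2.898)}),
    (18, 30, {"M": (0.063, 2.896), "F": (0.062, 2.036)}),
    (30, 60, {"M": (0.048, 3.653), "F": (0.034, 3.538)}),
    (60, 200, {"M": (0.049, 2.459), "F": (0.038, 2.755)}),
]


def reference_weight(sex: str, age: int) -> float:
    table = REFERENCE_WEIGHTS[sex]
    return table.get(min(int(age), 20), table[20])


def reference_bmr_kcal(sex: str, age: int) -> float:
    """Schofield-type BMR (kcal/day) at the sex-age reference weight."""
    w = reference_weight(sex, age)
    for lo, hi, coef in _SCHOFIELD:
        if lo <= age < hi:
            a, b = coef[sex]
            return (a * w + b) * _MJ_TO_KCAL
    raise IntakeError(f"no BMR band for age {age}")


def goldberg_classify(
    energy_kcal: float, sex: str, age: int, params: GoldbergParams | None = None
) -> str:
    """Classify one recall day as 'under', 'plausible' or 'over'.

    Compares EI/BMR with the closed interval [lower, upper] of plausibility
    cutoffs; boundary values count as plausible.
    """
    if energy_kcal <= 0:
        raise IntakeError(f"non-positive energy {energy_kcal}")
    params = params or GoldbergParams()
    lo, hi = params.cutoffs()
    ratio = energy_kcal / reference_bmr_kcal(sex, age)
    if ratio < lo:
        return "under"
    if ratio > hi:
        return "over"
    return "plausible"


# ---------------------------------------------------------------------------
# Imputation and recall filtering
# ---------------------------------------------------------------------------

def child_age_group(age: float, edges: tuple[int, ...]) -> str:
    """Label of the child age group [edges[k], edges[k+1]) containing age."""
    for lo, hi in zip(edges[:-1], edges[1:]):
        if lo <= age < hi:
            return f"{lo}-{hi}"
    raise IntakeError(f"age {age} outside child age-group edges {edges}")


def person_age_group(role: str, age: float, edges: tuple[int, ...]) -> str:
    return "adult" if role != "child" else child_age_group(age, edges)


def compute_reference_medians(
    recalls: pd.DataFrame,
    persons: pd.DataFrame,
    composition: pd.DataFrame,
    edges: tuple[int, ...],
) -> pd.DataFrame:
    """Median amounts by country x coarse food group x age group, from the
    observed (non-missing, positive) records."""
    merged = recalls.merge(
        persons[["person_id", "role", "age", "country"]], on="person_id"
    ).merge(composition[["food_id", "coarse_group"]], on="food_id")
    merged = merged[merged["amount_g"] > 0]
    merged["age_group"] = [
        person_age_group(r, a, edges) for r, a in zip(merged["role"], merged["age"])
    ]
    med = (
        merged.groupby(["country", "coarse_group", "age_group"])["amount_g"]
        .median()
        .reset_index()
        .rename(columns={"amount_g": "median_g"})
    )
    return med


def impute_food_amounts(
    recalls: pd.DataFrame,
    persons: pd.DataFrame,
    composition: pd.DataFrame,
    reference_medians: pd.DataFrame,
    edges: tuple[int, ...] = (2, 6, 9, 12, 15, 20),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replace missing/non-positive single-item amounts by the
    country x food-group x age-group median; count imputations per recall.

    Returns (records with amounts filled, per-recall imputation counts with
    columns person_id, day_index, n_imputed).
    """
    out = recalls.merge(
        persons[["person_id", "role", "age", "country"]], on="person_id", how="left"
    ).merge(composition[["food_id", "coarse_group"]], on="food_id", how="left")
    out["age_group"] = [
        person_age_group(r, a, edges) for r, a in zip(out["role"], out["age"])
    ]
    needs = ~(out["amount_g"] > 0)  # NaN or <= 0
    if needs.any():
        ref = reference_medians.set_index(["country", "coarse_group", "age_group"])[
            "median_g"
        ]
        fills = []
        for row in out.loc[needs].itertuples(index=False):
            key = (row.country, row.coarse_group, row.age_group)
            if key not in ref.index:
                raise IntakeError(f"no reference median for stratum {key}")
            fills.append(ref.loc[key])
        out.loc[needs, "amount_g"] = fills
    out["imputed"] = needs.astype(int)
    counts = (
        out.groupby(["person_id", "day_index"])["imputed"]
        .sum()
        .reset_index()
        .rename(columns={"imputed": "n_imputed"})
    )
    return out[recalls.columns], counts


def filter_recalls(
    recall_days: pd.DataFrame, max_imputed: int = 4
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop incomplete recalls and recalls with more than ``max_imputed``
    imputed items. ``recall_days`` has one row per recall with boolean
    ``complete`` and integer ``n_imputed``. Returns (retained, log)."""
    incomplete = ~recall_days["complete"].astype(bool)
    too_imputed = recall_days["n_imputed"] > max_imputed
    log = {
        "incomplete": int(incomplete.sum()),
        "too_many_imputed": int((too_imputed & ~incomplete).sum()),
        "retained": int((~incomplete & ~too_imputed).sum()),
    }
    return recall_days[~incomplete & ~too_imputed].copy(), log


# ---------------------------------------------------------------------------
# Usual-intake model
# ---------------------------------------------------------------------------

COVARIATE_NAMES = ("intercept", "age", "ffq", "weekend")


@dataclass
class UsualIntakeModel:
    """Fitted Box-Cox person-level measurement-error model for one stratum
    and one dietary variable."""

    lam: float
    beta: np.ndarray
    beta_names: tuple[str, ...]
    sigma2_u: float
    sigma2_eps: dict[str, float]       # age-group label -> residual variance
    loglik: float
    stratum: str = ""
    variable: str = ""
    identifiable: bool = True
    age_group_edges: tuple[int, ...] = (2, 6, 9, 12, 15, 20)
    keep_cols: tuple[int, ...] = (0, 1, 2, 3)   # design columns used in the fit
    messages: list[str] = field(default_factory=list)


def _boxcox(y: np.ndarray, lam: float) -> np.ndarray:
    return np.log(y) if lam == 0.0 else (np.power(y, lam) - 1.0) / lam


def _boxcox_inv_mean(m: float, sigma2: float, lam: float) -> float:
    """Back-transform of a transformed-scale mean with second-order bias
    correction: E[g^{-1}(m + eps)] ~= g^{-1}(m) + 0.5 sigma2 g^{-1}''(m)."""
    if lam == 0.0:
        return math.exp(m + sigma2 / 2.0)
    base = lam * m + 1.0
    if base <= 0:
        raise FittingError(f"Box-Cox back-transform undefined at m={m}, lambda={lam}")
    y = base ** (1.0 / lam)
    correction = 0.5 * sigma2 * (1.0 - lam) * base ** (1.0 / lam - 2.0)
    return y + correction


def _design(days: pd.DataFrame) -> np.ndarray:
    return np.column_stack(
        [
            np.ones(len(days)),
            days["age"].to_numpy(float),
            days["ffq"].to_numpy(float),
            days["weekend"].to_numpy(float),
        ]
    )


class _Stacked:
    """Person-blocked data ordered for reduceat-style aggregation."""

    def __init__(self, days: pd.DataFrame, edges: tuple[int, ...]):
        days = days.sort_values(["person_id", "day_index"]).reset_index(drop=True)
        self.days = days
        X_full = _design(days)
        # constant covariates (e.g. an all-missing FFQ filled with one value)
        # are collinear with the intercept and dropped from the fit
        self.keep_cols = tuple(
            j for j in range(X_full.shape[1]) if j == 0 or np.ptp(X_full[:, j]) > 0
        )
        self.X = X_full[:, self.keep_cols]
        codes, uniques = pd.factorize(days["person_id"], sort=True)
        self.person_ids = uniques
        self.starts = np.searchsorted(codes, np.arange(len(uniques)))
        self.n_i = np.diff(np.append(self.starts, len(codes)))
        roles = days.groupby("person_id", sort=True)[["role", "age"]].first()
        labels = [person_age_group(r, a, edges) for r, a in zip(roles["role"], roles["age"])]
        self.group_labels = sorted(set(labels))
        self.group_of_person = np.array([self.group_labels.index(l) for l in labels])
        # per-row group index for residual variance lookup
        self.group_of_row = np.repeat(self.group_of_person, self.n_i)


def _profile_negloglik(
    theta: np.ndarray, st: _Stacked, z: np.ndarray
) -> tuple[float, np.ndarray]:
    """-2 profile log-likelihood in (log sigma2_u, log sigma2_eps_k...) with
    beta profiled out by GLS; returns (value, beta)."""
    s2u = math.exp(theta[0])
    s2e_groups = np.exp(theta[1:])
    s2e_row = s2e_groups[st.group_of_row]
    s2e_person = s2e_groups[st.group_of_person]

    # Woodbury: V_i^{-1} = (1/s2e) (I - a_i J),  a_i = s2u / (s2e + n_i s2u)
    a_i = s2u / (s2e_person + st.n_i * s2u)

    Xw = st.X / s2e_row[:, None]
    XtX = st.X.T @ Xw
    Xsum = np.add.reduceat(st.X, st.starts, axis=0)          # per-person sums
    zsum = np.add.reduceat(z, st.starts)
    w = a_i / s2e_person
    XtX -= (Xsum * w[:, None]).T @ Xsum
    Xtz = Xw.T @ z - (Xsum * (w * zsum)[:, None]).sum(axis=0)
    try:
        beta = np.linalg.solve(XtX, Xtz)
    except np.linalg.LinAlgError as exc:
        raise FittingError(f"singular GLS system: {exc}") from exc

    resid = z - st.X @ beta
    rsum = np.add.reduceat(resid, st.starts)
    quad = float((resid**2 / s2e_row).sum() - (w * rsum**2).sum())
    logdet = float(
        ((st.n_i - 1) * np.log(s2e_person)).sum()
        + np.log(s2e_person + st.n_i * s2u).sum()
    )
    n = len(z)
    nll2 = logdet + quad + n * math.log(2.0 * math.pi)
    return nll2, beta


def fit_usual_intake_model(
    days: pd.DataFrame,
    *,
    config: AnalysisConfig | None = None,
    stratum: str = "",
    variable: str = "",
) -> UsualIntakeModel:
    """Fit the usual-intake model for one stratum and variable.

    ``days`` has one row per person-day with columns person_id, day_index,
    value (> 0), age, role, ffq, weekend. Box-Cox lambda is selected by
    profile likelihood over the configured grid; variances are bounded
    below at 1e-8 on the original scale.
    """
    config = config or AnalysisConfig()
    if len(days) == 0:
        raise FittingError("empty stratum")
    y = days["value"].to_numpy(float)
    if np.any(y <= 0):
        raise FittingError(
            "non-positive intake values: the one-part model requires positive consumption"
        )
    edges = config.child_age_group_edges
    st = _Stacked(days, edges)
    y = st.days["value"].to_numpy(float)
    log_jac = float(np.log(y).sum())

    messages: list[str] = []
    if int(st.n_i.max()) == 1:
        return _single_day_fallback(st, y, config, stratum, variable)

    best = None
    n_groups = len(st.group_labels)
    for lam in config.boxcox_grid:
        z = _boxcox(y, lam)
        var0 = max(float(np.var(z)), 1e-6)
        x0 = np.log(np.full(1 + n_groups, var0 / 2.0))
        res = optimize.minimize(
            lambda th: _profile_negloglik(th, st, z)[0],
            x0,
            method="L-BFGS-B",
            bounds=[(math.log(1e-8), math.log(1e6))] * (1 + n_groups),
        )
        nll2, beta = _profile_negloglik(res.x, st, z)
        loglik = -0.5 * nll2 + (lam - 1.0) * log_jac
        if best is None or loglik > best[0]:
            best = (loglik, lam, res, beta)
    loglik, lam, res, beta = best
    if not res.success and "ABNORMAL" in str(res.message).upper():
        raise FittingError(f"variance optimization failed: {res.message}")
    s2u = math.exp(res.x[0])
    s2e = {lab: math.exp(v) for lab, v in zip(st.group_labels, res.x[1:])}
    if s2u <= 2e-8:
        messages.append("person variance at boundary 0")
    return UsualIntakeModel(
        lam=lam,
        beta=beta,
        beta_names=tuple(COVARIATE_NAMES[j] for j in st.keep_cols),
        sigma2_u=s2u,
        sigma2_eps=s2e,
        loglik=loglik,
        stratum=stratum,
        variable=variable,
        age_group_edges=edges,
        keep_cols=st.keep_cols,
        messages=messages,
    )


def _single_day_fallback(
    st: _Stacked, y: np.ndarray, config: AnalysisConfig, stratum: str, variable: str
) -> UsualIntakeModel:
    """With a single day per person everywhere, sigma2_u and sigma2_eps are
    not separable; fall back to an FFQ-informed regression with the total
    residual variance split evenly, and flag reduced identifiability."""
    lam = 0.0 if np.all(y > 0) else 1.0
    z = _boxcox(y, lam)
    X = st.X
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    resid = z - X @ beta
    total = max(float(np.var(resid)), 1e-8)
    s2e = {lab: total / 2.0 for lab in st.group_labels}
    warnings.warn(
        "single recall day per person: person and day variances not separable; "
        "using FFQ-informed shrinkage with an even split",
        stacklevel=3,
    )
    return UsualIntakeModel(
        lam=lam,
        beta=beta,
        beta_names=tuple(COVARIATE_NAMES[j] for j in st.keep_cols),
        sigma2_u=total / 2.0,
        sigma2_eps=s2e,
        loglik=float("nan"),
        stratum=stratum,
        variable=variable,
        identifiable=False,
        age_group_edges=config.child_age_group_edges,
        keep_cols=st.keep_cols,
        messages=["reduced identifiability: single day per person"],
    )


def predict_usual_intake(
    model: UsualIntakeModel,
    person_days: pd.DataFrame,
    *,
    weekday_weight: float = 5.0 / 7.0,
    weekend_weight: float = 2.0 / 7.0,
) -> float:
    """Usual intake for one person from their recall days.

    Empirical-Bayes person effect from the transformed-scale residuals,
    then the weekday/weekend mixture of bias-corrected back-transforms.
    """
    required = {"value", "age", "ffq", "weekend", "role"}
    if not required <= set(person_days.columns):
        raise IntakeError(f"person days missing columns {required - set(person_days.columns)}")
    y = person_days["value"].to_numpy(float)
    z = _boxcox(y, model.lam)
    X = _design(person_days)[:, model.keep_cols]
    resid = z - X @ model.beta
    n = len(y)
    row = person_days.iloc[0]
    group = person_age_group(row["role"], row["age"], model.age_group_edges)
    s2e = model.sigma2_eps[group]
    shrink = n * model.sigma2_u / (s2e + n * model.sigma2_u)
    u_hat = shrink * float(resid.mean())

    x_wd = np.array([1.0, row["age"], row["ffq"], 0.0])[list(model.keep_cols)]
    x_we = np.array([1.0, row["age"], row["ffq"], 1.0])[list(model.keep_cols)]
    t_wd = _boxcox_inv_mean(float(x_wd @ model.beta) + u_hat, s2e, model.lam)
    t_we = _boxcox_inv_mean(float(x_we @ model.beta) + u_hat, s2e, model.lam)
    return weekday_weight * t_wd + weekend_weight * t_we


def estimate_usual_intakes(
    person_days: pd.DataFrame,
    persons: pd.DataFrame,
    ffq: pd.DataFrame,
    variables: tuple[str, ...] = ("energy_kcal", "healthy_sum", "unhealthy_sum"),
    *,
    config: AnalysisConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, UsualIntakeModel]]:
    """Per-person usual intakes for several dietary variables.

    Screens days with the Goldberg cutoffs on energy, then fits the model
    per sex-by-generation stratum per variable (FFQ item ``<variable>`` is
    the frequency covariate; missing frequencies get the stratum median)
    and predicts each person's usual intake. Returns (long-format usual
    intakes, fitted models keyed by 'variable/stratum').
    """
    config = config or AnalysisConfig()
    info = persons.set_index("person_id")
    days = person_days.merge(
        persons[["person_id", "role", "sex", "age"]], on="person_id"
    )
    days["goldberg"] = [
        goldberg_classify(e, s, int(a), config.goldberg)
        for e, s, a in zip(days["energy_kcal"], days["sex"], days["age"])
    ]
    plausible = days[days["goldberg"] == "plausible"].copy()
    plausible["weekend"] = (plausible["day_type"] == "weekend").astype(float)
    plausible["generation"] = np.where(plausible["role"] == "child", "child", "parent")
    plausible["stratum"] = plausible["sex"] + "-" + plausible["generation"]

    ffq_wide = ffq.pivot_table(
        index="person_id", columns="item_id", values="frequency_code", aggfunc="first"
    )

    rows = []
    models: dict[str, UsualIntakeModel] = {}
    for variable in variables:
        sub = plausible[["person_id", "day_index", "role", "sex", "age", "weekend", "stratum"]].copy()
        sub["value"] = plausible[variable].to_numpy()
        item = variable if (ffq_wide is not None and variable in ffq_wide.columns) else None
        if item is not None:
            sub = sub.merge(
                ffq_wide[item].rename("ffq"), left_on="person_id", right_index=True, how="left"
            )
        else:
            sub["ffq"] = np.nan
        for stratum, grp in sub.groupby("stratum", sort=True):
            grp = grp.copy()
            med = grp["ffq"].median()
            grp["ffq"] = grp["ffq"].fillna(0.0 if math.isnan(med) else med)
            model = fit_usual_intake_model(
                grp, config=config, stratum=stratum, variable=variable
            )
            models[f"{variable}/{stratum}"] = model
            for pid, pdays in grp.groupby("person_id", sort=True):
                value = predict_usual_intake(
                    model,
                    pdays,
                    weekday_weight=config.weekday_weight,
                    weekend_weight=config.weekend_weight,
                )
                rows.append(
                    {
                        "person_id": pid,
                        "variable": variable,
                        "value": value,
                        "stratum": stratum,
                        "n_days": len(pdays),
                    }
                )
    usual = pd.DataFrame(rows)
    usual["family_id"] = usual["person_id"].map(info["family_id"])
    return usual, models
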