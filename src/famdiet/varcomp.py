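"""Maximum-likelihood variance components on nuclear families.

The trait vector of family f is modelled as zero-mean multivariate normal
(traits are standardized residuals, so the mean model is an intercept at
zero) with covariance

    Sigma_f = 2*Phi_f * sigma2_g + H_f * sigma2_c + I * sigma2_e,

where 2*Phi is the kinship matrix (0.5 between parent-offspring and full
siblings, 0 between spouses) and H the household matrix (all ones within a
family). Familiality is F = (sigma2_g + sigma2_c) / total: the share of
trait variance attributable to everything family members share. With
nuclear families only, sigma2_g and sigma2_c cannot be interpreted
separately (spouse pairs are the only contrast), and when the sample holds
no spouse pairs at all they are not even identified: the likelihood is
flat along 0.5*sigma2_g + sigma2_c = const. That ridge is detected and the
reduced familial model Sigma = sigma2_f * H + sigma2_e * I is reported
instead of an arbitrary split. Non-negativity uses a softplus
reparameterization with explicit refits at the 0 boundary; the familiality
CI is profile-likelihood by default with a logit-scale delta-method
fallback.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .pedigree import Family, kinship_and_household


class VarCompError(RuntimeError):
    pass


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_c: float
    sigma2_e: float
    familiality: float
    loglik: float
    model: str = "gce"                  # 'gce' (g+c+e) or 'fe' (familial+e)
    ci: tuple[float, float] | None = None
    ci_method: str = ""
    converged: bool = True
    boundary: list[str] = field(default_factory=list)
    ridge: bool = False
    n_families: int = 0
    messages: list[str] = field(default_factory=list)

    @property
    def sigma2_familial(self) -> float:
        return self.sigma2_g + self.sigma2_c

    @property
    def total(self) -> float:
        return self.sigma2_g + self.sigma2_c + self.sigma2_e


def family_covariance(
    family: Family, components: tuple[float, float, float]
) -> np.ndarray:
    """Sigma_f = 2Phi sigma2_g + H sigma2_c + I sigma2_e for one family."""
    s2g, s2c, s2e = components
    if min(s2g, s2c, s2e) < 0:
        raise VarCompError("variance components must be non-negative")
    phi2, household = kinship_and_household(family)
    return s2g * phi2 + s2c * household + s2e * np.eye(len(family.members))


# ---------------------------------------------------------------------------
# Grouped data: families sharing a covariance structure are stacked
# ---------------------------------------------------------------------------

class FamilyTraitData:
    """Trait vectors over families, grouped by identical (2Phi, H) blocks
    so the likelihood does one Cholesky per distinct structure."""

    def __init__(self, blocks: Sequence[tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # blocks: (phi2, household, y) per family, members without trait
        # values already dropped
        groups: dict[bytes, list] = {}
        for phi2, hh, y in blocks:
            key = phi2.tobytes() + b"|" + hh.tobytes()
            groups.setdefault(key, [phi2, hh, []])[2].append(y)
        self.groups = [
            (phi2, hh, np.vstack(ys)) for phi2, hh, ys in groups.values()
        ]
        self.n_families = sum(g[2].shape[0] for g in self.groups)
        self.n_obs = sum(g[2].size for g in self.groups)
        # genetic contrasts exist only where some pair has kinship > 0
        self.has_kinship_pairs = any(
            bool(np.any(phi2[~np.eye(len(phi2), dtype=bool)] > 0))
            for phi2, _, _ in self.groups
        )
        # a spouse pair is a co-resident dyad with zero kinship
        self.has_spouse_pairs = any(
            bool(
                np.any(
                    np.isclose(phi2, 0.0)
                    & np.isclose(hh, 1.0)
                    & ~np.eye(len(phi2), dtype=bool)
                )
            )
            for phi2, hh, _ in self.groups
        )

    @classmethod
    def from_families(
        cls, families: Sequence[Family], values: Mapping[str, float] | pd.Series
    ) -> "FamilyTraitData":
        blocks = []
        for fam in families:
            have = [i for i, m in enumerate(fam.members) if m.person_id in values]
            if not have:
                continue
            phi2, hh = kinship_and_household(fam)
            idx = np.array(have)
            y = np.array([values[fam.members[i].person_id] for i in have], float)
            blocks.append((phi2[np.ix_(idx, idx)], hh[np.ix_(idx, idx)], y))
        if not blocks:
            raise VarCompError("no families with trait values")
        return cls(blocks)

    def sample_variance(self) -> float:
        y = np.concatenate([g[2].ravel() for g in self.groups])
        return float(np.var(y))


def log_likelihood(
    components: tuple[float, float, float], data: FamilyTraitData
) -> float:
    """Sum over families of the zero-mean MVN log-density under Sigma_f."""
    s2g, s2c, s2e = components
    if min(s2g, s2c, s2e) < 0:
        raise VarCompError("variance components must be non-negative")
    total = 0.0
    for phi2, hh, Y in data.groups:
        k = phi2.shape[0]
        sigma = s2g * phi2 + s2c * hh + s2e * np.eye(k)
        try:
            L = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError as exc:
            raise VarCompError(
                f"singular family covariance for structure of size {k}: {exc}"
            ) from exc
        logdet = 2.0 * float(np.log(np.diag(L)).sum())
        sol = np.linalg.solve(L, Y.T)
        quad = float((sol**2).sum())
        m = Y.shape[0]
        total += -0.5 * (m * k * math.log(2.0 * math.pi) + m * logdet + quad)
    return total


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

_SOFTPLUS_FLOOR = 1e-10


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _softplus_inv(y: float) -> float:
    y = max(y, 1e-6)
    return math.log(math.expm1(y)) if y < 20.0 else y


def _negll(theta: np.ndarray, data: FamilyTraitData, free: np.ndarray,
           fixed: np.ndarray, model: str) -> float:
    params = fixed.copy()
    params[free] = _softplus(theta)
    if model == "fe":
        comps = (0.0, params[0], params[1])
    else:
        comps = tuple(params)
    try:
        return -log_likelihood(comps, data)
    except VarCompError:
        return 1e12


def _optimize(data: FamilyTraitData, model: str, starts: list[np.ndarray],
              fix_zero: tuple[int, ...] = ()) -> tuple[np.ndarray, float, bool]:
    """Maximize the likelihood over the non-fixed components; returns
    (components on the variance scale, loglik, converged)."""
    npar = 2 if model == "fe" else 3
    free = np.array([i for i in range(npar) if i not in fix_zero])
    fixed = np.zeros(npar)
    best = None
    converged = False
    for x0 in starts:
        th0 = np.array([_softplus_inv(max(x0[i], 1e-4)) for i in free])
        res = optimize.minimize(
            _negll, th0, args=(data, free, fixed, model),
            method="L-BFGS-B", options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success) or converged
    params = fixed.copy()
    params[free] = np.maximum(_softplus(best.x), 0.0)
    params[np.abs(params) < _SOFTPLUS_FLOOR] = 0.0
    return params, -float(best.fun), converged


def fit_variance_components(
    data: FamilyTraitData | Sequence[Family],
    values: Mapping[str, float] | pd.Series | None = None,
    *,
    model: str = "gce",
    ci: bool = True,
    ci_level: float = 0.95,
    ci_method: str = "profile",
) -> VarianceComponents:
    """ML variance components and familiality for one trait.

    Accepts either a prebuilt FamilyTraitData or (families, values).
    Fits with multi-start quasi-Newton on the softplus scale, refits with
    components pinned at the 0 boundary when the unconstrained solution
    lands there, and flags the g/c ridge when no spouse pairs are present
    (in which case the reduced familial model is reported).
    """
    if not isinstance(data, FamilyTraitData):
        if values is None:
            raise VarCompError("provide trait values")
        data = FamilyTraitData.from_families(data, values)
    if data.n_families < 50:
        warnings.warn(
            f"only {data.n_families} families: variance-component estimates "
            "may be unstable",
            stacklevel=2,
        )

    ridge = model == "gce" and not data.has_spouse_pairs
    messages = []
    pin: tuple[int, ...] = ()
    if ridge:
        messages.append(
            "no spouse pairs: sigma2_g and sigma2_c are confounded "
            "(likelihood flat along 0.5*sigma2_g + sigma2_c); reporting the "
            "reduced familial model"
        )
        model = "fe"
    elif model == "gce" and not data.has_kinship_pairs:
        # spouse-pairs-only data: sigma2_g appears only on the diagonal and
        # is confounded with sigma2_e; pin it at the 0 boundary
        messages.append(
            "no genetically related pairs: sigma2_g carries no signal and is "
            "fixed at 0"
        )
        pin = (0,)

    var = data.sample_variance()
    if model == "fe":
        starts = [np.array([f * var, (1 - f) * var]) for f in (0.3, 0.6, 0.05)]
    else:
        starts = [
            np.array([0.25 * var, 0.2 * var, 0.55 * var]),
            np.array([0.05 * var, 0.05 * var, 0.9 * var]),
            np.array([0.5 * var, 0.1 * var, 0.4 * var]),
        ]
    params, loglik, converged = _optimize(data, model, starts, fix_zero=pin)

    # explicit boundary refits for components near zero
    npar = 2 if model == "fe" else 3
    boundary: list[str] = []
    small = [i for i in range(npar - 1) if params[i] < 1e-3 * max(var, 1e-12)]
    for combo in [(i,) for i in small] + ([tuple(small)] if len(small) > 1 else []):
        combo = tuple(sorted(set(combo) | set(pin)))
        p2, ll2, conv2 = _optimize(data, model, starts, fix_zero=combo)
        if ll2 >= loglik - 1e-6:
            params, loglik, converged = p2, ll2, conv2 or converged
    if not converged:
        raise VarCompError("variance-component optimization failed to converge")

    if model == "fe":
        s2g, s2c, s2e = 0.0, params[0], params[1]
        names = ("sigma2_familial", "sigma2_e")
        for name, value in zip(names, params):
            if value == 0.0:
                boundary.append(name)
    else:
        s2g, s2c, s2e = params
        for name, value in zip(("sigma2_g", "sigma2_c", "sigma2_e"), params):
            if value == 0.0:
                boundary.append(name)
    total = s2g + s2c + s2e
    fam = (s2g + s2c) / total if total > 0 else 0.0

    fit = VarianceComponents(
        sigma2_g=s2g,
        sigma2_c=s2c,
        sigma2_e=s2e,
        familiality=fam,
        loglik=loglik,
        model=model,
        converged=converged,
        boundary=boundary,
        ridge=ridge,
        n_families=data.n_families,
        messages=messages,
    )
    if ci:
        fit.ci = familiality_ci(data, fit, level=ci_level, method=ci_method)
        fit.ci_method = (
            "delta"
            if any(m.startswith("delta fallback") for m in fit.messages)
            else ci_method
        )
    return fit


# ---------------------------------------------------------------------------
# Familiality confidence interval
# ---------------------------------------------------------------------------

def _profile_loglik_at_F(
    F: float, data: FamilyTraitData, model: str, warm: dict
) -> float:
    """Max loglik subject to familial share fixed at F.

    Inner parameters: log total variance, and (gce model) the genetic
    share a of the familial part, bounded in [0, 1]. Both a fresh and a
    warm start are tried; the better optimum wins."""
    if model == "fe":
        def nll(x):
            v = math.exp(x[0])
            return -_safe_ll((0.0, F * v, (1.0 - F) * v), data)
        starts = [np.array([0.0])]
        bounds = [(-20.0, 20.0)]
    else:
        def nll(x):
            v = math.exp(x[0])
            a = x[1]
            return -_safe_ll((a * F * v, (1 - a) * F * v, (1.0 - F) * v), data)
        starts = [np.array([0.0, 0.5])]
        bounds = [(-20.0, 20.0), (0.0, 1.0)]
    if "x" in warm:
        starts.append(warm["x"])
    best = None
    for x0 in starts:
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                                options={"ftol": 1e-13, "gtol": 1e-9})
        if best is None or res.fun < best.fun:
            best = res
    warm["x"] = best.x
    return -float(best.fun)


def _safe_ll(comps, data):
    try:
        return log_likelihood(comps, data)
    except VarCompError:
        return -1e12


def familiality_ci(
    data: FamilyTraitData,
    fit: VarianceComponents,
    *,
    level: float = 0.95,
    method: str = "profile",
) -> tuple[float, float]:
    """CI for familiality F: profile likelihood (default) or logit-scale
    delta method. lo >= 0 and hi <= 1 always."""
    if method == "delta":
        return _delta_ci(data, fit, level)
    F_hat = fit.familiality
    target = fit.loglik - 0.5 * stats.chi2.ppf(level, 1)
    model = fit.model
    warm: dict = {}

    def pll(F: float) -> float:
        F = min(max(F, 1e-9), 1.0 - 1e-9)
        return _profile_loglik_at_F(F, data, model, warm)

    try:
        lo = 0.0
        if pll(1e-9) < target:
            lo = optimize.brentq(lambda F: pll(F) - target, 1e-9, max(F_hat, 2e-9),
                                 xtol=1e-5)
        warm.clear()
        hi = 1.0
        if pll(1.0 - 1e-9) < target:
            hi = optimize.brentq(lambda F: pll(F) - target,
                                 min(F_hat, 1.0 - 2e-9), 1.0 - 1e-9, xtol=1e-5)
    except ValueError:
        fit.messages.append("delta fallback: profile CI failed to bracket")
        warnings.warn("profile CI failed to bracket; falling back to delta method",
                      stacklevel=2)
        return _delta_ci(data, fit, level)
    return max(lo, 0.0), min(hi, 1.0)


def _delta_ci(data: FamilyTraitData, fit: VarianceComponents,
              level: float) -> tuple[float, float]:
    F_hat = min(max(fit.familiality, 1e-6), 1.0 - 1e-6)
    warm: dict = {}
    h = 1e-3

    def pll(F):
        return _profile_loglik_at_F(min(max(F, 1e-9), 1 - 1e-9), data, fit.model, warm)

    d2 = (pll(F_hat + h) - 2.0 * pll(F_hat) + pll(F_hat - h)) / h**2
    if d2 >= 0:
        return 0.0, 1.0
    var_F = -1.0 / d2
    sd_logit = math.sqrt(var_F) / (F_hat * (1.0 - F_hat))
    z = stats.norm.ppf(0.5 + level / 2.0)
    logit = math.log(F_hat / (1.0 - F_hat))
    lo = 1.0 / (1.0 + math.exp(-(logit - z * sd_logit)))
    hi = 1.0 / (1.0 + math.exp(-(logit + z * sd_logit)))
    if fit.familiality <= 1e-6:
        lo = 0.0
    return lo, hi


# ---------------------------------------------------------------------------
# Age-stratified familiality
# ---------------------------------------------------------------------------

def stratified_familiality(
    families: Sequence[Family],
    values: Mapping[str, float] | pd.Series,
    *,
    cutoff_years: int = 11,
    model: str = "gce",
    ci_level: float = 0.95,
) -> dict:
    """Familiality per child-age stratum (parents plus in-band children).

    Returns {'younger': fit, 'older': fit, 'nonoverlap': bool}; the flag is
    True when the two familiality CIs do not overlap."""
    from .pedigree import split_children_by_age

    younger, older = split_children_by_age(families, cutoff_years)
    out = {}
    for name, fams in (("younger", younger), ("older", older)):
        if not fams:
            raise VarCompError(f"empty {name} stratum")
        out[name] = fit_variance_components(fams, values, model=model,
                                            ci_level=ci_level)
    lo_y, hi_y = out["younger"].ci
    lo_o, hi_o = out["older"].ci
    out["nonoverlap"] = bool(hi_y < lo_o or hi_o < lo_y)
    return out
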