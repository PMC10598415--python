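"""Univariate and bivariate ACE-family maximum-likelihood estimation.

The likelihood treats each twin pair as one draw from a multivariate
normal whose covariance is implied by the biometric paths
(:mod:`twinace.acecov`): MZ pairs share all additive-genetic variance,
DZ pairs half of it, shared environment is common to both twins and
non-shared environment (which also absorbs measurement error) is
twin-specific.  Pairs with partially missing phenotypes contribute the
marginal likelihood of their observed values (FIML).

Estimation is by quasi-Newton optimization of an unconstrained
reparameterization — log path coefficients, atanh component
correlations — from a moment-based (Falconer) start plus jittered
restarts with fixed internal seeds, so fits are deterministic.
Confidence intervals are profile-likelihood based: a 95% bound is the
quantity value at which the constrained -2lnL exceeds the optimum by
chi-square(0.95, 1) = 3.841, with a delta-method fallback if profiling
fails and explicit flags when a bound sits on the parameter-space
boundary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from ._mvn import (NONPD_PENALTY, PatternStats, finite_difference_hessian,
                   neg2_loglik, split_patterns)
from .acecov import bivariate_pair_cov, univariate_pair_cov
from .data_io import CohortTable

logger = logging.getLogger(__name__)

UNIVARIATE_MODELS = ("ACE", "AE", "CE", "E")
BIVARIATE_MODELS = ("ACE", "AE")

_JITTER_SEED = 20231888
_N_STARTS = 3
_MIN_PATH = 1e-8   # floor when a dropped-to-zero path re-enters a transform


class FitError(RuntimeError):
    """Optimization failed to converge from every start."""


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class UnivariateACEParams:
    """Path coefficients and mean for one phenotype.

    ``a``, ``c``, ``e`` are nonnegative paths; the standardized variance
    proportions are the squared paths over the total variance.
    """

    a: float
    c: float
    e: float
    mean: float = 0.0

    @property
    def variance(self) -> float:
        return self.a ** 2 + self.c ** 2 + self.e ** 2

    @property
    def A(self) -> float:
        return self.a ** 2 / self.variance

    @property
    def C(self) -> float:
        return self.c ** 2 / self.variance

    @property
    def E(self) -> float:
        return self.e ** 2 / self.variance

    def proportions(self) -> dict[str, float]:
        return {"A": self.A, "C": self.C, "E": self.E}


@dataclass
class BivariateACEParams:
    """Correlated-factors parameters for two phenotypes.

    Per-trait paths plus the component correlations r_a, r_c, r_e between
    the same-named factors of the two traits.
    """

    a1: float
    c1: float
    e1: float
    a2: float
    c2: float
    e2: float
    r_a: float = 0.0
    r_c: float = 0.0
    r_e: float = 0.0
    mean1: float = 0.0
    mean2: float = 0.0

    @property
    def variance1(self) -> float:
        return self.a1 ** 2 + self.c1 ** 2 + self.e1 ** 2

    @property
    def variance2(self) -> float:
        return self.a2 ** 2 + self.c2 ** 2 + self.e2 ** 2

    def covariance_components(self) -> dict[str, float]:
        return {"A": self.a1 * self.a2 * self.r_a,
                "C": self.c1 * self.c2 * self.r_c,
                "E": self.e1 * self.e2 * self.r_e}

    @property
    def r_ph(self) -> float:
        """Phenotypic correlation implied by the component structure."""
        comps = self.covariance_components()
        return sum(comps.values()) / math.sqrt(self.variance1 * self.variance2)

    def covariance_shares(self) -> dict[str, float]:
        """A/C/E shares of the phenotypic covariance (sum to 1).

        Shares may lie outside [0, 1] when components have opposing signs.
        """
        comps = self.covariance_components()
        total = sum(comps.values())
        if total == 0:
            raise ZeroDivisionError("phenotypic covariance is zero")
        return {k: v / total for k, v in comps.items()}

    def standardized_components(self, trait: int) -> dict[str, float]:
        if trait == 1:
            v = self.variance1
            return {"A": self.a1 ** 2 / v, "C": self.c1 ** 2 / v,
                    "E": self.e1 ** 2 / v}
        v = self.variance2
        return {"A": self.a2 ** 2 / v, "C": self.c2 ** 2 / v,
                "E": self.e2 ** 2 / v}


def bivariate_heritability(params: BivariateACEParams) -> float:
    """Share of the phenotypic covariance attributable to additive genetics."""
    return params.covariance_shares()["A"]


@dataclass
class ModelComparison:
    parent: str
    nested: str
    delta_minus2ll: float
    delta_df: int
    p_value: float
    p_value_boundary: float | None = None  # 50:50 chi2(0)/chi2(1) mixture


@dataclass
class FitResult:
    model: str
    params: UnivariateACEParams | BivariateACEParams
    minus2ll: float
    n_free_params: int
    convergence: dict
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)
    ci_flags: dict[str, str] = field(default_factory=dict)
    _ctx: dict = field(default_factory=dict, repr=False)

    @property
    def converged(self) -> bool:
        return bool(self.convergence.get("success", False))


# ---------------------------------------------------------------------------
# data preparation


def _prepare_groups(cohort: CohortTable, traits) -> list[tuple[float, list[PatternStats], int]]:
    """Pattern statistics per relatedness group (MZ, pooled DZ)."""
    if isinstance(traits, str):
        traits = [traits]
    out = []
    for k_a, zygs in ((1.0, ("MZ",)), (0.5, ("DZ_SS", "DZ_OS"))):
        X = cohort.pair_matrix(traits, zygosities=zygs)
        pats = split_patterns(X)
        n = sum(p.n for p in pats)
        out.append((k_a, pats, n))
    return out


# ---------------------------------------------------------------------------
# likelihoods


def _uni_neg2ll(params: UnivariateACEParams, groups) -> float:
    total = 0.0
    mu = np.array([params.mean, params.mean])
    for k_a, pats, _ in groups:
        if not pats:
            continue
        sigma = univariate_pair_cov(params.a, params.c, params.e, k_a)
        total += neg2_loglik(mu, sigma, pats)
    return total


def _biv_neg2ll(params: BivariateACEParams, groups) -> float:
    total = 0.0
    mu = np.array([params.mean1, params.mean2, params.mean1, params.mean2])
    p1 = (params.a1, params.c1, params.e1)
    p2 = (params.a2, params.c2, params.e2)
    for k_a, pats, _ in groups:
        if not pats:
            continue
        sigma = bivariate_pair_cov(p1, p2, params.r_a, params.r_c,
                                   params.r_e, k_a)
        total += neg2_loglik(mu, sigma, pats)
    return total


def univariate_minus2ll(params: UnivariateACEParams, cohort: CohortTable,
                        trait: str | None = None) -> float:
    """-2 log-likelihood of a univariate ACE parameter set on a cohort."""
    trait = cohort.trait_names[0] if trait is None else trait
    return _uni_neg2ll(params, _prepare_groups(cohort, trait))


def bivariate_minus2ll(params: BivariateACEParams, cohort: CohortTable,
                       traits=None) -> float:
    """-2 log-likelihood of a bivariate correlated-factors parameter set."""
    traits = cohort.trait_names[:2] if traits is None else traits
    return _biv_neg2ll(params, _prepare_groups(cohort, traits))


# ---------------------------------------------------------------------------
# transformed parameter vectors

_UNI_LAYOUT = {"ACE": ("mean", "a", "c", "e"),
               "AE": ("mean", "a", "e"),
               "CE": ("mean", "c", "e"),
               "E": ("mean", "e")}

_BIV_LAYOUT = {
    "ACE": ("mean1", "mean2", "a1", "c1", "e1", "a2", "c2", "e2",
            "r_a", "r_c", "r_e"),
    "AE": ("mean1", "mean2", "a1", "e1", "a2", "e2", "r_a", "r_e"),
}

_CORR_NAMES = {"r_a", "r_c", "r_e"}
_MEAN_NAMES = {"mean", "mean1", "mean2"}


def _to_theta(names, values: dict) -> np.ndarray:
    theta = []
    for nm in names:
        v = values[nm]
        if nm in _MEAN_NAMES:
            theta.append(v)
        elif nm in _CORR_NAMES:
            theta.append(np.arctanh(np.clip(v, -0.999999, 0.999999)))
        else:
            theta.append(math.log(max(v, _MIN_PATH)))
    return np.array(theta, dtype=float)


def _from_theta(names, theta: np.ndarray) -> dict:
    out = {}
    for nm, t in zip(names, theta):
        if nm in _MEAN_NAMES:
            out[nm] = float(t)
        elif nm in _CORR_NAMES:
            out[nm] = float(np.tanh(t))
        else:
            out[nm] = float(math.exp(min(t, 30.0)))
    return out


def _uni_params(model: str, theta: np.ndarray) -> UnivariateACEParams:
    vals = _from_theta(_UNI_LAYOUT[model], theta)
    return UnivariateACEParams(a=vals.get("a", 0.0), c=vals.get("c", 0.0),
                               e=vals["e"], mean=vals["mean"])


def _biv_params(model: str, theta: np.ndarray) -> BivariateACEParams:
    vals = _from_theta(_BIV_LAYOUT[model], theta)
    return BivariateACEParams(
        a1=vals.get("a1", 0.0), c1=vals.get("c1", 0.0), e1=vals["e1"],
        a2=vals.get("a2", 0.0), c2=vals.get("c2", 0.0), e2=vals["e2"],
        r_a=vals.get("r_a", 0.0), r_c=vals.get("r_c", 0.0),
        r_e=vals.get("r_e", 0.0),
        mean1=vals["mean1"], mean2=vals["mean2"])


# ---------------------------------------------------------------------------
# moment-based initialization


def symmetrized_twin_correlation(cohort: CohortTable, trait: str,
                                 zygosities) -> float:
    """Twin-order-symmetric (intraclass-style) correlation on complete pairs."""
    X = cohort.pair_matrix(trait, zygosities=zygosities)
    X = X[~np.isnan(X).any(axis=1)]
    if X.shape[0] < 2:
        return 0.0
    m = X.mean()
    v = ((X - m) ** 2).mean()
    if v == 0:
        return 0.0
    c = ((X[:, 0] - m) * (X[:, 1] - m)).mean()
    return float(np.clip(c / v, -1.0, 1.0))


@dataclass
class FalconerEstimates:
    """Moment estimators from the MZ/DZ correlation contrast.

    A = 2(rMZ - rDZ), C = 2 rDZ - rMZ, E = 1 - rMZ; raw (unclipped) values.
    """

    r_mz: float
    r_dz: float

    @property
    def A(self) -> float:
        return 2.0 * (self.r_mz - self.r_dz)

    @property
    def C(self) -> float:
        return 2.0 * self.r_dz - self.r_mz

    @property
    def E(self) -> float:
        return 1.0 - self.r_mz


def falconer_estimates(cohort: CohortTable, trait: str) -> FalconerEstimates:
    return FalconerEstimates(
        r_mz=symmetrized_twin_correlation(cohort, trait, ("MZ",)),
        r_dz=symmetrized_twin_correlation(cohort, trait, ("DZ_SS", "DZ_OS")))


def _uni_start(cohort: CohortTable, trait: str, model: str) -> dict:
    vals = cohort.pair_matrix(trait).ravel()
    vals = vals[~np.isnan(vals)]
    mean = float(vals.mean()) if vals.size else 0.0
    var = float(vals.var(ddof=1)) if vals.size > 1 else 1.0
    fal = falconer_estimates(cohort, trait)
    A0 = float(np.clip(fal.A, 0.02, 0.95))
    C0 = float(np.clip(fal.C, 0.02, 0.95))
    if model == "AE":
        A0 = float(np.clip(fal.r_mz, 0.02, 0.95))
        C0 = 0.0
    elif model == "CE":
        C0 = float(np.clip(fal.r_mz, 0.02, 0.95))
        A0 = 0.0
    elif model == "E":
        A0 = C0 = 0.0
    E0 = max(1.0 - A0 - C0, 0.05)
    scale = var / (A0 + C0 + E0)
    return {"mean": mean, "a": math.sqrt(A0 * scale), "c": math.sqrt(C0 * scale),
            "e": math.sqrt(E0 * scale)}


def _minimize(fun, x0: np.ndarray, n_starts: int = _N_STARTS,
              jitter: float = 0.25):
    """Quasi-Newton minimization with fixed-seed jittered restarts."""
    rng = np.random.default_rng(_JITTER_SEED)
    best = None
    n_ok = 0
    for s in range(n_starts):
        start = x0 if s == 0 else x0 + jitter * rng.standard_normal(x0.size)
        res = optimize.minimize(fun, start, method="L-BFGS-B",
                                options={"maxiter": 1000, "ftol": 1e-13,
                                         "gtol": 1e-8})
        if res.fun < NONPD_PENALTY / 2:
            n_ok += 1
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        raise FitError("optimization failed from every start")
    best.n_successful_starts = n_ok
    return best


# ---------------------------------------------------------------------------
# fitting


def fit_univariate(cohort: CohortTable, trait: str | None = None,
                   model: str = "ACE", ci=("A", "C", "E"),
                   n_starts: int = _N_STARTS) -> FitResult:
    """ML fit of an ACE-family model with DZ twins pooled.

    ``ci`` names the standardized quantities to report 95% profile CIs for
    (restricted to components present in the model); pass ``()`` to skip CI
    computation, e.g. inside replicate loops.
    """
    if model not in UNIVARIATE_MODELS:
        raise ValueError(f"model must be one of {UNIVARIATE_MODELS}")
    trait = cohort.trait_names[0] if trait is None else trait
    groups = _prepare_groups(cohort, trait)
    if all(n == 0 for _, _, n in groups):
        raise ValueError(f"no data for trait {trait!r}")
    names = _UNI_LAYOUT[model]
    start = _uni_start(cohort, trait, model)

    def fun(theta):
        return _uni_neg2ll(_uni_params(model, theta), groups)

    res = _minimize(fun, _to_theta(names, start), n_starts=n_starts)
    params = _uni_params(model, res.x)
    fit = FitResult(
        model=model, params=params, minus2ll=float(res.fun),
        n_free_params=len(names),
        convergence={"success": bool(res.success), "n_iter": int(res.nit),
                     "n_successful_starts": res.n_successful_starts},
        _ctx={"kind": "uni", "model": model, "groups": groups,
              "names": names, "theta": res.x.copy()})
    present = {"ACE": ("A", "C", "E"), "AE": ("A", "E"),
               "CE": ("C", "E"), "E": ("E",)}[model]
    for q in ci:
        if q in present:
            fit.ci95[q] = likelihood_ci(fit, q)
    return fit


def _biv_start(cohort: CohortTable, traits, model: str) -> dict:
    t1, t2 = traits
    s1 = _uni_start(cohort, t1, "ACE" if model == "ACE" else "AE")
    s2 = _uni_start(cohort, t2, "ACE" if model == "ACE" else "AE")
    # moment starts for the component correlations from CTCT / phenotypic corr
    X = cohort.pair_matrix(traits)
    both = X[:, [0, 1]]
    both = both[~np.isnan(both).any(axis=1)]
    r_ph = float(np.corrcoef(both.T)[0, 1]) if both.shape[0] > 2 else 0.0
    a1, a2 = s1["a"], s2["a"]
    e1, e2 = s1["e"], s2["e"]
    v1 = a1 ** 2 + s1["c"] ** 2 + e1 ** 2
    v2 = a2 ** 2 + s2["c"] ** 2 + e2 ** 2
    denom = a1 * a2 / math.sqrt(v1 * v2)
    r_a0 = float(np.clip(0.6 * r_ph / denom if denom > 1e-6 else 0.0,
                         -0.9, 0.9))
    denom_e = e1 * e2 / math.sqrt(v1 * v2)
    r_e0 = float(np.clip(0.4 * r_ph / denom_e if denom_e > 1e-6 else 0.0,
                         -0.9, 0.9))
    return {"mean1": s1["mean"], "mean2": s2["mean"],
            "a1": a1, "c1": s1["c"], "e1": e1,
            "a2": a2, "c2": s2["c"], "e2": e2,
            "r_a": r_a0, "r_c": 0.1 if model == "ACE" else 0.0, "r_e": r_e0}


def fit_bivariate(cohort: CohortTable, traits=None, model: str = "AE",
                  ci=("rPh", "rA", "rE", "bivA", "bivE"),
                  n_starts: int = _N_STARTS) -> FitResult:
    """ML fit of the bivariate correlated-factors model (DZ pooled, FIML).

    Individuals missing one trait still contribute through the marginal
    likelihood of their observed values.
    """
    if model not in BIVARIATE_MODELS:
        raise ValueError(f"model must be one of {BIVARIATE_MODELS}")
    traits = cohort.trait_names[:2] if traits is None else list(traits)
    if len(traits) != 2:
        raise ValueError("need exactly two traits")
    groups = _prepare_groups(cohort, traits)
    names = _BIV_LAYOUT[model]
    start = _biv_start(cohort, traits, model)

    def fun(theta):
        return _biv_neg2ll(_biv_params(model, theta), groups)

    res = _minimize(fun, _to_theta(names, start), n_starts=n_starts)
    params = _biv_params(model, res.x)
    fit = FitResult(
        model=model, params=params, minus2ll=float(res.fun),
        n_free_params=len(names),
        convergence={"success": bool(res.success), "n_iter": int(res.nit),
                     "n_successful_starts": res.n_successful_starts},
        _ctx={"kind": "biv", "model": model, "groups": groups,
              "names": names, "theta": res.x.copy(), "traits": traits})
    for q in ci:
        try:
            fit.ci95[q] = likelihood_ci(fit, q)
        except Exception as exc:   # CI failure should not void the fit
            logger.warning("CI for %s failed: %s", q, exc)
    return fit


def compare_nested(parent: FitResult, nested: FitResult) -> ModelComparison:
    """Likelihood-ratio test of a nested model against its parent.

    The naive chi-square p-value is primary; for a single dropped variance
    component the 50:50 chi-square(0):chi-square(1) boundary mixture is
    reported alongside.
    """
    nesting = {("ACE", "AE"), ("ACE", "CE"), ("ACE", "E"),
               ("AE", "E"), ("CE", "E")}
    if (parent.model, nested.model) not in nesting:
        raise ValueError(
            f"{nested.model} is not nested in {parent.model}")
    delta_df = parent.n_free_params - nested.n_free_params
    delta = max(nested.minus2ll - parent.minus2ll, 0.0)
    p = float(stats.chi2.sf(delta, delta_df)) if delta > 0 else 1.0
    p_boundary = None
    if delta_df == 1:
        p_boundary = 0.5 * float(stats.chi2.sf(delta, 1)) if delta > 0 else 1.0
    return ModelComparison(parent.model, nested.model, delta, delta_df,
                           p, p_boundary)


# ---------------------------------------------------------------------------
# profile-likelihood machinery

CHI2_95_DF1 = float(stats.chi2.ppf(0.95, 1))   # 3.841...

# quantity registry: how to read each named quantity off a parameter set
_UNI_QUANTITIES = {
    "A": lambda p: p.A, "C": lambda p: p.C, "E": lambda p: p.E,
    "mean": lambda p: p.mean,
}
_BIV_QUANTITIES = {
    "rA": lambda p: p.r_a, "rC": lambda p: p.r_c, "rE": lambda p: p.r_e,
    "rPh": lambda p: p.r_ph,
    "bivA": lambda p: p.covariance_shares()["A"],
    "bivC": lambda p: p.covariance_shares()["C"],
    "bivE": lambda p: p.covariance_shares()["E"],
    "A1": lambda p: p.standardized_components(1)["A"],
    "E1": lambda p: p.standardized_components(1)["E"],
    "A2": lambda p: p.standardized_components(2)["A"],
    "E2": lambda p: p.standardized_components(2)["E"],
}
_DOMAINS = {"A": (0.0, 1.0), "C": (0.0, 1.0), "E": (0.0, 1.0),
            "rA": (-1.0, 1.0), "rC": (-1.0, 1.0), "rE": (-1.0, 1.0),
            "rPh": (-1.0, 1.0),
            "A1": (0.0, 1.0), "E1": (0.0, 1.0),
            "A2": (0.0, 1.0), "E2": (0.0, 1.0)}
# component-correlation quantities are single transformed parameters: profile
# them by fixing the parameter rather than via an equality constraint
_PARAM_QUANTITIES = {"rA": "r_a", "rC": "r_c", "rE": "r_e", "mean": "mean"}


def quantity_value(fit: FitResult, quantity: str) -> float:
    table = _UNI_QUANTITIES if fit._ctx.get("kind") == "uni" else _BIV_QUANTITIES
    return float(table[quantity](fit.params))


def _profile_fixed_param(fit: FitResult, pname: str, value: float,
                         warm: np.ndarray | None = None) -> float:
    ctx = fit._ctx
    names = ctx["names"]
    idx = names.index(pname)
    fixed_t = (float(np.arctanh(np.clip(value, -0.9999999, 0.9999999)))
               if pname in _CORR_NAMES else float(value))
    free_idx = [i for i in range(len(names)) if i != idx]
    if warm is None:
        warm = ctx.setdefault("_warm", {}).get(pname, ctx["theta"])
    theta0 = warm.copy()

    make = _uni_params if ctx["kind"] == "uni" else _biv_params

    def fun(free):
        theta = theta0.copy()
        theta[free_idx] = free
        theta[idx] = fixed_t
        params = make(ctx["model"], theta)
        obj = _uni_neg2ll if ctx["kind"] == "uni" else _biv_neg2ll
        return obj(params, ctx["groups"])

    res = optimize.minimize(fun, theta0[free_idx], method="L-BFGS-B",
                            options={"maxiter": 500, "ftol": 1e-13})
    full = theta0.copy()
    full[free_idx] = res.x
    full[idx] = fixed_t
    ctx.setdefault("_warm", {})[pname] = full
    return float(res.fun)


def _profile_constrained(fit: FitResult, quantity: str, value: float) -> float:
    ctx = fit._ctx
    make = _uni_params if ctx["kind"] == "uni" else _biv_params
    obj = _uni_neg2ll if ctx["kind"] == "uni" else _biv_neg2ll
    table = _UNI_QUANTITIES if ctx["kind"] == "uni" else _BIV_QUANTITIES
    qfn = table[quantity]

    def fun(theta):
        return obj(make(ctx["model"], theta), ctx["groups"])

    def cons(theta):
        return qfn(make(ctx["model"], theta)) - value

    # warm-start from the last profiled solution for this quantity: CI
    # root-finding evaluates many nearby constraint values in sequence
    warm = ctx.setdefault("_warm", {})
    x0 = warm.get(quantity, ctx["theta"]).copy()
    res = optimize.minimize(fun, x0, method="SLSQP",
                            constraints=[{"type": "eq", "fun": cons}],
                            options={"maxiter": 300, "ftol": 1e-12})
    if res.success and abs(cons(res.x)) <= 1e-6:
        warm[quantity] = res.x.copy()
        return float(res.fun)
    # quadratic-penalty retry with increasing weight (more robust than
    # SLSQP when the constraint surface is poorly scaled)
    x = ctx["theta"].copy()
    for weight in (1e4, 1e6, 1e8):
        pen = optimize.minimize(
            lambda th: fun(th) + weight * cons(th) ** 2, x,
            method="L-BFGS-B", options={"maxiter": 500, "ftol": 1e-13})
        x = pen.x
    if abs(cons(x)) <= 1e-5:
        return float(fun(x))
    raise FitError(f"constrained profiling of {quantity} at {value} failed")


_MODEL_COMPONENTS = {"ACE": ("A", "C", "E"), "AE": ("A", "E"),
                     "CE": ("C", "E"), "E": ("E",)}


def _profile_uni_proportion(fit: FitResult, comp: str, q: float) -> float:
    """Profile -2lnL with a standardized component fixed at ``q``.

    Reparameterizes the univariate model as (mean, log total variance,
    mixing of the remaining components), which makes the fixed proportion
    exact (including q = 0) and keeps the optimization unconstrained.
    """
    ctx = fit._ctx
    comps = _MODEL_COMPONENTS[ctx["model"]]
    if comp not in comps:
        raise ValueError(f"{comp} is not free in the {ctx['model']} model")
    others = [c for c in comps if c != comp]
    p = fit.params
    mle_props = p.proportions()
    x0 = [p.mean, math.log(p.variance)]
    if len(others) == 2:
        rem = mle_props[others[0]] + mle_props[others[1]]
        share = mle_props[others[0]] / rem if rem > 1e-12 else 0.5
        share = min(max(share, 1e-6), 1 - 1e-6)
        x0.append(math.log(share / (1.0 - share)))

    def build(tf):
        props = dict.fromkeys(("A", "C", "E"), 0.0)
        props[comp] = q
        rem = 1.0 - q
        if len(others) == 1:
            props[others[0]] = rem
        else:
            s = float(stats.logistic.cdf(tf[2]))
            props[others[0]] = rem * s
            props[others[1]] = rem * (1.0 - s)
        v = math.exp(tf[1])
        return UnivariateACEParams(a=math.sqrt(props["A"] * v),
                                   c=math.sqrt(props["C"] * v),
                                   e=math.sqrt(props["E"] * v), mean=tf[0])

    def fun(tf):
        return _uni_neg2ll(build(tf), ctx["groups"])

    res = optimize.minimize(fun, np.array(x0), method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10,
                                     "maxiter": 2000})
    return float(res.fun)


def profile_deviance(fit: FitResult, quantity: str, value: float) -> float:
    """Constrained -2lnL at ``quantity == value`` minus the optimum.

    The 95% profile CI is exactly the set of values with deviance at most
    3.841, so this is also the cheap way to test whether a value is covered.
    """
    ctx = fit._ctx
    if ctx["kind"] == "uni" and quantity in ("A", "C", "E"):
        prof = _profile_uni_proportion(fit, quantity, value)
    elif quantity in _PARAM_QUANTITIES and _PARAM_QUANTITIES[quantity] in ctx["names"]:
        prof = _profile_fixed_param(fit, _PARAM_QUANTITIES[quantity], value)
    else:
        prof = _profile_constrained(fit, quantity, value)
    return max(prof - fit.minus2ll, 0.0)


def _delta_method_ci(fit: FitResult, quantity: str, level: float):
    """Wald fallback: quadratic approximation from the -2lnL Hessian."""
    ctx = fit._ctx
    make = _uni_params if ctx["kind"] == "uni" else _biv_params
    obj = _uni_neg2ll if ctx["kind"] == "uni" else _biv_neg2ll
    table = _UNI_QUANTITIES if ctx["kind"] == "uni" else _BIV_QUANTITIES

    def fun(theta):
        return obj(make(ctx["model"], theta), ctx["groups"])

    hess = finite_difference_hessian(fun, ctx["theta"])
    cov = 2.0 * np.linalg.pinv(hess)   # Var(theta) = inv(info), info = H/2
    qfn = table[quantity]
    th = ctx["theta"]
    grad = np.zeros(th.size)
    for i in range(th.size):
        h = 1e-5 * max(1.0, abs(th[i]))
        tp = th.copy(); tp[i] += h
        tm = th.copy(); tm[i] -= h
        grad[i] = (qfn(make(ctx["model"], tp)) - qfn(make(ctx["model"], tm))) / (2 * h)
    se = math.sqrt(max(float(grad @ cov @ grad), 0.0))
    z = stats.norm.ppf(0.5 + level / 2.0)
    qhat = quantity_value(fit, quantity)
    return qhat - z * se, qhat + z * se


def likelihood_ci(fit: FitResult, quantity: str,
                  level: float = 0.95) -> tuple[float, float]:
    """Profile-likelihood confidence interval for a parameter or derived
    quantity; bounds on the parameter-space boundary are flagged in
    ``fit.ci_flags``."""
    if not fit.converged:
        raise FitError("fit did not converge; no CI available")
    crit = float(stats.chi2.ppf(level, 1))
    qhat = quantity_value(fit, quantity)
    lo_dom, hi_dom = _DOMAINS.get(quantity, (-math.inf, math.inf))

    def gap(v):
        return profile_deviance(fit, quantity, v) - crit

    bounds = []
    for direction in (-1.0, 1.0):
        dom = lo_dom if direction < 0 else hi_dom
        try:
            bounds.append(_search_bound(gap, qhat, direction, dom))
        except FitError:
            logger.warning("profiling failed for %s; delta-method fallback",
                           quantity)
            lo, hi = _delta_method_ci(fit, quantity, level)
            fit.ci_flags[quantity] = "delta-method"
            return (max(lo, lo_dom), min(hi, hi_dom))
    (lo, lo_flag), (hi, hi_flag) = bounds
    if lo_flag or hi_flag:
        fit.ci_flags[quantity] = "boundary"
    return (lo, hi)


def _search_bound(gap, qhat: float, direction: float, domain_edge: float,
                  xtol: float = 1e-4):
    """Expand outward from the MLE until the deviance crosses the critical
    value, then root-find; returns (bound, hit_boundary)."""
    step = 0.05 * max(1.0, abs(qhat))
    prev = qhat
    for _ in range(60):
        cand = prev + direction * step
        hit_edge = ((direction < 0 and cand <= domain_edge)
                    or (direction > 0 and cand >= domain_edge))
        if hit_edge:
            cand = domain_edge
        g = gap(cand)
        if g >= 0.0:
            lo, hi = (cand, prev) if direction < 0 else (prev, cand)
            root = optimize.brentq(gap, lo, hi, xtol=xtol)
            return float(root), False
        if hit_edge:
            return float(domain_edge), True
        prev = cand
        step *= 1.7
    raise FitError("could not bracket the profile-CI bound")


# ---------------------------------------------------------------------------
# serialization


def fit_to_dict(fit: FitResult) -> dict:
    """Machine-readable fit dump (for reports and regression tests)."""
    p = fit.params
    if isinstance(p, UnivariateACEParams):
        params = {"a": p.a, "c": p.c, "e": p.e, "mean": p.mean,
                  "A": p.A, "C": p.C, "E": p.E}
    else:
        params = {"a1": p.a1, "c1": p.c1, "e1": p.e1, "a2": p.a2,
                  "c2": p.c2, "e2": p.e2, "rA": p.r_a, "rC": p.r_c,
                  "rE": p.r_e, "mean1": p.mean1, "mean2": p.mean2,
                  "rPh": p.r_ph}
        try:
            params.update({f"biv{k}": v for k, v in p.covariance_shares().items()})
        except ZeroDivisionError:
            pass
    return {"model": fit.model, "minus2ll": fit.minus2ll,
            "n_free_params": fit.n_free_params, "params": params,
            "ci95": {k: list(v) for k, v in fit.ci95.items()},
            "ci_flags": dict(fit.ci_flags),
            "convergence": dict(fit.convergence)}
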