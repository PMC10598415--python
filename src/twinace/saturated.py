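"""Saturated and constrained-saturated multivariate-normal twin models.

The saturated model estimates a free mean vector and covariance matrix per
zygosity group; the *constrained* saturated model equates means and
variances across twin order and ties the correlation structure to be
symmetric under swapping the twins (for two traits this equates the two
within-person cross-trait correlations and the two cross-twin cross-trait
correlations).  These fits provide the assumption tests (equality of
means/variances across twin order and zygosity) and the twin and
cross-twin cross-trait (CTCT) correlations with profile-likelihood CIs.

Variables are ordered twin-major: for traits ``(x, y)`` the per-pair
vector is ``(x_twin1, y_twin1, x_twin2, y_twin2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from ._mvn import NONPD_PENALTY, neg2_loglik, split_patterns
from .data_io import CohortTable

ORDER_CONSTRAINTS = frozenset({"order_means", "order_variances",
                               "order_correlations"})
ALL_CONSTRAINTS = ORDER_CONSTRAINTS | {"zygosity_means", "zygosity_variances"}


class SaturatedFitError(RuntimeError):
    pass


@dataclass
class CorrelationEstimate:
    label: str
    zygosity: str
    estimate: float
    ci95: tuple[float, float]
    boundary: bool = False


@dataclass
class SaturatedEstimates:
    groups: list[str]
    means: dict[str, np.ndarray]
    covariances: dict[str, np.ndarray]
    constraints: frozenset[str]
    minus2ll: float
    n_free_params: int
    n_pairs: dict[str, int]
    _ctx: dict = field(default_factory=dict, repr=False)

    def correlation(self, group: str, i: int, j: int) -> float:
        cov = self.covariances[group]
        return float(cov[i, j] / math.sqrt(cov[i, i] * cov[j, j]))


@dataclass
class ModelComparison:
    constrained: str
    delta_minus2ll: float
    delta_df: int
    p_value: float


# ---------------------------------------------------------------------------
# parameter tying


def _corr_pairs(dim: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(dim) for j in range(i + 1, dim)]


def _swap_index(idx: int, n_traits: int) -> int:
    """Index of the same trait on the co-twin (twin-major layout)."""
    return (idx + n_traits) % (2 * n_traits)


def _canonical_slots(groups: list[str], n_traits: int,
                     constraints: frozenset[str]):
    """Map every (group, slot) onto a canonical free-parameter key."""
    dim = 2 * n_traits
    keymap: dict[tuple, tuple] = {}

    def canon_group(g: str, kind: str) -> str:
        if kind == "mean" and "zygosity_means" in constraints:
            return "*"
        if kind == "lsd" and "zygosity_variances" in constraints:
            return "*"
        return g

    for g in groups:
        for idx in range(dim):
            trait = idx % n_traits
            i = trait if "order_means" in constraints else idx
            keymap[(g, "mean", idx)] = (canon_group(g, "mean"), "mean", i)
            i = trait if "order_variances" in constraints else idx
            keymap[(g, "lsd", idx)] = (canon_group(g, "lsd"), "lsd", i)
        for (i, j) in _corr_pairs(dim):
            if "order_correlations" in constraints:
                si, sj = sorted((_swap_index(i, n_traits),
                                 _swap_index(j, n_traits)))
                pair = min((i, j), (si, sj))
            else:
                pair = (i, j)
            keymap[(g, "z", (i, j))] = (g, "z", pair)
    keys = sorted(set(keymap.values()), key=repr)
    index = {k: n for n, k in enumerate(keys)}
    return keymap, keys, index


def _group_data(cohort: CohortTable, traits, pool_dz: bool):
    if isinstance(traits, str):
        traits = [traits]
    if pool_dz:
        labels = [("MZ", ("MZ",)), ("DZ", ("DZ_SS", "DZ_OS"))]
    else:
        labels = [("MZ", ("MZ",)), ("DZ_SS", ("DZ_SS",)), ("DZ_OS", ("DZ_OS",))]
    out = []
    for label, zygs in labels:
        X = cohort.pair_matrix(traits, zygosities=zygs)
        X = X[~np.isnan(X).all(axis=1)]
        if X.shape[0] > 0:
            out.append((label, X, split_patterns(X)))
    if not out:
        raise SaturatedFitError("no data in any zygosity group")
    return traits, out


def _start_values(data, n_traits: int):
    """Complete-case moments per group (symmetrization happens via tying)."""
    dim = 2 * n_traits
    starts = {}
    for label, X, _ in data:
        comp = X[~np.isnan(X).any(axis=1)]
        if comp.shape[0] >= dim + 2:
            mu = comp.mean(axis=0)
            cov = np.cov(comp.T, ddof=0)
            sd = np.sqrt(np.clip(np.diag(cov), 1e-8, None))
            r = cov / np.outer(sd, sd)
        else:
            mu = np.zeros(dim)
            sd = np.ones(dim)
            r = np.full((dim, dim), 0.2) + 0.8 * np.eye(dim)
        starts[label] = (mu, sd, r)
    return starts


def fit_saturated(cohort: CohortTable, traits=None,
                  constraints=ORDER_CONSTRAINTS,
                  pool_dz: bool = True) -> SaturatedEstimates:
    """FIML fit of the (constrained) saturated model.

    ``constraints`` is a subset of
    ``{"order_means", "order_variances", "order_correlations",
    "zygosity_means", "zygosity_variances"}``; the default is the
    constrained saturated model (equality across twin order, correlations
    free per group).  With no constraints and complete data the estimates
    equal the closed-form group sample moments.
    """
    constraints = frozenset(constraints)
    unknown = constraints - ALL_CONSTRAINTS
    if unknown:
        raise ValueError(f"unknown constraints: {sorted(unknown)}")
    traits = cohort.trait_names if traits is None else traits
    traits, data = _group_data(cohort, traits, pool_dz)
    n_traits = len(traits)
    dim = 2 * n_traits
    groups = [label for label, _, _ in data]
    keymap, keys, index = _canonical_slots(groups, n_traits, constraints)

    starts = _start_values(data, n_traits)
    x0 = np.zeros(len(keys))
    counts = np.zeros(len(keys))
    for g in groups:
        mu, sd, r = starts[g]
        for idx in range(dim):
            k = index[keymap[(g, "mean", idx)]]
            x0[k] += mu[idx]; counts[k] += 1
            k = index[keymap[(g, "lsd", idx)]]
            x0[k] += math.log(sd[idx]); counts[k] += 1
        for (i, j) in _corr_pairs(dim):
            k = index[keymap[(g, "z", (i, j))]]
            x0[k] += float(np.arctanh(np.clip(r[i, j], -0.99, 0.99)))
            counts[k] += 1
    x0 /= np.maximum(counts, 1)

    def unpack(theta, g):
        mu = np.array([theta[index[keymap[(g, "mean", i)]]] for i in range(dim)])
        sd = np.exp([theta[index[keymap[(g, "lsd", i)]]] for i in range(dim)])
        R = np.eye(dim)
        for (i, j) in _corr_pairs(dim):
            R[i, j] = R[j, i] = math.tanh(theta[index[keymap[(g, "z", (i, j))]]])
        return mu, np.outer(sd, sd) * R

    def fun(theta):
        total = 0.0
        for label, _, pats in data:
            mu, sigma = unpack(theta, label)
            total += neg2_loglik(mu, sigma, pats)
        return total

    res = optimize.minimize(fun, x0, method="L-BFGS-B",
                            options={"maxiter": 2000, "ftol": 1e-13,
                                     "gtol": 1e-8})
    if res.fun >= NONPD_PENALTY / 2:
        raise SaturatedFitError(f"saturated fit failed: {res.message}")
    means, covs, n_pairs = {}, {}, {}
    for label, X, _ in data:
        mu, sigma = unpack(res.x, label)
        means[label], covs[label] = mu, sigma
        n_pairs[label] = X.shape[0]
    return SaturatedEstimates(
        groups=groups, means=means, covariances=covs, constraints=constraints,
        minus2ll=float(res.fun), n_free_params=len(keys), n_pairs=n_pairs,
        _ctx={"fun": fun, "theta": res.x.copy(), "index": index,
              "keymap": keymap, "dim": dim, "n_traits": n_traits,
              "groups": groups, "unpack": unpack})


# ---------------------------------------------------------------------------
# equality assumption tests

_CASCADE = {
    "order_means": (frozenset(), frozenset({"order_means"})),
    "order_variances": (frozenset({"order_means"}),
                        frozenset({"order_means", "order_variances"})),
    "zygosity_means": (ORDER_CONSTRAINTS,
                       ORDER_CONSTRAINTS | {"zygosity_means"}),
    "zygosity_variances": (ORDER_CONSTRAINTS | {"zygosity_means"},
                           ORDER_CONSTRAINTS | {"zygosity_means",
                                                "zygosity_variances"}),
}


def test_equality(cohort: CohortTable, which: str, traits=None,
                  pool_dz: bool = False) -> ModelComparison:
    """LRT of one equality assumption in the standard testing cascade.

    Each test adds its constraint on top of the previously accepted ones
    (twin-order equality before zygosity equality); the p-value comes from
    the chi-square distribution with df equal to the number of parameters
    removed.
    """
    if which not in _CASCADE:
        raise ValueError(f"which must be one of {sorted(_CASCADE)}")
    base_c, full_c = _CASCADE[which]
    base = fit_saturated(cohort, traits, constraints=base_c, pool_dz=pool_dz)
    constrained = fit_saturated(cohort, traits, constraints=full_c,
                                pool_dz=pool_dz)
    delta = max(constrained.minus2ll - base.minus2ll, 0.0)
    ddf = base.n_free_params - constrained.n_free_params
    return ModelComparison(which, delta, ddf,
                           float(stats.chi2.sf(delta, ddf)) if delta > 0 else 1.0)


# ---------------------------------------------------------------------------
# correlations with profile-likelihood CIs

_CHI2_95 = float(stats.chi2.ppf(0.95, 1))


def _profile_corr_ci(fit: SaturatedEstimates, key: tuple,
                     level: float = 0.95) -> tuple[float, float, bool]:
    """Profile CI for one tied correlation parameter (by canonical key)."""
    ctx = fit._ctx
    idx = ctx["index"][key]
    theta_hat = ctx["theta"]
    fun = ctx["fun"]
    crit = float(stats.chi2.ppf(level, 1))
    free = [i for i in range(theta_hat.size) if i != idx]

    def profile(r):
        z = float(np.arctanh(np.clip(r, -0.9999999, 0.9999999)))

        def f(sub):
            theta = theta_hat.copy()
            theta[free] = sub
            theta[idx] = z
            return fun(theta)

        res = optimize.minimize(f, theta_hat[free], method="L-BFGS-B",
                                options={"maxiter": 500, "ftol": 1e-13})
        return float(res.fun)

    r_hat = float(math.tanh(theta_hat[idx]))

    def gap(r):
        return profile(r) - fit.minus2ll - crit

    bounds = []
    boundary = False
    for direction in (-1.0, 1.0):
        edge = -1.0 if direction < 0 else 1.0
        prev, step = r_hat, 0.04
        root = None
        for _ in range(40):
            cand = prev + direction * step
            hit = cand * direction >= edge * direction
            if hit:
                cand = edge - direction * 1e-6
            if gap(cand) >= 0:
                lo, hi = (cand, prev) if direction < 0 else (prev, cand)
                root = float(optimize.brentq(gap, lo, hi, xtol=1e-4))
                break
            if hit:
                root, boundary = edge, True
                break
            prev = cand
            step *= 1.6
        if root is None:
            raise SaturatedFitError("could not bracket correlation CI bound")
        bounds.append(root)
    return bounds[0], bounds[1], boundary


def _corr_key(fit: SaturatedEstimates, group: str, i: int, j: int) -> tuple:
    return fit._ctx["keymap"][(group, "z", (min(i, j), max(i, j)))]


def twin_correlations(cohort: CohortTable, trait: str | None = None,
                      pool_dz: bool = True,
                      ci: bool = True) -> list[CorrelationEstimate]:
    """Twin correlations per zygosity from the constrained saturated model
    (means and variances equated across twin order within group)."""
    trait = cohort.trait_names[0] if trait is None else trait
    fit = fit_saturated(cohort, trait, constraints=ORDER_CONSTRAINTS,
                        pool_dz=pool_dz)
    out = []
    for g in fit.groups:
        est = fit.correlation(g, 0, 1)
        lo, hi, boundary = (_profile_corr_ci(fit, _corr_key(fit, g, 0, 1))
                            if ci else (math.nan, math.nan, False))
        out.append(CorrelationEstimate(f"{trait} twin correlation ({g})", g,
                                       est, (lo, hi), boundary))
    return out


def ctct_correlations(cohort: CohortTable, traits=None, pool_dz: bool = True,
                      ci: bool = True) -> list[CorrelationEstimate]:
    """Cross-twin cross-trait correlations per zygosity, symmetrized across
    twin order via the constrained saturated bivariate model."""
    traits = cohort.trait_names[:2] if traits is None else list(traits)
    if len(traits) != 2:
        raise ValueError("need exactly two traits")
    fit = fit_saturated(cohort, traits, constraints=ORDER_CONSTRAINTS,
                        pool_dz=pool_dz)
    out = []
    for g in fit.groups:
        est = fit.correlation(g, 0, 3)   # trait1 twin1 x trait2 twin2
        lo, hi, boundary = (_profile_corr_ci(fit, _corr_key(fit, g, 0, 3))
                            if ci else (math.nan, math.nan, False))
        out.append(CorrelationEstimate(
            f"CTCT {traits[0]} x {traits[1]} ({g})", g, est, (lo, hi),
            boundary))
    return out


def bivariate_correlation_table(cohort: CohortTable, traits=None,
                                pool_dz: bool = True, ci: bool = True):
    """Per-zygosity twin correlations for both traits plus the CTCT
    correlation, from one constrained saturated bivariate fit."""
    import pandas as pd

    traits = cohort.trait_names[:2] if traits is None else list(traits)
    fit = fit_saturated(cohort, traits, constraints=ORDER_CONSTRAINTS,
                        pool_dz=pool_dz)
    rows = []
    labels = [(traits[0], 0, 2), (traits[1], 1, 3), ("CTCT", 0, 3)]
    for g in fit.groups:
        for name, i, j in labels:
            est = fit.correlation(g, i, j)
            if ci:
                lo, hi, _ = _profile_corr_ci(fit, _corr_key(fit, g, i, j))
            else:
                lo = hi = math.nan
            rows.append({"group": g, "correlation": name, "estimate": est,
                         "lo95": lo, "hi95": hi})
    return pd.DataFrame(rows)
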