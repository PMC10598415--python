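"""Synthetic twin cohorts with a specified A/C/E covariance structure.

Cohorts are drawn directly from the implied per-pair multivariate-normal
covariance (see :mod:`twinace.acecov`), which makes the implied-covariance
algebra the single source of truth shared with the ML likelihoods.
Realism layers — ordinal score discretization, sex/birth-year covariate
effects, MCAR missingness, item-level response generation — are separate,
composable operations, so recovery tests can run on the clean continuous
phenotypes while pipeline tests exercise the full chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from . import conditions
from .acecov import bivariate_pair_cov, kinship_coefficient, univariate_pair_cov
from .data_io import CohortTable, Twin, TwinPairRecord


def _check_components(a2: float, c2: float, e2: float, label: str = "") -> None:
    if min(a2, c2, e2) < 0:
        raise ValueError(f"negative variance proportion in {label or 'spec'}")
    if abs(a2 + c2 + e2 - 1.0) > 1e-9:
        raise ValueError(f"variance proportions must sum to 1 in {label or 'spec'}")


@dataclass(frozen=True)
class UnivariateSimSpec:
    """Generating spec for one standardized phenotype.

    ``a2 + c2 + e2`` must equal 1; ``n_dz`` are same-sex DZ pairs and
    ``n_dz_os`` opposite-sex DZ pairs (modelled identically, kept distinct
    for cohort-composition realism).
    """

    a2: float
    c2: float
    e2: float
    n_mz: int
    n_dz: int
    n_dz_os: int = 0
    seed: int = 0
    trait: str = "trait"

    def __post_init__(self) -> None:
        _check_components(self.a2, self.c2, self.e2, self.trait)

    @property
    def paths(self) -> tuple[float, float, float]:
        return (math.sqrt(self.a2), math.sqrt(self.c2), math.sqrt(self.e2))


@dataclass(frozen=True)
class BivariateSimSpec:
    """Generating spec for two standardized phenotypes with component
    correlations r_a, r_c, r_e between same-named factors."""

    a2_1: float
    c2_1: float
    e2_1: float
    a2_2: float
    c2_2: float
    e2_2: float
    r_a: float
    r_c: float
    r_e: float
    n_mz: int
    n_dz: int
    n_dz_os: int = 0
    seed: int = 0
    traits: tuple[str, str] = ("trait1", "trait2")

    def __post_init__(self) -> None:
        _check_components(self.a2_1, self.c2_1, self.e2_1, self.traits[0])
        _check_components(self.a2_2, self.c2_2, self.e2_2, self.traits[1])
        for name, r in (("r_a", self.r_a), ("r_c", self.r_c), ("r_e", self.r_e)):
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"{name} must lie in [-1, 1]")
        for zyg in ("MZ", "DZ"):
            cov = implied_pair_covariance(self, zyg)
            lam = np.linalg.eigvalsh(cov)
            if lam[0] < -1e-10:
                raise ValueError(
                    "implied pair covariance not PSD for "
                    f"{zyg}; check r_a={self.r_a}, r_c={self.r_c}, r_e={self.r_e}")

    @property
    def paths1(self) -> tuple[float, float, float]:
        return (math.sqrt(self.a2_1), math.sqrt(self.c2_1), math.sqrt(self.e2_1))

    @property
    def paths2(self) -> tuple[float, float, float]:
        return (math.sqrt(self.a2_2), math.sqrt(self.c2_2), math.sqrt(self.e2_2))


def implied_pair_covariance(spec, zygosity: str) -> np.ndarray:
    """Implied per-pair covariance (2x2 univariate, 4x4 bivariate).

    Unit diagonal by construction since component proportions sum to 1.
    """
    k_a = kinship_coefficient(zygosity)
    if isinstance(spec, UnivariateSimSpec):
        return univariate_pair_cov(*spec.paths, k_a=k_a)
    if isinstance(spec, BivariateSimSpec):
        return bivariate_pair_cov(spec.paths1, spec.paths2,
                                  spec.r_a, spec.r_c, spec.r_e, k_a=k_a)
    raise TypeError(f"unsupported spec type {type(spec).__name__}")


def _spec_traits(spec) -> list[str]:
    if isinstance(spec, UnivariateSimSpec):
        return [spec.trait]
    return list(spec.traits)


def simulate_pairs(spec, seed: int | None = None) -> CohortTable:
    """Draw a cohort from the implied pair covariance; deterministic per seed.

    Sexes follow the study's per-group female fractions (opposite-sex DZ
    pairs get discordant sexes) and birth years are uniform over the cohort
    window, so downstream covariate operations have realistic inputs.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    traits = _spec_traits(spec)
    records: list[TwinPairRecord] = []
    lo, hi = conditions.BIRTH_YEARS
    for zyg, n in (("MZ", spec.n_mz), ("DZ_SS", spec.n_dz), ("DZ_OS", spec.n_dz_os)):
        if n <= 0:
            continue
        cov = implied_pair_covariance(spec, zyg)
        draws = rng.multivariate_normal(np.zeros(cov.shape[0]), cov,
                                        size=n, method="cholesky")
        years = rng.integers(lo, hi + 1, size=n)
        if zyg == "DZ_OS":
            first_female = rng.random(n) < 0.5
            sexes = [("F", "M") if f else ("M", "F") for f in first_female]
        else:
            p_f = conditions.FEMALE_FRACTION.get(zyg, 0.5)
            same = np.where(rng.random(n) < p_f, "F", "M")
            sexes = [(s, s) for s in same]
        k = len(traits)
        for i in range(n):
            twins = []
            for w in range(2):
                ph = {t: float(draws[i, w * k + j]) for j, t in enumerate(traits)}
                twins.append(Twin(sex=sexes[i][w], birth_year=int(years[i]),
                                  phenotypes=ph))
            records.append(TwinPairRecord(f"{zyg.lower()}_{i:05d}", zyg,
                                          *twins))
    return CohortTable(records, traits,
                       provenance=f"simulated ({type(spec).__name__})")


def discretize_to_scale(latent, thresholds, levels) -> np.ndarray:
    """Map latent values onto ordinal levels via ordered cut points.

    A value exactly at a threshold goes to the upper level (closed-below
    convention).  Missing propagates.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    levels = np.asarray(levels, dtype=float)
    if levels.size != thresholds.size + 1:
        raise ValueError("need len(levels) == len(thresholds) + 1")
    if thresholds.size and np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be strictly increasing")
    arr = np.asarray(latent, dtype=float)
    out = np.full(arr.shape, np.nan)
    obs = ~np.isnan(arr)
    idx = np.searchsorted(thresholds, arr[obs], side="right")
    out[obs] = levels[idx]
    return out


def calibrate_thresholds(levels, mean: float, sd: float) -> np.ndarray:
    """Standard-normal cut points whose induced marginal matches mean/sd.

    Fits a zero-inflated truncated-geometric distribution over ``levels``
    (the right-skewed shape of sum-of-rare-endorsements scores) to the two
    target moments and converts its cumulative probabilities to cut points.
    Used once to ship the default screening thresholds; available for
    calibrating other ordinal scales.
    """
    levels = np.asarray(levels, dtype=float)
    m = levels.size - 1

    def probs(x):
        pi = 1.0 / (1.0 + np.exp(-x[0]))
        rho = 1.0 / (1.0 + np.exp(-x[1]))
        p = np.empty(levels.size)
        p[0] = pi
        j = np.arange(1, levels.size)
        p[1:] = (1 - pi) * (1 - rho) * rho ** (j - 1) / (1 - rho ** m)
        return p

    def eqs(x):
        p = probs(x)
        mu = float(p @ levels)
        var = float(p @ levels ** 2) - mu ** 2
        return [mu - mean, math.sqrt(max(var, 0.0)) - sd]

    x, info, ok, msg = optimize.fsolve(eqs, [0.0, 0.0], full_output=True)
    if ok != 1:
        raise RuntimeError(f"threshold calibration failed: {msg}")
    cum = np.cumsum(probs(x))[:-1]
    return stats.norm.ppf(cum)


def discretize_trait(cohort: CohortTable, trait: str,
                     thresholds=None, levels=None) -> CohortTable:
    """Replace a (standard-normal) trait by its ordinal screening version."""
    thresholds = conditions.SYNAESTHESIA_THRESHOLDS if thresholds is None else thresholds
    levels = conditions.SYNAESTHESIA_LEVELS if levels is None else levels
    frame = cohort.individual_frame()
    vals = discretize_to_scale(frame[trait].to_numpy(), thresholds, levels)
    return cohort.with_transformed_trait(trait, vals)


def add_covariate_effects(cohort: CohortTable, sex_effect: float,
                          year_effect: float, traits=None) -> CohortTable:
    """Add linear sex / birth-year shifts to phenotype values.

    ``sex_effect`` is the male-minus-female mean shift in sd units;
    ``year_effect`` is per year, centred on the cohort's midpoint year so
    the grand mean is unchanged.  Deterministic (no randomness involved).
    """
    traits = list(cohort.trait_names) if traits is None else list(traits)
    mid = sum(conditions.BIRTH_YEARS) / 2.0
    out = cohort
    for t in traits:
        frame = out.individual_frame()
        male = (frame["sex"] == "M").to_numpy(dtype=float)
        yr = frame["birth_year"].to_numpy(dtype=float)
        shift = sex_effect * male + year_effect * (yr - mid)
        out = out.with_transformed_trait(t, frame[t].to_numpy() + shift)
    return out


def inject_missingness(cohort: CohortTable, rate: float, seed: int,
                       traits=None) -> CohortTable:
    """Set phenotype cells missing independently with probability ``rate``
    (missing completely at random)."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    if rate == 0.0:
        return cohort
    rng = np.random.default_rng(seed)
    traits = list(cohort.trait_names) if traits is None else list(traits)
    out = cohort
    for t in traits:
        frame = out.individual_frame()
        vals = frame[t].to_numpy(dtype=float)
        vals = np.where(rng.random(vals.size) < rate, np.nan, vals)
        out = out.with_transformed_trait(t, vals)
    return out


def simulate_item_responses(latent, items=None, loading: float = 0.74,
                            cuts: tuple[float, float] = (1.2, 1.8),
                            seed: int = 0):
    """Graded item responses {0, 0.5, 1} from a latent liability.

    Each item's propensity is ``loading * z + sqrt(1 - loading^2) * noise``;
    values above ``cuts[0]`` score 0.5 and above ``cuts[1]`` score 1.  With
    the defaults, eight items give a rare-endorsement sum score resembling
    the screening distribution, and the common loading of 0.74 (calibrated
    on a standard-normal liability) puts the 8-item Cronbach alpha near the
    instrument's reported 0.79.
    """
    import pandas as pd

    items = conditions.SCREENING_ITEMS if items is None else list(items)
    z = np.asarray(latent, dtype=float)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((z.size, len(items)))
    prop = loading * z[:, None] + math.sqrt(1.0 - loading ** 2) * noise
    codes = np.where(prop >= cuts[1], 1.0, np.where(prop >= cuts[0], 0.5, 0.0))
    codes[np.isnan(prop)] = np.nan
    from .preprocess import ItemResponseMatrix
    return ItemResponseMatrix(pd.DataFrame(codes, columns=items))


@dataclass
class PowerEstimate:
    component: str
    power: float
    ci_low: float
    ci_high: float
    n_reps: int
    alpha: float


def power_by_simulation(spec: UnivariateSimSpec, n_reps: int = 200,
                        alpha: float = 0.05, component: str = "A",
                        seed: int = 0) -> PowerEstimate:
    """Simulation-based power of the LRT dropping one variance component.

    For component A, each replicate compares the ACE fit with the CE fit
    (A fixed at zero); for C, ACE vs AE.  The naive chi-square(1) p-value is
    used, matching the study's convention (conservative at the boundary).
    """
    from statsmodels.stats.proportion import proportion_confint

    from .biometric import compare_nested, fit_univariate

    if n_reps < 100:
        raise ValueError("need at least 100 replicates")
    if component not in ("A", "C"):
        raise ValueError("component must be 'A' or 'C'")
    reduced = "CE" if component == "A" else "AE"
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        rep_seed = int(rng.integers(2 ** 31))
        cohort = simulate_pairs(spec, seed=rep_seed)
        full = fit_univariate(cohort, spec.trait, model="ACE", ci=())
        nested = fit_univariate(cohort, spec.trait, model=reduced, ci=())
        comp = compare_nested(full, nested)
        rejections += int(comp.p_value < alpha)
    lo, hi = proportion_confint(rejections, n_reps, alpha=0.05, method="wilson")
    return PowerEstimate(component, rejections / n_reps, float(lo), float(hi),
                         n_reps, alpha)


# ---------------------------------------------------------------------------
# study-condition spec factories


def study_univariate_spec(seed: int = 0) -> UnivariateSimSpec:
    """Synaesthesia-score spec at the study's composition and AE structure."""
    ace = conditions.SYNAESTHESIA_ACE
    return UnivariateSimSpec(ace["a2"], ace["c2"], ace["e2"],
                             n_mz=conditions.N_MZ, n_dz=conditions.N_DZ_SS,
                             n_dz_os=conditions.N_DZ_OS, seed=seed,
                             trait="synaesthesia")


def study_bivariate_spec(trait: str, seed: int = 0,
                         n_mz: int | None = None, n_dz: int | None = None,
                         n_dz_os: int | None = None) -> BivariateSimSpec:
    """Synaesthesia x autistic-trait spec at the study conditions.

    ``trait`` is one of ``total_autistic_traits``, ``rrbid``, ``sic``.
    """
    if trait not in conditions.TRAIT_ACE:
        raise KeyError(f"unknown trait {trait!r}; options: "
                       f"{sorted(conditions.TRAIT_ACE)}")
    syn = conditions.SYNAESTHESIA_ACE
    oth = conditions.TRAIT_ACE[trait]
    cross = conditions.TRAIT_CROSS[trait]
    return BivariateSimSpec(
        syn["a2"], syn["c2"], syn["e2"], oth["a2"], oth["c2"], oth["e2"],
        cross["r_a"], cross["r_c"], cross["r_e"],
        n_mz=conditions.N_MZ if n_mz is None else n_mz,
        n_dz=conditions.N_DZ_SS if n_dz is None else n_dz,
        n_dz_os=conditions.N_DZ_OS if n_dz_os is None else n_dz_os,
        seed=seed, traits=("synaesthesia", trait))
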