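"""Item scoring, exclusion rules, transformations and descriptives.

The screening instruments score each item "yes" = 1, "yes, to some
extent" = 0.5, "no" = 0, with "don't know / won't answer" treated as
missing.  A scale score is the plain sum of the available item codes;
individuals missing more than ``max_missing_fraction`` of a scale's items
(default 20%) do not receive a score for that scale.  Scores are
log(1 + x)-transformed to reduce positive skew, regressed on sex and birth
year, and the residuals standardized, before any twin modelling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

VALID_CODES = (0.0, 0.5, 1.0)


class ItemCodingError(ValueError):
    """A response cell is not one of the allowed item codes."""


@dataclass
class ItemResponseMatrix:
    """Per-individual coded item responses (NaN = missing).

    Backed by a DataFrame with one row per individual and one column per
    item; every non-missing cell must be exactly 0, 0.5 or 1.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.data.to_numpy(dtype=float)
        ok = np.isnan(vals)
        for code in VALID_CODES:
            ok |= vals == code
        if not ok.all():
            bad = sorted({float(v) for v in vals[~ok].ravel()})
            raise ItemCodingError(f"invalid item codes present: {bad}")

    @property
    def items(self) -> list[str]:
        return list(self.data.columns)

    @property
    def individuals(self) -> pd.Index:
        return self.data.index


@dataclass
class ScaleSpec:
    name: str
    items: list[str]
    max_missing_fraction: float = 0.20
    collapse_groups: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.items:
            raise ValueError("a scale needs at least one item")
        for grp in self.collapse_groups:
            unknown = set(grp) - set(self.items)
            if unknown:
                raise ValueError(f"collapse group items not in scale: {unknown}")


def score_scale(responses: ItemResponseMatrix, spec: ScaleSpec) -> pd.Series:
    """Sum of available item codes; missing when too many items are missing.

    No proration for missing items — with the ≤20% allowance on an 8-item
    scale, one missing item is tolerated (score is the sum of the 7
    available codes) and two or more disqualify the individual.
    """
    unknown = set(spec.items) - set(responses.items)
    if unknown:
        raise KeyError(f"unknown item name(s): {sorted(unknown)}")
    sub = responses.data[spec.items]
    frac_missing = sub.isna().mean(axis=1)
    score = sub.sum(axis=1, skipna=True)
    score[frac_missing > spec.max_missing_fraction] = np.nan
    score.name = spec.name
    return score


def collapse_items(responses: ItemResponseMatrix,
                   spec: ScaleSpec) -> tuple[ItemResponseMatrix, ScaleSpec]:
    """Replace each collapse group by one derived item (max over the group).

    The maximum preserves any-endorsement semantics for graded codes; the
    derived item is missing only when every item in the group is missing.
    Returns the collapsed matrix together with the matching reduced spec.
    """
    if not spec.collapse_groups:
        raise ValueError("spec has no collapse groups")
    df = responses.data.copy()
    new_items = list(spec.items)
    for grp in spec.collapse_groups:
        derived = "+".join(grp)
        df[derived] = df[list(grp)].max(axis=1, skipna=True)
        df = df.drop(columns=list(grp))
        pos = min(new_items.index(it) for it in grp)
        new_items = [it for it in new_items if it not in grp]
        new_items.insert(min(pos, len(new_items)), derived)
    collapsed_spec = ScaleSpec(name=spec.name + "_collapsed", items=new_items,
                               max_missing_fraction=spec.max_missing_fraction)
    return ItemResponseMatrix(df[new_items]), collapsed_spec


def log1p_transform(values) -> pd.Series | np.ndarray:
    """Elementwise log(1 + x); missing propagates; negative input is an error."""
    arr = np.asarray(values, dtype=float)
    if np.nanmin(arr, initial=0.0) < 0:
        raise ValueError("log1p_transform requires non-negative values")
    out = np.log1p(arr)
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def residualize_standardize(values, sex, birth_year) -> pd.Series | np.ndarray:
    """OLS-residualize on sex and birth year, then standardize to sd 1.

    Sex enters as a two-level indicator, birth year linearly.  The
    regression uses individuals with a complete (value, sex, year) triple;
    rows with a missing value or missing predictor come back missing.
    Constant predictor columns are dropped with a warning.
    """
    vals = np.asarray(values, dtype=float)
    sex_arr = np.asarray(sex, dtype=object)
    year_arr = np.asarray(birth_year, dtype=float)
    sex_known = np.array([s in ("F", "M") for s in sex_arr])
    complete = ~np.isnan(vals) & sex_known & ~np.isnan(year_arr)
    if complete.sum() < 3:
        raise ValueError("need at least 3 complete rows to residualize")

    cols = [np.ones(int(complete.sum()))]
    names = ["const"]
    sex_ind = (sex_arr[complete] == "M").astype(float)
    if len(np.unique(sex_ind)) > 1:
        cols.append(sex_ind)
        names.append("sex")
    else:
        logger.warning("sex is constant; dropped from residualization")
    yr = year_arr[complete]
    if len(np.unique(yr)) > 1:
        cols.append(yr - yr.mean())
        names.append("birth_year")
    else:
        logger.warning("birth year is constant; dropped from residualization")
    design = np.column_stack(cols)
    fit = sm.OLS(vals[complete], design).fit()
    resid = fit.resid
    sd = resid.std(ddof=1)
    if sd == 0:
        raise ValueError("residuals have zero variance")
    out = np.full(vals.shape, np.nan)
    out[complete] = (resid - resid.mean()) / sd
    if isinstance(values, pd.Series):
        return pd.Series(out, index=values.index, name=values.name)
    return out


def sample_skewness(values) -> float:
    """Adjusted Fisher–Pearson skewness g1 * sqrt(n(n-1)) / (n-2)."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 3:
        raise ValueError("need at least 3 non-missing values")
    if np.var(arr) == 0:
        raise ValueError("skewness undefined for zero variance")
    return float(stats.skew(arr, bias=False))


@dataclass
class AlphaEstimate:
    alpha: float
    ci_low: float
    ci_high: float
    n_individuals: int
    n_items: int


def cronbach_alpha(responses: ItemResponseMatrix,
                   level: float = 0.95) -> AlphaEstimate:
    """Cronbach's alpha on complete cases, with the Feldt F-based CI.

    alpha = k/(k-1) * (1 - sum(item variances) / var(total)); the CI uses
    1 - (1 - alpha) * F-quantiles with (n-1, (n-1)(k-1)) degrees of freedom.
    """
    df = responses.data.dropna()
    n, k = df.shape
    if k < 2:
        raise ValueError("need at least 2 items")
    if n < 3:
        raise ValueError("need at least 3 complete-case individuals")
    item_vars = df.var(axis=0, ddof=1)
    total_var = df.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance")
    alpha = k / (k - 1) * (1.0 - item_vars.sum() / total_var)
    q = (1.0 - level) / 2.0
    df1, df2 = n - 1, (n - 1) * (k - 1)
    lo = 1.0 - (1.0 - alpha) * stats.f.ppf(1.0 - q, df1, df2)
    hi = 1.0 - (1.0 - alpha) * stats.f.ppf(q, df1, df2)
    return AlphaEstimate(float(alpha), float(lo), float(hi), n, k)


@dataclass
class TraitDescriptives:
    trait: str
    n: int
    mean: float
    sd: float
    skew: float
    skew_after_log: float


def describe_trait(values, name: str = "") -> TraitDescriptives:
    """Mean / sd / skewness of a score, plus skewness after log(1+x)."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    return TraitDescriptives(
        trait=name, n=int(arr.size), mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)), skew=sample_skewness(arr),
        skew_after_log=sample_skewness(np.log1p(arr)))


def prepare_trait(values, sex, birth_year) -> pd.Series | np.ndarray:
    """The study's preparation chain: log(1+x) → residualize → standardize."""
    return residualize_standardize(log1p_transform(values), sex, birth_year)
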