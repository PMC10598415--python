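"""End-to-end study pipeline: simulate/load → prepare → describe → model.

The pipeline mirrors the study's analysis sequence on three twin-pair
tables (synaesthesia paired with total autistic traits, with RRBI-D and
with SIC): ordinal scores are log(1+x)-transformed, residualized on sex
and birth year and standardized; the constrained saturated models supply
twin and CTCT correlations; univariate ACE-family models decompose the
synaesthesia-score variance; bivariate correlated-factors AE/ACE models
estimate rPh, rA, rE and the covariance shares; and a sensitivity stage
re-scores the screening with the four sequence-colour types counted as
one and re-runs the univariate model.  Everything is deterministic given
the config seed and every stage persists its artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import conditions, preprocess
from .biometric import (FitResult, compare_nested, fit_bivariate,
                        fit_to_dict, fit_univariate)
from .data_io import CohortTable, read_pairs_csv, write_pairs_csv, ColumnMap
from .saturated import bivariate_correlation_table, test_equality
from .simulate import (add_covariate_effects, calibrate_thresholds,
                       discretize_to_scale, inject_missingness,
                       simulate_item_responses, simulate_pairs,
                       study_bivariate_spec)

logger = logging.getLogger(__name__)

# ordinal scale layout per autistic-trait measure: (max score, mean, sd)
TRAIT_SCALES = {
    "total_autistic_traits": (12.0, 1.91, 1.62),
    "rrbid": (4.0, 0.92, 0.88),
    "sic": (8.0, 1.09, 1.15),
}


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "results/pipeline"
    simulate: bool = True
    input_csvs: dict[str, str] = field(default_factory=dict)  # trait -> path
    univariate_trait: str = "synaesthesia"
    bivariate_traits: list[str] = field(
        default_factory=lambda: list(TRAIT_SCALES))
    prepare: bool = True
    sensitivity: bool = True
    alpha: float = 0.05
    sex_effect: float = conditions.DEFAULT_SEX_EFFECT
    year_effect: float = conditions.DEFAULT_YEAR_EFFECT
    missing_rate: float = conditions.DEFAULT_MISSING_RATE
    model_family: str = "AE"   # bivariate model to report
    # pair counts for simulated cohorts; None = the study composition
    n_mz: int | None = None
    n_dz: int | None = None
    n_dz_os: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        if not cfg.simulate and not cfg.input_csvs:
            raise ValueError("config needs either simulate: true or input_csvs")
        for t in cfg.bivariate_traits:
            if cfg.simulate and t not in TRAIT_SCALES:
                raise ValueError(f"no simulation profile for trait {t!r}")
        return cfg


@dataclass
class StudyReport:
    descriptives: pd.DataFrame
    correlations: pd.DataFrame
    univariate: pd.DataFrame
    model_comparisons: pd.DataFrame
    bivariate: pd.DataFrame
    assumption_tests: pd.DataFrame
    sensitivity: pd.DataFrame | None = None


def simulate_trait_cohort(trait: str, seed: int,
                           cfg: PipelineConfig) -> CohortTable:
    """One analysis-ready twin table: synaesthesia + one autistic trait.

    Latent standardized phenotypes are drawn from the study-condition
    bivariate spec, discretized onto their ordinal scales, given sex and
    birth-year effects, and degraded with MCAR missingness.
    """
    spec = study_bivariate_spec(trait, seed=seed, n_mz=cfg.n_mz,
                                n_dz=cfg.n_dz, n_dz_os=cfg.n_dz_os)
    cohort = simulate_pairs(spec)
    frame = cohort.individual_frame()
    syn = discretize_to_scale(frame["synaesthesia"].to_numpy(),
                              conditions.SYNAESTHESIA_THRESHOLDS,
                              conditions.SYNAESTHESIA_LEVELS)
    cohort = cohort.with_transformed_trait("synaesthesia", syn)
    max_score, mean, sd = TRAIT_SCALES[trait]
    levels = np.arange(int(max_score * 2) + 1) * 0.5
    th = calibrate_thresholds(levels, mean, sd)
    vals = discretize_to_scale(frame[trait].to_numpy(), th, levels)
    cohort = cohort.with_transformed_trait(trait, vals)
    cohort = add_covariate_effects(cohort, cfg.sex_effect, cfg.year_effect)
    if cfg.missing_rate > 0:
        cohort = inject_missingness(cohort, cfg.missing_rate, seed=seed + 7)
    return cohort


def prepare_cohort(cohort: CohortTable) -> CohortTable:
    """log(1+x) → residualize on sex/birth year → standardize, per trait."""
    frame = cohort.individual_frame()
    out = cohort
    for trait in cohort.trait_names:
        shifted = frame[trait] - np.nanmin(frame[trait].to_numpy())
        prepared = preprocess.prepare_trait(shifted, frame["sex"],
                                            frame["birth_year"])
        out = out.with_transformed_trait(trait, prepared.to_numpy())
    return out


def make_report(fits: dict[str, FitResult],
                correlations: pd.DataFrame,
                descriptives: pd.DataFrame,
                comparisons: pd.DataFrame | None = None,
                univariate: pd.DataFrame | None = None,
                assumption_tests: pd.DataFrame | None = None,
                required_traits=None,
                sensitivity: pd.DataFrame | None = None) -> StudyReport:
    """Assemble the study tables from fitted models; pure function.

    ``fits`` maps autistic-trait name → bivariate FitResult.  A missing
    required fit is an error naming the trait pair; empty descriptives are
    allowed with a warning (describe stage skipped).
    """
    required = list(fits) if required_traits is None else list(required_traits)
    missing = [t for t in required if t not in fits]
    if missing:
        raise KeyError("missing bivariate fit(s) for: " + ", ".join(missing))
    if descriptives is None or descriptives.empty:
        logger.warning("descriptives are empty (describe stage skipped)")
        descriptives = pd.DataFrame()
    rows = []
    for trait in required:
        fit = fits[trait]
        p = fit.params
        shares = p.covariance_shares()
        row = {"trait_pair": f"synaesthesia x {trait}", "model": fit.model,
               "rPh": p.r_ph, "rA": p.r_a, "rE": p.r_e,
               "bivariate_A_share": shares["A"],
               "bivariate_E_share": shares["E"],
               "minus2ll": fit.minus2ll}
        for q, (lo, hi) in fit.ci95.items():
            row[f"{q}_lo95"], row[f"{q}_hi95"] = lo, hi
        rows.append(row)
    bivariate = pd.DataFrame(rows)
    return StudyReport(
        descriptives=descriptives, correlations=correlations,
        univariate=univariate if univariate is not None else pd.DataFrame(),
        model_comparisons=(comparisons if comparisons is not None
                           else pd.DataFrame()),
        bivariate=bivariate,
        assumption_tests=(assumption_tests if assumption_tests is not None
                          else pd.DataFrame()),
        sensitivity=sensitivity)


def _univariate_stage(cohort: CohortTable, trait: str, alpha: float):
    fits = {m: fit_univariate(cohort, trait, model=m,
                              ci=("A", "C", "E") if m in ("ACE", "AE") else ())
            for m in ("ACE", "AE", "CE", "E")}
    comps = [compare_nested(fits["ACE"], fits[m]) for m in ("AE", "CE", "E")]
    comp_df = pd.DataFrame([{
        "parent": c.parent, "nested": c.nested,
        "delta_minus2ll": c.delta_minus2ll, "delta_df": c.delta_df,
        "p_value": c.p_value, "p_value_boundary": c.p_value_boundary}
        for c in comps])
    keep = [c.nested for c in comps if c.p_value >= alpha]
    # most parsimonious nested model not significantly worse than ACE
    order = {"E": 0, "CE": 1, "AE": 2, "ACE": 3}
    selected = min(keep, key=lambda m: order[m]) if keep else "ACE"
    rows = []
    for m in ("ACE", "AE"):
        fit = fits[m]
        p = fit.params
        row = {"trait": trait, "model": m, "A": p.A, "C": p.C, "E": p.E,
               "minus2ll": fit.minus2ll, "selected": m == selected}
        for q, (lo, hi) in fit.ci95.items():
            row[f"{q}_lo95"], row[f"{q}_hi95"] = lo, hi
        rows.append(row)
    return pd.DataFrame(rows), comp_df, fits, selected


def _sensitivity_stage(cohort: CohortTable, seed: int) -> pd.DataFrame:
    """Re-score the screening with sequence-colour types counted as one.

    Item responses are generated from the prepared synaesthesia score used
    as the liability; both the plain 8-item sum and the collapsed 5-item
    score are pushed through the same preparation and univariate AE model,
    so the comparison isolates the scoring rule.
    """
    frame = cohort.individual_frame()
    latent = frame["synaesthesia"].to_numpy(dtype=float)
    filled = np.where(np.isnan(latent), 0.0, latent)
    items = simulate_item_responses(filled, seed=seed)
    spec = preprocess.ScaleSpec(
        name="synaesthesia", items=conditions.SCREENING_ITEMS,
        collapse_groups=[conditions.SEQUENCE_COLOUR_GROUP])
    rows = []
    variants = {"main_scoring": (items, spec)}
    variants["sequence_colour_collapsed"] = preprocess.collapse_items(items, spec)
    for label, (mat, sc) in variants.items():
        score = preprocess.score_scale(mat, sc).to_numpy(dtype=float)
        score[np.isnan(latent)] = np.nan
        prepared = preprocess.residualize_standardize(
            preprocess.log1p_transform(score), frame["sex"],
            frame["birth_year"])
        variant = cohort.with_transformed_trait("synaesthesia", prepared)
        fit = fit_univariate(variant, "synaesthesia", model="AE", ci=("A",))
        rows.append({"scoring": label, "A": fit.params.A, "E": fit.params.E,
                     "A_lo95": fit.ci95["A"][0], "A_hi95": fit.ci95["A"][1]})
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> StudyReport:
    """Execute all stages and persist artifacts under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    stage_seeds = {t: int(rng.integers(2 ** 31))
                   for t in config.bivariate_traits}
    cohorts: dict[str, CohortTable] = {}
    for trait in config.bivariate_traits:
        if config.simulate:
            cohort = simulate_trait_cohort(trait, stage_seeds[trait], config)
        else:
            cohort = read_pairs_csv(
                config.input_csvs[trait],
                ColumnMap(traits=["synaesthesia", trait]))
        write_pairs_csv(cohort, out / f"cohort_{trait}.csv")
        cohorts[trait] = cohort
    logger.info("stage simulate/load done: %s",
                {t: len(c) for t, c in cohorts.items()})

    # descriptives on the raw (ordinal) scores
    desc_rows = []
    first = config.bivariate_traits[0]
    frame0 = cohorts[first].individual_frame()
    desc_rows.append(vars(preprocess.describe_trait(
        frame0["synaesthesia"], "synaesthesia")))
    for trait in config.bivariate_traits:
        frame = cohorts[trait].individual_frame()
        desc_rows.append(vars(preprocess.describe_trait(frame[trait], trait)))
    descriptives = pd.DataFrame(desc_rows)

    prepared: dict[str, CohortTable] = {}
    for trait, cohort in cohorts.items():
        prepared[trait] = prepare_cohort(cohort) if config.prepare else cohort
        write_pairs_csv(prepared[trait], out / f"prepared_{trait}.csv")
    logger.info("stage prepare done")

    uni_cohort = prepared[first]
    assumption_rows = []
    for which in ("order_means", "order_variances", "zygosity_means",
                  "zygosity_variances"):
        mc = test_equality(uni_cohort, which, traits=config.univariate_trait)
        assumption_rows.append({"test": mc.constrained,
                                "delta_minus2ll": mc.delta_minus2ll,
                                "delta_df": mc.delta_df, "p": mc.p_value})
    assumption_tests = pd.DataFrame(assumption_rows)

    corr_frames = []
    for trait, cohort in prepared.items():
        tbl = bivariate_correlation_table(
            cohort, ["synaesthesia", trait], pool_dz=True)
        tbl.insert(0, "trait_pair", f"synaesthesia x {trait}")
        corr_frames.append(tbl)
    correlations = pd.concat(corr_frames, ignore_index=True)
    correlations.to_csv(out / "correlations.csv", index=False)
    logger.info("stage describe done")

    uni_table, comp_df, uni_fits, selected = _univariate_stage(
        uni_cohort, config.univariate_trait, config.alpha)
    uni_table.to_csv(out / "univariate.csv", index=False)
    logger.info("stage univariate done (selected model: %s)", selected)

    biv_fits: dict[str, FitResult] = {}
    for trait, cohort in prepared.items():
        fit = fit_bivariate(cohort, ["synaesthesia", trait],
                            model=config.model_family)
        biv_fits[trait] = fit
        (out / f"fit_bivariate_{trait}.json").write_text(
            json.dumps(fit_to_dict(fit), indent=2))
    logger.info("stage bivariate done")

    sensitivity = None
    if config.sensitivity:
        sensitivity = _sensitivity_stage(uni_cohort,
                                         seed=stage_seeds[first] + 13)
        sensitivity.to_csv(out / "sensitivity.csv", index=False)
        logger.info("stage sensitivity done")

    report = make_report(biv_fits, correlations, descriptives,
                         comparisons=comp_df, univariate=uni_table,
                         assumption_tests=assumption_tests,
                         required_traits=config.bivariate_traits,
                         sensitivity=sensitivity)
    report.descriptives.to_csv(out / "descriptives.csv", index=False)
    report.bivariate.to_csv(out / "bivariate.csv", index=False)
    report.model_comparisons.to_csv(out / "model_comparisons.csv", index=False)
    report.assumption_tests.to_csv(out / "assumption_tests.csv", index=False)
    _write_markdown(report, out / "report.md", selected)
    logger.info("pipeline complete; outputs under %s", out)
    return report


def _write_markdown(report: StudyReport, path: Path, selected: str) -> None:
    lines = ["# Twin-study replication report", ""]
    if not report.descriptives.empty:
        lines += ["## Descriptives", "",
                  report.descriptives.round(3).to_markdown(index=False), ""]
    lines += ["## Twin and cross-twin cross-trait correlations", "",
              report.correlations.round(3).to_markdown(index=False), "",
              "## Assumption tests (equality across twin order / zygosity)",
              "", report.assumption_tests.round(4).to_markdown(index=False),
              "", "## Univariate variance decomposition "
              f"(selected model: {selected})", "",
              report.univariate.round(3).to_markdown(index=False), "",
              "## Model comparisons", "",
              report.model_comparisons.round(4).to_markdown(index=False), "",
              "## Bivariate correlated-factors results", "",
              report.bivariate.round(3).to_markdown(index=False), ""]
    if report.sensitivity is not None:
        lines += ["## Sensitivity analysis (sequence-colour types as one)",
                  "", report.sensitivity.round(3).to_markdown(index=False), ""]
    path.write_text("\n".join(lines))
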