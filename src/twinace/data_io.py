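"""Reading, validating and writing twin-pair phenotype tables.

A cohort is a collection of twin pairs, each with a zygosity code
(MZ / same-sex DZ / opposite-sex DZ), per-twin sex and birth year, and one
or more phenotype values per twin.  Files are plain CSV in either a *wide*
layout (one row per pair, ``<trait>_1`` / ``<trait>_2`` columns) or a *long*
layout (two rows per pair with a twin-order column).  All reading goes
through a :class:`ColumnMap`, so registry exports with arbitrary headers can
be ingested without code changes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MZ = "MZ"
DZ_SS = "DZ_SS"
DZ_OS = "DZ_OS"
UNKNOWN = "UNKNOWN"
ZYGOSITIES = (MZ, DZ_SS, DZ_OS)

#: Default normalisation table for zygosity strings (matched lowercase,
#: stripped).  Unknown strings are retained but flagged by validation.
DEFAULT_ZYGOSITY_ALIASES: dict[str, str] = {
    "mz": MZ, "1": MZ, "monozygotic": MZ,
    "dz": DZ_SS, "dz_ss": DZ_SS, "dzss": DZ_SS, "2": DZ_SS,
    "dizygotic": DZ_SS, "dz same sex": DZ_SS,
    "dzos": DZ_OS, "dz_os": DZ_OS, "os": DZ_OS, "3": DZ_OS,
    "dz opposite sex": DZ_OS,
}

_MISSING_STRINGS = {"", "na", "nan", "n/a", "none", "."}
_SEX_ALIASES = {"f": "F", "female": "F", "1": "F",
                "m": "M", "male": "M", "2": "M"}


class ConfigurationError(ValueError):
    """A column map does not match the file at hand."""


class ValidationError(ValueError):
    """The file content violates the pair structure."""


@dataclass
class Twin:
    sex: str = "unknown"                       # "F", "M" or "unknown"
    birth_year: int | None = None
    phenotypes: dict[str, float] = field(default_factory=dict)  # NaN = missing


@dataclass
class TwinPairRecord:
    pair_id: str
    zygosity: str                              # MZ / DZ_SS / DZ_OS / UNKNOWN
    twin1: Twin = field(default_factory=Twin)
    twin2: Twin = field(default_factory=Twin)

    @property
    def twins(self) -> tuple[Twin, Twin]:
        return (self.twin1, self.twin2)


@dataclass
class CohortTable:
    """Ordered collection of twin pairs sharing a trait list."""

    records: list[TwinPairRecord]
    trait_names: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.pair_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            logger.warning("cohort has duplicate pair_ids: %s", dupes)
        for rec in self.records:
            for twin in rec.twins:
                for t in self.trait_names:
                    twin.phenotypes.setdefault(t, math.nan)

    def __len__(self) -> int:
        return len(self.records)

    def zygosity_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.records:
            counts[rec.zygosity] = counts.get(rec.zygosity, 0) + 1
        return counts

    def subset(self, zygosities) -> "CohortTable":
        keep = [r for r in self.records if r.zygosity in set(zygosities)]
        return CohortTable(keep, list(self.trait_names), self.provenance)

    def pair_matrix(self, traits, zygosities=None) -> np.ndarray:
        """Per-pair data matrix with columns ordered twin-major.

        For traits ``[x, y]`` the columns are
        ``x_twin1, y_twin1, x_twin2, y_twin2`` — the variable order the
        saturated and biometric models use.
        """
        if isinstance(traits, str):
            traits = [traits]
        recs = self.records
        if zygosities is not None:
            zset = set([zygosities] if isinstance(zygosities, str) else zygosities)
            recs = [r for r in recs if r.zygosity in zset]
        rows = np.full((len(recs), 2 * len(traits)), np.nan)
        for i, rec in enumerate(recs):
            for w, twin in enumerate(rec.twins):
                for j, t in enumerate(traits):
                    rows[i, w * len(traits) + j] = twin.phenotypes.get(t, math.nan)
        return rows

    def individual_frame(self) -> pd.DataFrame:
        """One row per individual (pair_id, twin order, sex, year, traits)."""
        rows = []
        for rec in self.records:
            for w, twin in enumerate(rec.twins, start=1):
                row = {"pair_id": rec.pair_id, "twin": w,
                       "zygosity": rec.zygosity, "sex": twin.sex,
                       "birth_year": twin.birth_year}
                row.update({t: twin.phenotypes.get(t, math.nan)
                            for t in self.trait_names})
                rows.append(row)
        return pd.DataFrame(rows)

    def with_transformed_trait(self, trait: str, values) -> "CohortTable":
        """Return a copy with ``trait`` replaced by per-individual ``values``.

        ``values`` must align with :meth:`individual_frame` row order.
        """
        values = np.asarray(values, dtype=float)
        if values.size != 2 * len(self.records):
            raise ValueError("values must have one entry per individual")
        records = []
        for i, rec in enumerate(self.records):
            twins = []
            for w, twin in enumerate(rec.twins):
                ph = dict(twin.phenotypes)
                ph[trait] = float(values[2 * i + w])
                twins.append(replace(twin, phenotypes=ph))
            records.append(TwinPairRecord(rec.pair_id, rec.zygosity, *twins))
        traits = list(self.trait_names)
        if trait not in traits:
            traits.append(trait)
        return CohortTable(records, traits, self.provenance)


@dataclass
class ColumnMap:
    """Maps file columns onto the cohort schema.

    ``layout`` is ``"wide"`` (one row per pair) or ``"long"`` (two rows per
    pair).  In the wide layout, per-twin columns are ``<base><suffix>`` with
    the two ``twin_suffixes``; in the long layout per-twin fields use the
    bare base name and ``twin_order`` gives the 1/2 column.
    """

    traits: list[str]
    layout: str = "wide"
    pair_id: str = "pair_id"
    zygosity: str = "zygosity"
    sex: str | None = "sex"
    birth_year: str | None = "birth_year"
    twin_suffixes: tuple[str, str] = ("_1", "_2")
    twin_order: str = "twin"
    zygosity_aliases: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_ZYGOSITY_ALIASES))


#: Reader profile for the study's shared (noised) analysis-ready CSVs: wide
#: layout, standardized scores, one synaesthesia column and one autistic-trait
#: column per file.  Headers are adjustable here without code changes.
def supplementary_profile(trait: str) -> ColumnMap:
    return ColumnMap(traits=["synaesthesia", trait], layout="wide",
                     pair_id="pair_id", zygosity="zygosity",
                     sex=None, birth_year=None)


def normalize_zygosity(raw, aliases: dict[str, str] | None = None) -> str:
    aliases = aliases if aliases is not None else DEFAULT_ZYGOSITY_ALIASES
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return UNKNOWN
    key = str(raw).strip().lower()
    if key in _MISSING_STRINGS:
        return UNKNOWN
    if key in {z.lower() for z in ZYGOSITIES}:
        return key.upper()
    return aliases.get(key, UNKNOWN)


def _parse_float(raw) -> tuple[float, bool]:
    """Return (value, was_unparseable)."""
    if raw is None:
        return math.nan, False
    if isinstance(raw, float):
        return raw, False
    s = str(raw).strip()
    if s.lower() in _MISSING_STRINGS:
        return math.nan, False
    try:
        return float(s), False
    except ValueError:
        return math.nan, True


def _parse_sex(raw) -> str:
    if raw is None:
        return "unknown"
    s = str(raw).strip().lower()
    if s in _MISSING_STRINGS:
        return "unknown"
    return _SEX_ALIASES.get(s, "unknown")


def _parse_year(raw) -> int | None:
    val, _ = _parse_float(raw)
    if math.isnan(val):
        return None
    return int(round(val))


def read_pairs_csv(path, column_map: ColumnMap) -> CohortTable:
    """Read a twin-pair CSV into a :class:`CohortTable`.

    Unparseable phenotype cells become missing, with a logged count.  A
    missing mandatory column raises :class:`ConfigurationError`; a long-layout
    pair with a row count other than two raises :class:`ValidationError`.
    """
    cm = column_map
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = [cm.pair_id, cm.zygosity]
    if cm.layout == "wide":
        for t in cm.traits:
            required += [t + s for s in cm.twin_suffixes]
        if cm.sex:
            required += [cm.sex + s for s in cm.twin_suffixes]
        if cm.birth_year:
            required += [cm.birth_year + s for s in cm.twin_suffixes]
    elif cm.layout == "long":
        required += [cm.twin_order] + list(cm.traits)
        if cm.sex:
            required.append(cm.sex)
        if cm.birth_year:
            required.append(cm.birth_year)
    else:
        raise ConfigurationError(f"unknown layout {cm.layout!r}")
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ConfigurationError(
            f"missing mandatory column(s): {', '.join(missing_cols)}")

    bad_cells = 0
    records: list[TwinPairRecord] = []

    def cell_to_float(raw):
        nonlocal bad_cells
        val, bad = _parse_float(raw)
        bad_cells += int(bad)
        return val

    if cm.layout == "wide":
        for _, row in df.iterrows():
            twins = []
            for s in cm.twin_suffixes:
                twins.append(Twin(
                    sex=_parse_sex(row[cm.sex + s]) if cm.sex else "unknown",
                    birth_year=_parse_year(row[cm.birth_year + s]) if cm.birth_year else None,
                    phenotypes={t: cell_to_float(row[t + s]) for t in cm.traits},
                ))
            records.append(TwinPairRecord(
                pair_id=str(row[cm.pair_id]).strip(),
                zygosity=normalize_zygosity(row[cm.zygosity], cm.zygosity_aliases),
                twin1=twins[0], twin2=twins[1]))
    else:
        bad_pairs = [pid for pid, grp in df.groupby(cm.pair_id, sort=False)
                     if len(grp) != 2]
        if bad_pairs:
            raise ValidationError(
                "pairs without exactly 2 rows: "
                + ", ".join(str(p) for p in bad_pairs))
        for pid, grp in df.groupby(cm.pair_id, sort=False):
            grp = grp.copy()
            grp["_order"] = [int(float(v)) for v in grp[cm.twin_order]]
            grp = grp.sort_values("_order")
            twins = []
            for _, row in grp.iterrows():
                twins.append(Twin(
                    sex=_parse_sex(row[cm.sex]) if cm.sex else "unknown",
                    birth_year=_parse_year(row[cm.birth_year]) if cm.birth_year else None,
                    phenotypes={t: cell_to_float(row[t]) for t in cm.traits},
                ))
            records.append(TwinPairRecord(
                pair_id=str(pid).strip(),
                zygosity=normalize_zygosity(grp[cm.zygosity].iloc[0],
                                            cm.zygosity_aliases),
                twin1=twins[0], twin2=twins[1]))

    if bad_cells:
        logger.warning("%d unparseable phenotype cells set to missing in %s",
                       bad_cells, path)
    return CohortTable(records, list(cm.traits), provenance=f"read from {path}")


def write_pairs_csv(cohort: CohortTable, path) -> None:
    """Write a cohort as a wide CSV; re-reading reproduces it exactly.

    Finite values are printed at full ``repr`` precision; missing values as
    empty cells.
    """
    cols = ["pair_id", "zygosity"]
    for s in ("_1", "_2"):
        cols += ["sex" + s, "birth_year" + s] + [t + s for t in cohort.trait_names]
    rows = []
    for rec in cohort.records:
        row = {"pair_id": rec.pair_id, "zygosity": rec.zygosity}
        for s, twin in zip(("_1", "_2"), rec.twins):
            row["sex" + s] = "" if twin.sex == "unknown" else twin.sex
            row["birth_year" + s] = "" if twin.birth_year is None else twin.birth_year
            for t in cohort.trait_names:
                v = twin.phenotypes.get(t, math.nan)
                row[t + s] = "" if (isinstance(v, float) and math.isnan(v)) else repr(float(v))
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


@dataclass
class ValidationReport:
    unknown_zygosity: list[str]
    duplicate_pair_ids: list[str]
    sex_discordant_mz: list[str]
    missingness: dict[str, float]   # trait -> fraction of missing individuals

    @property
    def clean(self) -> bool:
        return not (self.unknown_zygosity or self.duplicate_pair_ids
                    or self.sex_discordant_mz)


def validate_cohort(cohort: CohortTable) -> ValidationReport:
    """Content checks: reports issues, never raises on data problems."""
    seen: set[str] = set()
    dupes: list[str] = []
    unknown: list[str] = []
    discordant: list[str] = []
    for rec in cohort.records:
        if rec.pair_id in seen and rec.pair_id not in dupes:
            dupes.append(rec.pair_id)
        seen.add(rec.pair_id)
        if rec.zygosity not in ZYGOSITIES:
            unknown.append(rec.pair_id)
        if (rec.zygosity == MZ and "unknown" not in (rec.twin1.sex, rec.twin2.sex)
                and rec.twin1.sex != rec.twin2.sex):
            discordant.append(rec.pair_id)
    if discordant:
        logger.warning("sex-discordant MZ pairs: %s", discordant)
    n_ind = 2 * len(cohort.records)
    missingness = {}
    for t in cohort.trait_names:
        n_miss = sum(1 for rec in cohort.records for twin in rec.twins
                     if math.isnan(twin.phenotypes.get(t, math.nan)))
        missingness[t] = n_miss / n_ind if n_ind else 0.0
    return ValidationReport(unknown, dupes, discordant, missingness)
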