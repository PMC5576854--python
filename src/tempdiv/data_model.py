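"""Survey data model: validated readers, filtering rules, and pivoting.

Long-format survey tables (one row per plot / date / species observation)
are the package's native input. Records are held in a validated
:class:`pandas.DataFrame` with one row per (plot, date, species) event and
pivoted into sample-by-species :class:`AbundanceMatrix` objects for the
diversity analyses. Years are always analysed separately; nothing in this
module ever concatenates counts across years.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SURVEY_COLUMNS = [
    "plot_id",
    "treatment",
    "year",
    "julian_date",
    "method",
    "species_id",
    "count",
    "id_level",
]
TRAIT_COLUMNS = ["species_id", "diet", "native", "genus"]

TREATMENTS = frozenset({"reserve", "fragment"})
METHODS = frozenset({"bowl", "net"})
ID_LEVELS = frozenset({"species", "morphospecies", "genus_only"})
DIETS = frozenset({"generalist", "specialist", "parasitic", "unknown"})

SAMPLE_KEY = ["plot_id", "year", "julian_date"]


class SurveyValidationError(ValueError):
    """Raised when a survey or trait table violates the data model."""


@dataclass
class FilterReport:
    """Counts of rows/individuals removed by each filtering rule."""

    rows_in: int = 0
    rows_out: int = 0
    removed: dict = field(default_factory=dict)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        rules = ", ".join(f"{k}: {v}" for k, v in self.removed.items()) or "none"
        return f"FilterReport({self.rows_in} -> {self.rows_out} rows; removed {rules})"


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SurveyValidationError(f"{what} is missing required column(s): {missing}")


def validate_survey(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a survey record table and normalise dtypes.

    Checks every invariant of the record model: positive integer counts,
    julian dates within [1, 366], known treatment/method/id_level levels,
    and a single treatment per plot within each year. Duplicate
    (plot, date, species) rows are summed with a warning, as field data
    commonly split one sample across several collection bouts.

    Returns a new, validated DataFrame; the input is not modified.
    """
    _check_columns(df, SURVEY_COLUMNS, "survey table")
    df = df.loc[:, SURVEY_COLUMNS].copy()

    # row numbers for error messages refer to the original table (1-based,
    # header excluded), matching what a user sees in the CSV
    rownum = pd.Series(np.arange(len(df)) + 2, index=df.index)

    def _bad(mask: pd.Series, msg: str) -> None:
        if mask.any():
            rows = rownum[mask].tolist()[:10]
            raise SurveyValidationError(f"{msg} (row(s) {rows})")

    counts = pd.to_numeric(df["count"], errors="coerce")
    _bad(counts.isna(), "non-integer count")
    _bad((counts % 1 != 0) | (counts < 1), "count must be a positive integer")
    df["count"] = counts.astype(int)

    jd = pd.to_numeric(df["julian_date"], errors="coerce")
    _bad(jd.isna() | (jd % 1 != 0), "non-integer julian_date")
    _bad((jd < 1) | (jd > 366), "julian_date outside [1, 366]")
    df["julian_date"] = jd.astype(int)

    yr = pd.to_numeric(df["year"], errors="coerce")
    _bad(yr.isna() | (yr % 1 != 0), "non-integer year")
    df["year"] = yr.astype(int)

    for col, levels in [
        ("treatment", TREATMENTS),
        ("method", METHODS),
        ("id_level", ID_LEVELS),
    ]:
        df[col] = df[col].astype(str).str.strip()
        _bad(~df[col].isin(levels), f"unknown {col} (allowed: {sorted(levels)})")

    # treatment must be constant within plot x year
    ntreat = df.groupby(["plot_id", "year"])["treatment"].nunique()
    bad = ntreat[ntreat > 1]
    if len(bad):
        raise SurveyValidationError(
            f"plot(s) with more than one treatment within a year: {bad.index.tolist()}"
        )

    group_cols = SAMPLE_KEY + ["treatment", "method", "species_id", "id_level"]
    dups = df.duplicated(group_cols)
    if dups.any():
        warnings.warn(
            f"{int(dups.sum())} duplicate (plot, date, species) row(s) summed",
            stacklevel=2,
        )
        df = df.groupby(group_cols, as_index=False, sort=False)["count"].sum()
        df = df.loc[:, SURVEY_COLUMNS]
    return df.reset_index(drop=True)


def read_survey(path) -> pd.DataFrame:
    """Read and validate a long-format survey CSV.

    The CSV must carry a header row with columns
    ``plot_id, treatment, year, julian_date, method, species_id, count,
    id_level``. Malformed rows fail hard with 1-based row numbers.
    """
    df = pd.read_csv(path, dtype={"plot_id": str, "species_id": str})
    return validate_survey(df)


def validate_traits(traits: pd.DataFrame) -> pd.DataFrame:
    """Validate a species-trait table (diet, native flag, genus)."""
    _check_columns(traits, TRAIT_COLUMNS, "trait table")
    traits = traits.loc[:, TRAIT_COLUMNS].copy()
    traits["diet"] = traits["diet"].astype(str).str.strip()
    bad = ~traits["diet"].isin(DIETS)
    if bad.any():
        raise SurveyValidationError(
            f"unknown diet value(s): {sorted(traits.loc[bad, 'diet'].unique())}"
        )
    if traits["species_id"].duplicated().any():
        dupes = traits.loc[traits["species_id"].duplicated(), "species_id"].tolist()
        raise SurveyValidationError(f"duplicate species_id in traits: {dupes[:10]}")
    if traits["native"].dtype != bool:
        traits["native"] = (
            traits["native"].astype(str).str.strip().str.lower().map(
                {"true": True, "false": False, "1": True, "0": False}
            )
        )
        if traits["native"].isna().any():
            raise SurveyValidationError("native column must be boolean (true/false)")
    return traits.reset_index(drop=True)


def read_traits(path) -> pd.DataFrame:
    """Read and validate a species-trait CSV (species_id, diet, native, genus)."""
    return validate_traits(pd.read_csv(path, dtype={"species_id": str, "genus": str}))


def check_trait_coverage(records: pd.DataFrame, traits: pd.DataFrame) -> None:
    """Every species appearing in the records must have a traits row."""
    missing = set(records["species_id"]) - set(traits["species_id"])
    if missing:
        raise SurveyValidationError(
            f"{len(missing)} species in records lack a traits row, e.g. "
            f"{sorted(missing)[:5]}"
        )


def write_survey(records: pd.DataFrame, path) -> None:
    records.loc[:, SURVEY_COLUMNS].to_csv(path, index=False)


def write_traits(traits: pd.DataFrame, path) -> None:
    traits.loc[:, TRAIT_COLUMNS].to_csv(path, index=False)


def filter_records(
    records: pd.DataFrame,
    keep_methods: set[str] | frozenset[str] = frozenset({"bowl"}),
    drop_nonnative: bool = True,
    drop_genus_only: bool = True,
    traits: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the analysis filtering rules and report what each removed.

    Defaults mirror the analysis conventions for native assemblages
    sampled by passive traps: only bowl-trap records are kept, non-native
    species (per the trait table's ``native`` flag) are excluded, and
    specimens not identifiable beyond genus are excluded.

    Parameters
    ----------
    records
        Validated survey records.
    keep_methods
        Collection methods to retain.
    drop_nonnative
        Drop species flagged ``native=False`` in `traits` (required then).
    drop_genus_only
        Drop rows with ``id_level == 'genus_only'``.

    Returns
    -------
    (filtered_records, FilterReport)

    Raises
    ------
    SurveyValidationError
        If no records survive, or traits are needed but absent.
    """
    report = FilterReport(rows_in=len(records))
    out = records

    keep_methods = set(keep_methods)
    unknown = keep_methods - METHODS
    if unknown:
        raise SurveyValidationError(f"unknown method(s) in keep_methods: {sorted(unknown)}")
    mask = out["method"].isin(keep_methods)
    report.removed["method"] = int((~mask).sum())
    out = out[mask]

    if drop_nonnative:
        if traits is None:
            raise SurveyValidationError("drop_nonnative=True requires a traits table")
        check_trait_coverage(out, traits)
        nonnative = set(traits.loc[~traits["native"], "species_id"])
        mask = ~out["species_id"].isin(nonnative)
        report.removed["nonnative"] = int((~mask).sum())
        out = out[mask]

    if drop_genus_only:
        mask = out["id_level"] != "genus_only"
        report.removed["genus_only"] = int((~mask).sum())
        out = out[mask]

    report.rows_out = len(out)
    if report.rows_out == 0:
        raise SurveyValidationError("no records survive filters")
    logger.info("%s", report)
    return out.reset_index(drop=True), report


@dataclass
class AbundanceMatrix:
    """Sample-by-species (or plot-by-species) count matrix with metadata.

    ``counts`` rows are samples keyed (plot_id, year, julian_date) — or
    plot_id alone after :func:`pool_by_plot` — and columns are taxa in a
    stable order. ``meta`` is row-aligned and carries at least the
    treatment of every row.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    taxon_level: str = "species"

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.meta.index):
            raise SurveyValidationError("counts and meta indexes are not aligned")
        if (self.counts.to_numpy() < 0).any():
            raise SurveyValidationError("negative counts in abundance matrix")
        colsums = self.counts.sum(axis=0)
        if (colsums == 0).any():
            raise SurveyValidationError(
                f"all-zero taxa columns: {list(colsums.index[colsums == 0])[:5]}"
            )

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def values(self) -> np.ndarray:
        return self.counts.to_numpy()


def to_matrix(
    records: pd.DataFrame,
    taxon_level: str = "species",
    traits: pd.DataFrame | None = None,
) -> AbundanceMatrix:
    """Pivot filtered records into a sample-by-taxon count matrix.

    One row per (plot, year, julian_date) sample. With
    ``taxon_level='genus'`` counts are summed across congeners, which
    requires a traits table mapping every species to its genus.
    """
    if taxon_level not in ("species", "genus"):
        raise ValueError("taxon_level must be 'species' or 'genus'")
    records = records.copy()
    if taxon_level == "genus":
        if traits is None:
            raise SurveyValidationError("taxon_level='genus' requires a traits table")
        check_trait_coverage(records, traits)
        genus_map = traits.set_index("species_id")["genus"]
        if genus_map.loc[records["species_id"].unique()].isna().any():
            raise SurveyValidationError("species lacking genus in traits table")
        records["taxon"] = records["species_id"].map(genus_map)
    else:
        records["taxon"] = records["species_id"]

    counts = (
        records.pivot_table(
            index=SAMPLE_KEY, columns="taxon", values="count", aggfunc="sum", fill_value=0
        )
        .sort_index()
        .sort_index(axis=1)
    )
    counts.columns.name = None
    meta = (
        records.groupby(SAMPLE_KEY)["treatment"].first().to_frame().loc[counts.index]
    )
    return AbundanceMatrix(counts=counts.astype(int), meta=meta, taxon_level=taxon_level)


def pool_by_plot(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Pool a sample-level matrix across all temporal samples of each plot.

    The pooled matrix has one row per plot (columnwise sums); its metadata
    records the treatment and the number of temporal samples pooled, which
    downstream analyses use for per-sample abundance averages.
    """
    pooled = matrix.counts.groupby(level="plot_id").sum()
    meta = matrix.meta.groupby(level="plot_id").agg(
        treatment=("treatment", "first"), n_samples=("treatment", "size")
    )
    # drop taxa that vanish (cannot happen when pooling a valid matrix,
    # but keeps the constructor invariant explicit)
    return AbundanceMatrix(
        counts=pooled.loc[:, pooled.sum(axis=0) > 0].astype(int),
        meta=meta.loc[pooled.index],
        taxon_level=matrix.taxon_level,
    )
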