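"""Shared data model and tabular I/O.

Survey data are long-format tables with one row per (period, patch, species)
observation. Periods are hydrological regimes in the canonical four-winter
design (ER, LR, NR, ED) but arbitrary period labels are accepted. All
downstream analyses consume the :class:`AbundanceMatrix` produced here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import FormatError, ValidationError

#: The four canonical hydrological regimes: early recession, late recession,
#: normal recession, extreme drought. Free-text labels are also accepted;
#: these four are recognized case-insensitively.
CANONICAL_REGIMES = ("ER", "LR", "NR", "ED")

#: The nine waterbird functional groups (diet / habitat-preference classes).
FUNCTIONAL_GROUPS = (
    "dabbling_ducks",
    "diving_ducks",
    "diving_fishers",
    "gulls",
    "large_wading_birds",
    "small_wading_birds",
    "herbivorous_geese",
    "tuber_feeding_birds",
    "vegetation_gleaners",
)

#: Default column names for long-format survey tables.
SURVEY_COLUMNS = ("period", "patch_id", "subregion", "species",
                  "functional_group", "count")


def canonical_period(label: str) -> str:
    """Return the canonical regime spelling for *label* if it matches one of
    ER/LR/NR/ED case-insensitively, else the label unchanged."""
    up = str(label).strip().upper()
    return up if up in CANONICAL_REGIMES else str(label).strip()


#: The four canonical regimes in calendar order of the study winters.
CHRONOLOGICAL_REGIMES = ("ER", "LR", "NR", "ED")


def chronological_periods(periods: Sequence[str]) -> list[str]:
    """Order *periods* chronologically when they are canonical regimes.

    If every label is one of ER/LR/NR/ED, returns them in calendar order
    (ER, LR, NR, ED); otherwise returns the input order unchanged. Useful
    after reading a sorted table, where first-appearance order is
    alphabetical rather than temporal.
    """
    periods = list(periods)
    if set(periods) <= set(CHRONOLOGICAL_REGIMES):
        return [p for p in CHRONOLOGICAL_REGIMES if p in periods]
    return periods


@dataclass(frozen=True)
class SurveyRecord:
    """One survey observation: a species count in a patch during a period."""

    period: str
    patch_id: str
    subregion: str
    species: str
    functional_group: str
    count: int

    def __post_init__(self):
        if self.count < 0:
            raise ValidationError(
                f"negative count {self.count} for "
                f"({self.period}, {self.patch_id}, {self.species})"
            )


@dataclass
class SurveySet:
    """A collection of survey records with an explicit period ordering.

    Invariants: every record's period appears in ``periods``; ``periods`` is
    non-empty (unless there are no records) and duplicate-free; the key
    (period, patch_id, species) is unique across records.
    """

    records: list[SurveyRecord] = field(default_factory=list)
    periods: list[str] = field(default_factory=list)

    def __post_init__(self):
        if len(set(self.periods)) != len(self.periods):
            raise ValidationError("duplicate period labels in period order")
        pset = set(self.periods)
        seen: set[tuple[str, str, str]] = set()
        for r in self.records:
            if r.period not in pset:
                raise ValidationError(
                    f"record period {r.period!r} not in declared periods"
                )
            key = (r.period, r.patch_id, r.species)
            if key in seen:
                raise ValidationError(f"duplicate survey key {key}")
            seen.add(key)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.period, r.patch_id, r.subregion, r.species,
              r.functional_group, r.count) for r in self.records],
            columns=list(SURVEY_COLUMNS),
        )

    def subset_period(self, period: str) -> list[SurveyRecord]:
        if period not in self.periods:
            raise KeyError(f"unknown period {period!r}")
        return [r for r in self.records if r.period == period]


@dataclass
class AbundanceMatrix:
    """Species x patch count matrix for a single period.

    Rows are species, columns are patches, both in lexicographic order.
    """

    period: str
    species_ids: list[str]
    patch_ids: list[str]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.species_ids), len(self.patch_ids)):
            raise ValidationError(
                f"matrix shape {self.counts.shape} does not match id lists "
                f"({len(self.species_ids)} species, {len(self.patch_ids)} patches)"
            )
        if (self.counts < 0).any():
            raise ValidationError("abundance matrix contains negative entries")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.species_ids,
                            columns=self.patch_ids)


@dataclass
class PatchAttributes:
    """Static environmental attributes of one habitat patch.

    Areas are km²; ``disturbance`` is an ordinal human-disturbance index or a
    density value; ``protection`` an ordinal protection level. Elevation (m)
    and perimeter (km) are optional (needed only for inundation duration and
    the shape index).
    """

    patch_id: str
    wetland_area: float
    water_area: float = 0.0
    mudflat_area: float = 0.0
    vegetation_area: float = 0.0
    disturbance: float = 0.0
    protection: float = 0.0
    elevation: float | None = None
    perimeter: float | None = None

    # the three habitat classes need not tile the wetland exactly
    # (open ground, reed masks...); allow 5% slack above the total
    AREA_TOLERANCE = 0.05

    def __post_init__(self):
        for name in ("wetland_area", "water_area", "mudflat_area",
                     "vegetation_area"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} < 0 for patch {self.patch_id}")
        habitat = self.water_area + self.mudflat_area + self.vegetation_area
        if habitat > self.wetland_area * (1 + self.AREA_TOLERANCE) + 1e-12:
            raise ValidationError(
                f"habitat areas ({habitat:.3f}) exceed wetland area "
                f"({self.wetland_area:.3f}) beyond tolerance for patch "
                f"{self.patch_id}"
            )


def read_survey_table(
    path: str | Path,
    *,
    delimiter: str = "\t",
    column_map: Mapping[str, str] | None = None,
    period_order: Sequence[str] | None = None,
) -> SurveySet:
    """Read a long-format survey table into a :class:`SurveySet`.

    Rows sharing the same (period, patch, species) key are summed. Period
    order is first-appearance order in the file unless *period_order* is
    given. *column_map* maps the canonical field names (``period``,
    ``patch_id``, ...) to the header names actually used in the file.

    Raises :class:`FormatError` if a required column is missing and
    :class:`ValidationError` (with the offending row number) on negative
    counts.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    colmap = {k: k for k in SURVEY_COLUMNS}
    if column_map:
        colmap.update(column_map)
    for field_name, col in colmap.items():
        if col not in df.columns:
            raise FormatError(
                f"{path.name}: missing required column {col!r} "
                f"(for field {field_name!r})"
            )
    df = df.rename(columns={v: k for k, v in colmap.items()})
    if df.empty:
        return SurveySet([], list(period_order or []))

    try:
        counts = pd.to_numeric(df["count"])
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path.name}: non-numeric count: {exc}") from exc
    neg = np.flatnonzero(counts.to_numpy() < 0)
    if neg.size:
        # +2: one for the header line, one for 1-based numbering
        raise ValidationError(
            f"{path.name}: negative count at data row {neg[0] + 2}"
        )
    df["count"] = counts.astype(int)
    df["period"] = df["period"].map(canonical_period)

    file_order = list(dict.fromkeys(df["period"]))
    if period_order is not None:
        periods = [canonical_period(p) for p in period_order]
        unknown = set(file_order) - set(periods)
        if unknown:
            raise ValidationError(
                f"periods {sorted(unknown)} in file but not in period_order"
            )
    else:
        periods = file_order

    grouped = (
        df.groupby(["period", "patch_id", "species"], sort=False)
        .agg(subregion=("subregion", "first"),
             functional_group=("functional_group", "first"),
             count=("count", "sum"))
        .reset_index()
    )
    records = [
        SurveyRecord(row.period, row.patch_id, row.subregion, row.species,
                     row.functional_group, int(row.count))
        for row in grouped.itertuples(index=False)
    ]
    return SurveySet(records, periods)


def to_abundance_matrix(s: SurveySet, period: str) -> AbundanceMatrix:
    """Build the species x patch count matrix for one period.

    Only species and patches observed in that period appear; absent
    combinations are zero; rows and columns are sorted lexicographically.
    """
    records = s.subset_period(period)  # raises KeyError on unknown period
    species = sorted({r.species for r in records})
    patches = sorted({r.patch_id for r in records})
    srow = {sp: i for i, sp in enumerate(species)}
    pcol = {p: j for j, p in enumerate(patches)}
    counts = np.zeros((len(species), len(patches)), dtype=int)
    for r in records:
        counts[srow[r.species], pcol[r.patch_id]] = r.count
    return AbundanceMatrix(period, species, patches, counts)


def read_patch_attributes(
    path: str | Path, *, delimiter: str = "\t"
) -> dict[str, PatchAttributes]:
    """Read a patch attribute table keyed by patch_id.

    Required columns: patch_id, wetland_area. Optional: water_area,
    mudflat_area, vegetation_area, disturbance, protection, elevation,
    perimeter.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter)
    if "patch_id" not in df.columns or "wetland_area" not in df.columns:
        raise FormatError(
            f"{path.name}: patch attribute table needs 'patch_id' and "
            f"'wetland_area' columns"
        )
    optional = ("water_area", "mudflat_area", "vegetation_area",
                "disturbance", "protection", "elevation", "perimeter")
    out: dict[str, PatchAttributes] = {}
    for row in df.itertuples(index=False):
        kwargs = {"patch_id": str(row.patch_id),
                  "wetland_area": float(row.wetland_area)}
        for name in optional:
            if hasattr(row, name):
                val = getattr(row, name)
                if val is not None and not (isinstance(val, float) and math.isnan(val)):
                    kwargs[name] = float(val)
        out[kwargs["patch_id"]] = PatchAttributes(**kwargs)
    return out


def read_patch_roster(
    path: str | Path, *, delimiter: str = "\t"
) -> dict[str, set[str]]:
    """Read a patch roster marking which patches were surveyed per period.

    Expected columns: period, patch_id, surveyed (1/0 or true/false). Returns
    a map period -> set of surveyed patch ids; downstream temporal
    comparisons can then exclude not-surveyed patches rather than treating
    them as true absences.
    """
    df = pd.read_csv(Path(path), sep=delimiter, dtype=str)
    for col in ("period", "patch_id", "surveyed"):
        if col not in df.columns:
            raise FormatError(f"roster missing required column {col!r}")
    truthy = {"1", "true", "yes", "y"}
    out: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        if str(row.surveyed).strip().lower() in truthy:
            out.setdefault(canonical_period(row.period), set()).add(
                str(row.patch_id))
    return out


def write_table(rows: pd.DataFrame, path: str | Path, *,
                delimiter: str = "\t") -> None:
    """Write a result table as delimited UTF-8 text, deterministically.

    Rows are sorted lexicographically by their leading (leftmost) columns so
    re-runs on identical input produce byte-identical files. Reals are
    printed at 12 significant digits so a read-back reproduces them.
    """
    df = pd.DataFrame(rows).copy()
    if len(df):
        df = df.sort_values(by=list(df.columns), kind="mergesort",
                            ignore_index=True)
    df.to_csv(Path(path), sep=delimiter, index=False, float_format="%.12g",
              encoding="utf-8", lineterminator="\n")


def read_table(path: str | Path, *, delimiter: str = "\t") -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(Path(path), sep=delimiter)
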