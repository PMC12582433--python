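"""Readers, writers and validation for aggregated registry-style tables.

Cancer registries and claims-data holders publish rates and proportions on
5-year age groups (with an open-ended 85+ category), while statistical
offices publish population counts by single year of age.  This module
defines the two table containers used throughout the package and the CSV
round-trip for them, plus the long-format writer for result surfaces.

CSV schemas (comma-separated, UTF-8, header mandatory):

* age-group tables: ``year,sex,age_low,age_high,value`` — an open-ended top
  group is encoded as ``age_high = -1``;
* population tables: ``year,sex,age,count``;
* output surfaces: ``year,sex,age,value`` sorted by (sex, year, age).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

SEXES = ("female", "male")

#: sentinel value of ``age_high`` marking an open-ended top age group (85+)
OPEN_AGE_HIGH = -1

AGE_GROUP_COLUMNS = ("year", "sex", "age_low", "age_high", "value")
POPULATION_COLUMNS = ("year", "sex", "age", "count")
SURFACE_COLUMNS = ("year", "sex", "age", "value")


class SchemaError(ValueError):
    """A file does not match the documented CSV schema."""


class ValidationError(ValueError):
    """A table violates a content invariant."""


def _require_columns(df: pd.DataFrame, columns, path) -> None:
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column '{col}'")


def _check_sexes(df: pd.DataFrame) -> None:
    bad = ~df["sex"].isin(SEXES)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"row {row}: sex must be one of {SEXES}, got {df['sex'].iloc[row]!r}"
        )


@dataclass(frozen=True)
class AgeGroupTable:
    """Aggregated rates or proportions on closed age groups plus an
    optional open-ended top group per (year, sex) stratum.

    ``kind`` is ``'rate'`` (values >= 0, units person-year^-1) or
    ``'proportion'`` (values in [0, 1)).  Within each stratum the groups
    must be non-overlapping and contiguous; the open group, if present,
    must sit on top of the closed ones.
    """

    data: pd.DataFrame
    kind: str = "rate"

    def __post_init__(self) -> None:
        if self.kind not in ("rate", "proportion"):
            raise ValueError(f"kind must be 'rate' or 'proportion', got {self.kind!r}")
        df = self.data.loc[:, list(AGE_GROUP_COLUMNS)].reset_index(drop=True)
        try:
            df = df.astype(
                {"year": int, "sex": str, "age_low": int, "age_high": int, "value": float}
            )
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"age-group table has non-numeric fields: {exc}") from exc
        _validate_age_groups(df, self.kind)
        object.__setattr__(self, "data", df)

    @property
    def sexes(self) -> tuple:
        return tuple(sorted(self.data["sex"].unique()))

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.data["year"].unique())

    def for_sex(self, sex: str) -> "AgeGroupTable":
        sub = self.data[self.data["sex"] == sex]
        if sub.empty:
            raise ValidationError(f"no rows for sex {sex!r}")
        return AgeGroupTable(sub.reset_index(drop=True), kind=self.kind)

    def closed_groups(self, year: int, sex: str) -> pd.DataFrame:
        """Closed groups of one stratum, sorted by age_low."""
        sub = self.data[
            (self.data["year"] == year)
            & (self.data["sex"] == sex)
            & (self.data["age_high"] != OPEN_AGE_HIGH)
        ]
        return sub.sort_values("age_low").reset_index(drop=True)


def _validate_age_groups(df: pd.DataFrame, kind: str) -> None:
    if df.empty:
        raise ValidationError("no rows")
    _check_sexes(df)
    neg = df["value"].to_numpy() < 0
    if neg.any():
        row = int(np.flatnonzero(neg)[0])
        raise ValidationError(f"row {row}: negative value {df['value'].iloc[row]}")
    if kind == "proportion":
        big = df["value"].to_numpy() >= 1.0
        if big.any():
            row = int(np.flatnonzero(big)[0])
            raise ValidationError(f"row {row}: proportion >= 1 ({df['value'].iloc[row]})")
    if (df["age_low"] < 0).any():
        row = int(np.flatnonzero((df["age_low"] < 0).to_numpy())[0])
        raise ValidationError(f"row {row}: negative age_low")
    closed = df["age_high"] != OPEN_AGE_HIGH
    bad_bounds = closed & (df["age_low"] > df["age_high"])
    if bad_bounds.any():
        row = int(np.flatnonzero(bad_bounds.to_numpy())[0])
        raise ValidationError(f"row {row}: age_low > age_high")

    for (year, sex), g in df.groupby(["year", "sex"], sort=False):
        g = g.sort_values("age_low")
        opens = g[g["age_high"] == OPEN_AGE_HIGH]
        if len(opens) > 1:
            raise ValidationError(f"stratum ({year}, {sex}): multiple open age groups")
        closed_g = g[g["age_high"] != OPEN_AGE_HIGH]
        lows = closed_g["age_low"].to_numpy()
        highs = closed_g["age_high"].to_numpy()
        for k in range(1, len(lows)):
            if lows[k] <= highs[k - 1]:
                raise ValidationError(
                    f"stratum ({year}, {sex}): overlapping age groups "
                    f"[{lows[k - 1]}, {highs[k - 1]}] and [{lows[k]}, ...]"
                )
            if lows[k] != highs[k - 1] + 1:
                raise ValidationError(
                    f"stratum ({year}, {sex}): non-contiguous age coverage between "
                    f"{highs[k - 1]} and {lows[k]}"
                )
        if len(opens) == 1:
            open_low = int(opens["age_low"].iloc[0])
            if len(closed_g):
                if open_low <= highs[-1]:
                    raise ValidationError(
                        f"stratum ({year}, {sex}): open group overlaps closed groups"
                    )
                if open_low != highs[-1] + 1:
                    raise ValidationError(
                        f"stratum ({year}, {sex}): open group not contiguous with closed groups"
                    )


@dataclass(frozen=True)
class PopulationTable:
    """Population counts by calendar year, sex and single year of age."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.loc[:, list(POPULATION_COLUMNS)].reset_index(drop=True)
        if df.empty:
            raise ValidationError("no rows")
        try:
            df = df.astype({"year": int, "sex": str, "age": int, "count": float})
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"population table has non-numeric fields: {exc}") from exc
        _check_sexes(df)
        neg = df["count"].to_numpy() < 0
        if neg.any():
            row = int(np.flatnonzero(neg)[0])
            raise ValidationError(f"row {row}: negative count {df['count'].iloc[row]}")
        dup = df.duplicated(subset=["year", "sex", "age"])
        if dup.any():
            row = int(np.flatnonzero(dup.to_numpy())[0])
            key = tuple(df.loc[row, ["year", "sex", "age"]])
            raise ValidationError(f"duplicate (year, sex, age) key {key}")
        object.__setattr__(self, "data", df)

    def lookup(self) -> pd.Series:
        """Counts indexed by (year, sex, age)."""
        return self.data.set_index(["year", "sex", "age"])["count"]


def read_age_group_table(path, kind: str) -> AgeGroupTable:
    """Read and validate an aggregated age-group table from CSV."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, AGE_GROUP_COLUMNS, path)
    return AgeGroupTable(df, kind=kind)


def read_population(path) -> PopulationTable:
    """Read and validate a single-age population table from CSV."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValidationError(f"{path}: no rows")
    _require_columns(df, POPULATION_COLUMNS, path)
    return PopulationTable(df)


def write_age_group_table(table: AgeGroupTable, path) -> None:
    table.data.to_csv(path, index=False)


def write_population(population: PopulationTable, path) -> None:
    population.data.to_csv(path, index=False)


def _as_long_frame(surface) -> pd.DataFrame:
    if isinstance(surface, pd.DataFrame):
        for col in SURFACE_COLUMNS:
            if col not in surface.columns:
                raise SchemaError(f"surface frame missing column '{col}'")
        return surface.loc[:, list(SURFACE_COLUMNS)].copy()
    if hasattr(surface, "to_long_frame"):
        return _as_long_frame(surface.to_long_frame())
    raise TypeError(f"cannot write object of type {type(surface).__name__} as a surface")


def write_surface(surface, path) -> None:
    """Write a prevalence surface or survivor table as long-format CSV.

    Output columns are ``year,sex,age,value`` sorted by (sex, year, age);
    values round-trip bit-exactly through :func:`read_surface`.
    """
    df = _as_long_frame(surface)
    df = df.sort_values(["sex", "year", "age"], kind="mergesort").reset_index(drop=True)
    df.to_csv(path, index=False)


def read_surface(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, SURFACE_COLUMNS, path)
    df = df.astype({"year": int, "sex": str, "age": int, "value": float})
    return df.sort_values(["sex", "year", "age"], kind="mergesort").reset_index(drop=True)
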