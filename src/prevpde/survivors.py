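"""Absolute survivor counts from prevalence surfaces and population data.

Lifetime prevalence answers "what fraction of people alive at (t, a) have
ever been diagnosed"; multiplying by the population count N(t, a) turns it
into the absolute number of survivors, the quantity health planners need.
Counts are kept as reals throughout — rounding happens only in the
human-readable report, so totals never accumulate rounding error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .solver import PrevalenceSurface
from .tables import PopulationTable, ValidationError

__all__ = ["SurvivorTable", "survivors", "summarize", "render_report"]


@dataclass(frozen=True)
class SurvivorTable:
    """Row-wise survivors = prevalence x population, with per-stratum totals.

    ``data`` columns: year, sex, age, prevalence, population, survivors.
    ``totals``: survivors summed over ages per (year, sex).
    """

    data: pd.DataFrame
    totals: pd.DataFrame

    def to_long_frame(self) -> pd.DataFrame:
        return self.data.rename(columns={"survivors": "value"})[
            ["year", "sex", "age", "value"]
        ]


def survivors(
    surfaces: Iterable[PrevalenceSurface] | PrevalenceSurface,
    population: PopulationTable,
) -> SurvivorTable:
    """Combine prevalence surfaces (one per sex) with population counts.

    Every (year, sex, age) cell of each surface must have a population
    count; a missing cell raises a validation error naming it.
    """
    if isinstance(surfaces, PrevalenceSurface):
        surfaces = [surfaces]
    frames = []
    lookup = population.lookup()
    for surface in surfaces:
        df = surface.to_long_frame().rename(columns={"value": "prevalence"})
        idx = pd.MultiIndex.from_frame(df[["year", "sex", "age"]])
        missing = ~idx.isin(lookup.index)
        if missing.any():
            row = df.loc[np.flatnonzero(missing)[0]]
            cell = (int(row["year"]), str(row["sex"]), int(row["age"]))
            raise ValidationError(f"population is missing cell (year, sex, age) = {cell}")
        df["population"] = lookup.loc[idx].to_numpy()
        df["survivors"] = df["prevalence"] * df["population"]
        frames.append(df)
    data = pd.concat(frames, ignore_index=True).sort_values(
        ["sex", "year", "age"], kind="mergesort"
    ).reset_index(drop=True)
    totals = (
        data.groupby(["year", "sex"], as_index=False)["survivors"]
        .sum()
        .sort_values(["sex", "year"], kind="mergesort")
        .reset_index(drop=True)
    )
    return SurvivorTable(data=data, totals=totals)


def summarize(table: SurvivorTable) -> pd.DataFrame:
    """Per-year summary: totals per sex, combined both-sex totals, and the
    age of maximum prevalence (ties broken toward the older age)."""
    rows = []
    for (year, sex), g in table.data.groupby(["year", "sex"]):
        peak = g.sort_values(["prevalence", "age"]).iloc[-1]
        total = float(g["survivors"].sum())
        rows.append(
            {"year": int(year), "sex": sex, "survivors_total": total,
             "peak_prevalence_age": int(peak["age"])}
        )
    both = (
        pd.DataFrame(rows)
        .groupby("year", as_index=False)["survivors_total"]
        .sum()
    )
    for _, r in both.iterrows():
        rows.append(
            {"year": int(r["year"]), "sex": "both",
             "survivors_total": float(r["survivors_total"]),
             "peak_prevalence_age": pd.NA}
        )
    out = pd.DataFrame(rows).sort_values(["year", "sex"], kind="mergesort")
    return out.reset_index(drop=True)


def render_report(summary: pd.DataFrame) -> str:
    """Human-readable summary; counts rounded here and only here."""
    lines = ["year  sex     survivors  peak-prevalence age"]
    for _, r in summary.iterrows():
        peak = "-" if pd.isna(r["peak_prevalence_age"]) else f"{int(r['peak_prevalence_age'])}"
        lines.append(
            f"{int(r['year'])}  {r['sex']:<7}{round(float(r['survivors_total'])):>9}  {peak:>6}"
        )
    return "\n".join(lines)
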