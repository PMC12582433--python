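"""End-to-end estimation pipeline: tables in, prevalence + survivors out.

This is the library behind the ``prevpde estimate`` command.  Sexes are
processed independently end to end; the diseased mortality enters either
directly (``mortality_mode: direct``) or derived from population
cause-specific mortality (``mortality_mode: cause_specific``, the default,
matching what cause-of-death statistics publish).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .rates import derive_m1_direct, interpolate_groups
from .solver import (
    PrevalenceSurface,
    SolverSettings,
    hazards_from_cause_specific,
    hazards_from_m1,
    solve_surface,
)
from .survivors import SurvivorTable, render_report, summarize, survivors
from .tables import read_age_group_table, read_population, write_surface

__all__ = [
    "EstimateResult",
    "estimate_surfaces",
    "load_config",
    "run_estimate",
    "write_outputs",
]

DEFAULT_CONFIG = {
    "t0": 2010,
    "t1": 2019,
    "max_age": 85,
    "mortality_mode": "cause_specific",
    "cause_specific_form": "via_m1",
    "anchor_zero_at_birth": True,
    "scheme": "rk4",
    "step_size": 0.1,
}


@dataclass
class EstimateResult:
    surfaces: dict  # sex -> PrevalenceSurface
    survivor_table: SurvivorTable
    summary: "pd.DataFrame"
    log: list = field(default_factory=list)


def load_config(path) -> dict:
    path = Path(path)
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError(f"{path}: config must be a mapping")
    merged = {**DEFAULT_CONFIG, **config}
    # input paths are relative to the config file
    inputs = merged.get("inputs", {})
    merged["inputs"] = {k: str((path.parent / v)) for k, v in inputs.items()}
    if merged["t0"] >= merged["t1"]:
        raise ValueError("t0 must be < t1")
    if merged["max_age"] > 85:
        raise ValueError("max_age must be <= 85 (no data beyond the open 85+ group)")
    return merged


def estimate_surfaces(
    tables: dict,
    year_range: tuple,
    max_age: int = 85,
    mortality_mode: str = "cause_specific",
    cause_specific_form: str = "via_m1",
    anchor_zero_at_birth: bool = True,
    settings: SolverSettings | None = None,
    log: list | None = None,
) -> dict:
    """Solve the PDE from in-memory age-group tables, per sex.

    ``tables`` must hold :class:`~prevpde.tables.AgeGroupTable` objects
    under the keys ``incidence``, ``general_mortality``,
    ``initial_prevalence`` and, depending on ``mortality_mode``,
    ``diseased_mortality`` (direct) or ``cause_specific_mortality``
    (cause_specific).  Returns ``{sex: PrevalenceSurface}``.
    """
    if mortality_mode not in ("direct", "cause_specific"):
        raise ValueError(
            f"mortality_mode must be 'direct' or 'cause_specific', got {mortality_mode!r}"
        )
    settings = settings or SolverSettings()
    surfaces: dict = {}
    for sex in tables["incidence"].sexes:
        i_surf = interpolate_groups(tables["incidence"], sex=sex, quantity="incidence")
        m_surf = interpolate_groups(
            tables["general_mortality"], sex=sex, quantity="general_mortality"
        )
        p0_surf = interpolate_groups(
            tables["initial_prevalence"],
            sex=sex,
            anchor_zero_at_birth=anchor_zero_at_birth,
            quantity="initial_prevalence",
        )
        if mortality_mode == "direct":
            m1_surf = derive_m1_direct(tables["diseased_mortality"], sex=sex)
            hazards = hazards_from_m1(i_surf, m1_surf, m_surf)
        else:
            mu_surf = interpolate_groups(
                tables["cause_specific_mortality"], sex=sex,
                quantity="cause_specific_mortality",
            )
            hazards = hazards_from_cause_specific(
                i_surf, mu_surf, m_surf, form=cause_specific_form
            )
        surface = solve_surface(
            p0_surf,
            hazards,
            year_range=year_range,
            age_range=(0, max_age),
            settings=settings,
            sex=sex,
        )
        if log is not None:
            for key in ("clamp_events", "negative_excess"):
                if surface.metadata.get(key):
                    log.append({"event": key, "sex": sex, "count": surface.metadata[key]})
        surfaces[sex] = surface
    return surfaces


def run_estimate(config: dict) -> EstimateResult:
    """Run the full estimation: read tables, interpolate, solve, count."""
    cfg = {**DEFAULT_CONFIG, **config}
    inputs = cfg["inputs"]
    log: list = []
    mode = cfg["mortality_mode"]

    tables = {
        "incidence": read_age_group_table(inputs["incidence"], kind="rate"),
        "general_mortality": read_age_group_table(inputs["general_mortality"], kind="rate"),
        "initial_prevalence": read_age_group_table(
            inputs["initial_prevalence"], kind="proportion"
        ),
    }
    if mode == "direct":
        tables["diseased_mortality"] = read_age_group_table(
            inputs["diseased_mortality"], kind="rate"
        )
    else:
        tables["cause_specific_mortality"] = read_age_group_table(
            inputs["cause_specific_mortality"], kind="rate"
        )
    population = read_population(inputs["population"])

    surfaces = estimate_surfaces(
        tables,
        year_range=(int(cfg["t0"]), int(cfg["t1"])),
        max_age=int(cfg["max_age"]),
        mortality_mode=mode,
        cause_specific_form=cfg["cause_specific_form"],
        anchor_zero_at_birth=bool(cfg["anchor_zero_at_birth"]),
        settings=SolverSettings(step_size=cfg["step_size"], scheme=cfg["scheme"]),
        log=log,
    )
    table = survivors(list(surfaces.values()), population)
    summary = summarize(table)
    return EstimateResult(surfaces=surfaces, survivor_table=table, summary=summary, log=log)


def write_outputs(result: EstimateResult, out_dir) -> dict:
    """Write prevalence.csv, survivors.csv, summary.csv, report.txt and
    the structured warning log (JSON lines)."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    prevalence = pd.concat(
        [s.to_long_frame() for s in result.surfaces.values()], ignore_index=True
    )
    paths["prevalence"] = out / "prevalence.csv"
    write_surface(prevalence, paths["prevalence"])
    paths["survivors"] = out / "survivors.csv"
    result.survivor_table.data.to_csv(paths["survivors"], index=False)
    paths["summary"] = out / "summary.csv"
    result.summary.to_csv(paths["summary"], index=False)
    paths["report"] = out / "report.txt"
    paths["report"].write_text(render_report(result.summary) + "\n")
    paths["log"] = out / "log.jsonl"
    with open(paths["log"], "w") as fh:
        for record in result.log:
            fh.write(json.dumps(record) + "\n")
    return paths
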