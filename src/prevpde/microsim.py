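"""Stochastic illness-death cohort simulation — the independent oracle.

The PDE solver and the simulator share nothing but the scenario's rate
functions: here every individual starts healthy at birth and walks through
the three-state model (healthy -> ill, healthy -> dead, ill -> dead, no
remission) in discrete time, with per-step transition probabilities
1 - exp(-rate * dt) evaluated at the individual's current (calendar time,
age).  Occupancy counts on the integer (year, age) grid then yield a
binomial prevalence estimate p_hat = ill / alive with standard error
sqrt(p_hat * (1 - p_hat) / alive), against which the deterministic
solution can be checked cell by cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .scenarios import Scenario

__all__ = [
    "CohortCounts",
    "OccupancyGrid",
    "PrevalenceEstimate",
    "ComparisonReport",
    "simulate_cohort",
    "simulate_grid",
    "estimate_prevalence",
    "compare_surfaces",
]

HEALTHY, ILL, DEAD = 0, 1, 2


@dataclass
class CohortCounts:
    """State occupancy of one birth cohort at integer ages."""

    sex: str
    birth_year: int
    n: int
    ages: np.ndarray  # integer ages at which counts were recorded
    healthy: np.ndarray
    ill: np.ndarray
    dead: np.ndarray

    def __post_init__(self) -> None:
        total = self.healthy + self.ill + self.dead
        if np.any(total != self.n):
            raise AssertionError("state conservation violated: healthy+ill+dead != n")


def simulate_cohort(
    scenario: Scenario,
    sex: str,
    birth_year: int,
    n: int,
    seed,
    dt: float = 0.05,
    max_age: int | None = None,
) -> CohortCounts:
    """Simulate ``n`` individuals of one birth cohort from birth.

    ``seed`` may be an integer or a :class:`numpy.random.SeedSequence`.
    The cohort is advanced in steps of ``dt`` (which must divide one year)
    up to ``max_age`` (default: the scenario's maximum age, truncated at
    the end of the scenario window), recording state counts at every
    integer age.  Given the same seed the counts are bit-identical.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    per_year = round(1.0 / dt)
    if abs(per_year * dt - 1.0) > 1e-9 or dt > 0.1:
        raise ValueError("dt must divide 1.0 evenly and be <= 0.1")
    if max_age is None:
        max_age = min(scenario.max_age, scenario.t1 - birth_year)
    if max_age < 0:
        raise ValueError("cohort is born after the scenario window")
    rng = np.random.default_rng(seed)

    i_fn = scenario.incidence(sex)
    m0_fn = scenario.mortality_healthy(sex)
    m1_fn = scenario.mortality_ill(sex)
    n_steps = max_age * per_year
    # rates at the start of each step, at the individual's current (t, a)
    aa = np.arange(n_steps) * dt
    tt = birth_year + aa
    p_ill = -np.expm1(-np.asarray(i_fn(tt, aa), float) * dt)
    p_die0 = -np.expm1(-np.asarray(m0_fn(tt, aa), float) * dt)
    p_die1 = -np.expm1(-np.asarray(m1_fn(tt, aa), float) * dt)

    state = np.zeros(n, dtype=np.int8)
    ages = np.arange(max_age + 1)
    healthy = np.empty(max_age + 1, dtype=np.int64)
    ill = np.empty(max_age + 1, dtype=np.int64)
    dead = np.empty(max_age + 1, dtype=np.int64)
    healthy[0], ill[0], dead[0] = n, 0, 0
    for k in range(n_steps):
        u = rng.random(n)
        is_healthy = state == HEALTHY
        is_ill = state == ILL
        pi, pd0, pd1 = p_ill[k], p_die0[k], p_die1[k]
        state[is_healthy & (u < pi)] = ILL
        state[is_healthy & (u >= pi) & (u < pi + pd0)] = DEAD
        state[is_ill & (u < pd1)] = DEAD
        if (k + 1) % per_year == 0:
            a = (k + 1) // per_year
            healthy[a] = int(np.count_nonzero(state == HEALTHY))
            ill[a] = int(np.count_nonzero(state == ILL))
            dead[a] = int(np.count_nonzero(state == DEAD))
    return CohortCounts(
        sex=sex, birth_year=int(birth_year), n=n, ages=ages,
        healthy=healthy, ill=ill, dead=dead,
    )


@dataclass
class OccupancyGrid:
    """Per-cell state counts on the integer (year, age) grid, per sex."""

    years: np.ndarray
    ages: np.ndarray
    healthy: dict
    ill: dict
    dead: dict
    cohort_n: dict  # sex -> per-cell cohort allocation (expected total)
    n_per_sex: int
    dt: float
    seed: int


def simulate_grid(
    scenario: Scenario, n_per_sex: int = 200_000, seed: int = 0, dt: float = 0.05
) -> OccupancyGrid:
    """Cover the scenario window with simulated birth cohorts.

    Individuals are split as evenly as possible over the birth cohorts
    t0 - max_age .. t1 (one characteristic per cohort), each simulated from
    birth with its own child seed, so every (year, age) cell of the window
    receives one cohort's counts.
    """
    t0, t1, a_max = scenario.t0, scenario.t1, scenario.max_age
    birth_years = np.arange(t0 - a_max, t1 + 1)
    n_coh = birth_years.size
    base, extra = divmod(n_per_sex, n_coh)
    alloc = np.full(n_coh, base, dtype=int)
    alloc[:extra] += 1
    years = np.arange(t0, t1 + 1)
    ages = np.arange(0, a_max + 1)
    shape = (years.size, ages.size)

    children = np.random.SeedSequence(seed).spawn(len(scenario.sexes) * n_coh)
    healthy: dict = {}
    ill: dict = {}
    dead: dict = {}
    cohort_n: dict = {}
    for si, sex in enumerate(scenario.sexes):
        h_grid = np.zeros(shape, dtype=np.int64)
        i_grid = np.zeros(shape, dtype=np.int64)
        d_grid = np.zeros(shape, dtype=np.int64)
        n_grid = np.zeros(shape, dtype=np.int64)
        for ci, b in enumerate(birth_years):
            n_c = int(alloc[ci])
            if n_c == 0:
                continue
            counts = simulate_cohort(
                scenario, sex, int(b), n_c, children[si * n_coh + ci], dt=dt
            )
            for a, h, il, d in zip(counts.ages, counts.healthy, counts.ill, counts.dead):
                t = b + a
                if t0 <= t <= t1 and a <= a_max:
                    h_grid[t - t0, a] = h
                    i_grid[t - t0, a] = il
                    d_grid[t - t0, a] = d
                    n_grid[t - t0, a] = n_c
        healthy[sex] = h_grid
        ill[sex] = i_grid
        dead[sex] = d_grid
        cohort_n[sex] = n_grid
    return OccupancyGrid(
        years=years, ages=ages, healthy=healthy, ill=ill, dead=dead,
        cohort_n=cohort_n, n_per_sex=n_per_sex, dt=dt, seed=seed,
    )


@dataclass
class PrevalenceEstimate:
    """Binomial prevalence estimate from occupancy counts.

    Cells where nobody is alive are flagged missing, not zero.
    """

    years: np.ndarray
    ages: np.ndarray
    p_hat: dict  # sex -> array with NaN at missing cells
    se: dict
    alive: dict

    def missing(self, sex: str) -> np.ndarray:
        return ~np.isfinite(self.p_hat[sex])


def estimate_prevalence(grid: OccupancyGrid) -> PrevalenceEstimate:
    """p_hat = ill / (healthy + ill), SE = sqrt(p_hat (1 - p_hat) / alive)."""
    p_hat: dict = {}
    se: dict = {}
    alive_d: dict = {}
    for sex in grid.healthy:
        alive = grid.healthy[sex] + grid.ill[sex]
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(alive > 0, grid.ill[sex] / np.maximum(alive, 1), np.nan)
            s = np.sqrt(p * (1.0 - p) / np.maximum(alive, 1))
        s = np.where(alive > 0, s, np.nan)
        p_hat[sex] = p
        se[sex] = s
        alive_d[sex] = alive
    return PrevalenceEstimate(
        years=grid.years, ages=grid.ages, p_hat=p_hat, se=se, alive=alive_d
    )


@dataclass
class ComparisonReport:
    """Cell-by-cell agreement between a deterministic solution and the
    microsimulation estimate: a cell agrees when
    |p_pde - p_hat| <= z * SE + allowance."""

    n_cells: int
    n_within: int
    n_missing: int
    max_abs_diff: float
    allowance: float
    z: float

    @property
    def frac_within(self) -> float:
        return self.n_within / self.n_cells if self.n_cells else float("nan")

    def passed(self, min_frac: float = 0.99) -> bool:
        return self.frac_within >= min_frac

    def summary(self) -> str:
        return (
            f"{self.n_within}/{self.n_cells} cells "
            f"({100.0 * self.frac_within:.2f}%) within {self.z:g}*SE + "
            f"{self.allowance:g}; max |diff| = {self.max_abs_diff:.5f}; "
            f"{self.n_missing} missing cells"
        )


def compare_surfaces(
    pde: Mapping[str, "PrevalenceSurface"],
    estimate: PrevalenceEstimate,
    allowance: float = 0.002,
    z: float = 3.0,
) -> ComparisonReport:
    """Compare PDE prevalence surfaces against the microsim estimate."""
    n_cells = 0
    n_within = 0
    n_missing = 0
    max_diff = 0.0
    for sex, surface in pde.items():
        p_hat = estimate.p_hat[sex]
        se = estimate.se[sex]
        if surface.values.shape != p_hat.shape:
            raise ValueError("surface grid does not match the estimate grid")
        ok = np.isfinite(p_hat)
        n_missing += int(np.count_nonzero(~ok))
        diff = np.abs(surface.values - p_hat)
        within = ok & (diff <= z * se + allowance)
        n_cells += int(np.count_nonzero(ok))
        n_within += int(np.count_nonzero(within))
        if ok.any():
            max_diff = max(max_diff, float(np.nanmax(diff[ok])))
    return ComparisonReport(
        n_cells=n_cells, n_within=n_within, n_missing=n_missing,
        max_abs_diff=max_diff, allowance=allowance, z=z,
    )
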