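"""Synthetic scenarios: parametric truth rates, their implied prevalence,
and registry-style aggregated input tables.

The real inputs of a lifetime-prevalence analysis (claims prevalence,
registry incidence, cause-of-death mortality, population projections) are
not freely redistributable, so every pipeline stage is exercised against
synthetic scenarios whose truth is known exactly:

* incidence  i(t, a) = alpha * exp(beta * a) * max(1 + gamma*(t - t0), 0)
  — exponential in age with a linear calendar-time trend (clipped at zero
  so the rate stays non-negative in the deep past);
* non-diseased mortality  m0(a) = g_a * exp(g_b * a)  (Gompertz);
* diseased mortality  m1(t, a) = m0(a) + delta0 * exp(delta_trend*(t - t0))
  — a non-negative excess hazard, optionally decaying over calendar time.

The implied prevalence p*(t, a) and cohort survival S(t, a) are obtained by
high-resolution Runge-Kutta integration of the cohort ODE system along
characteristics (birth cohorts), so the truth bundle is fully deterministic;
the stochastic cross-check lives in :mod:`prevpde.microsim`.  Aggregation
back to 5-year age-group tables uses person-time weighting (weights
proportional to the cohort survival), mimicking how registries compute
rates — the mismatch between such group averages and midpoint-anchored
linear interpolation is precisely the discretisation error the estimation
pipeline is meant to tolerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
import yaml

from .rates import RateSurface
from .tables import (
    OPEN_AGE_HIGH,
    SEXES,
    AgeGroupTable,
    PopulationTable,
    write_age_group_table,
    write_population,
    write_surface,
)

__all__ = [
    "SexParams",
    "Scenario",
    "TruthBundle",
    "ScenarioError",
    "build_truth",
    "aggregate_to_groups",
    "make_population",
    "write_bundle",
    "get_scenario",
    "SCENARIOS",
]


class ScenarioError(ValueError):
    """A scenario produces rates or prevalence outside the valid domain."""


@dataclass(frozen=True)
class SexParams:
    """Rate parameters for one sex.

    Units: alpha, gompertz_a, delta0 are rates per person-year; beta,
    gompertz_b are per year of age; gamma and delta_trend are per calendar
    year.
    """

    alpha: float = 1e-4
    beta: float = 0.09
    gamma: float = 0.02
    gompertz_a: float = 2e-5
    gompertz_b: float = 0.095
    delta0: float = 0.02
    delta_trend: float = 0.0


@dataclass(frozen=True)
class Scenario:
    """A fully specified synthetic study: rate functions per sex over a
    calendar window [t0, t1] and ages [0, max_age]."""

    name: str = "default"
    t0: int = 2010
    t1: int = 2019
    max_age: int = 85
    params: Mapping[str, SexParams] = field(
        default_factory=lambda: {s: SexParams() for s in SEXES}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t1 < self.t0:
            raise ScenarioError("t1 must be >= t0")
        for sex in self.params:
            if sex not in SEXES:
                raise ScenarioError(f"unknown sex {sex!r}")

    @property
    def sexes(self) -> tuple:
        return tuple(sorted(self.params))

    def incidence(self, sex: str) -> Callable:
        q = self.params[sex]
        t0 = self.t0

        def i(t, a):
            trend = np.maximum(1.0 + q.gamma * (np.asarray(t, float) - t0), 0.0)
            return q.alpha * np.exp(q.beta * np.asarray(a, float)) * trend

        return i

    def mortality_healthy(self, sex: str) -> Callable:
        q = self.params[sex]

        def m0(t, a):
            out = q.gompertz_a * np.exp(q.gompertz_b * np.asarray(a, float))
            return np.broadcast_arrays(out, np.asarray(t, float))[0]

        return m0

    def excess_hazard(self, sex: str) -> Callable:
        q = self.params[sex]
        t0 = self.t0

        def delta(t, a):
            out = q.delta0 * np.exp(q.delta_trend * (np.asarray(t, float) - t0))
            return np.broadcast_arrays(out, np.asarray(a, float))[0]

        return delta

    def mortality_ill(self, sex: str) -> Callable:
        m0 = self.mortality_healthy(sex)
        delta = self.excess_hazard(sex)

        def m1(t, a):
            return m0(t, a) + delta(t, a)

        return m1

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "t0": self.t0,
            "t1": self.t1,
            "max_age": self.max_age,
            "seed": self.seed,
            "params": {s: vars(q).copy() for s, q in self.params.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        params = {s: SexParams(**q) for s, q in d["params"].items()}
        return cls(
            name=d.get("name", "custom"),
            t0=int(d["t0"]),
            t1=int(d["t1"]),
            max_age=int(d.get("max_age", 85)),
            params=params,
            seed=int(d.get("seed", 0)),
        )


def _default_scenario() -> Scenario:
    return Scenario(name="default")


def _trend_scenario() -> Scenario:
    """Rising incidence and declining excess mortality over the decade,
    with higher male incidence — the qualitative regime reported for
    cancer in high-income countries."""
    female = SexParams(alpha=1e-4, gamma=0.03, delta0=0.03, delta_trend=-0.05)
    male = replace(female, alpha=1.5e-4)
    return Scenario(name="trend", params={"female": female, "male": male})


def _null_scenario() -> Scenario:
    zero = SexParams(alpha=0.0, gamma=0.0, gompertz_a=0.0, delta0=0.0)
    return Scenario(name="null", params={s: zero for s in SEXES})


SCENARIOS = {
    "default": _default_scenario,
    "trend": _trend_scenario,
    "null": _null_scenario,
}


def get_scenario(name: str) -> Scenario:
    try:
        return SCENARIOS[name]()
    except KeyError:
        raise ScenarioError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        ) from None


@dataclass
class TruthBundle:
    """Deterministic truth implied by a scenario.

    ``p_star`` and ``survival`` are stored per sex on integer years
    [t0, t1] x a fine age grid (default 0.5-year spacing); the mixing
    relation m = p*m1 + (1-p)*m0 and mu_c = p*(m1 - m0) hold at every node
    by construction.
    """

    scenario: Scenario
    years: np.ndarray
    ages_fine: np.ndarray
    p_star: dict  # sex -> (n_years, n_ages_fine)
    survival: dict  # sex -> (n_years, n_ages_fine)
    step: float

    @property
    def ages_int(self) -> np.ndarray:
        return self.ages_fine[:: self._per_year()].astype(int)

    def _per_year(self) -> int:
        return int(round(1.0 / (self.ages_fine[1] - self.ages_fine[0])))

    def p_star_grid(self, sex: str) -> np.ndarray:
        """Truth prevalence on the integer (year, age) output grid."""
        return self.p_star[sex][:, :: self._per_year()]

    def p0_profile(self, sex: str) -> np.ndarray:
        """Truth prevalence at t0 on integer ages (solver initial profile)."""
        return self.p_star_grid(sex)[0]

    def p_star_surface(self, sex: str) -> RateSurface:
        return RateSurface(
            "initial_prevalence", sex, self.years.astype(float), self.ages_fine,
            self.p_star[sex],
        )

    def _mesh_rates(self, sex: str):
        tt = self.years.astype(float)[:, None]
        aa = self.ages_fine[None, :]
        m0 = self.scenario.mortality_healthy(sex)(tt, aa)
        m1 = self.scenario.mortality_ill(sex)(tt, aa)
        return m0, m1

    def m_surface(self, sex: str) -> RateSurface:
        """General-population mortality m = p*m1 + (1-p)*m0."""
        m0, m1 = self._mesh_rates(sex)
        p = self.p_star[sex]
        return RateSurface(
            "general_mortality", sex, self.years.astype(float), self.ages_fine,
            p * m1 + (1.0 - p) * m0,
        )

    def mu_c_surface(self, sex: str) -> RateSurface:
        """Population cause-specific mortality mu_c = p*(m1 - m0)."""
        m0, m1 = self._mesh_rates(sex)
        p = self.p_star[sex]
        return RateSurface(
            "cause_specific_mortality", sex, self.years.astype(float),
            self.ages_fine, p * (m1 - m0),
        )

    def m1_grid_surface(self, sex: str) -> RateSurface:
        m0, m1 = self._mesh_rates(sex)
        return RateSurface(
            "diseased_mortality", sex, self.years.astype(float), self.ages_fine, m1
        )

    def to_long_frame(self) -> pd.DataFrame:
        frames = []
        per = self._per_year()
        for sex in sorted(self.p_star):
            vals = self.p_star[sex][:, ::per]
            yy, aa = np.meshgrid(self.years, self.ages_int, indexing="ij")
            frames.append(
                pd.DataFrame(
                    {"year": yy.ravel(), "sex": sex, "age": aa.ravel(),
                     "value": vals.ravel()}
                )
            )
        return pd.concat(frames, ignore_index=True)


def build_truth(
    scenario: Scenario, step: float = 1e-3, age_resolution: float = 0.5
) -> TruthBundle:
    """Reference-integrate the cohort ODE system of a scenario.

    For each birth cohort b (spaced ``age_resolution`` years apart so that
    every (integer year, fine age) cell of the window is covered) the pair

        dp/ds = (1 - p) i(b+s, s) - p (1 - p) (m1 - m0)(b+s, s)
        dS/ds = -(p m1 + (1 - p) m0)(b+s, s) S

    is integrated from (p, S) = (0, 1) at birth with classical RK4 at step
    ``step`` (default 1e-3 years).  Scenarios whose rates drive p >= 1
    anywhere in the window are rejected with the offending location.
    """
    t0, t1, a_max = scenario.t0, scenario.t1, scenario.max_age
    n_rec = int(round(a_max / age_resolution))
    rec_every = int(round(age_resolution / step))
    if abs(rec_every * step - age_resolution) > 1e-12:
        raise ValueError("step must divide age_resolution evenly")
    births = np.round(
        np.arange(t0 - a_max, t1 + age_resolution / 2, age_resolution), 6
    )
    n_steps = n_rec * rec_every
    years = np.arange(t0, t1 + 1)
    ages_fine = np.arange(n_rec + 1) * age_resolution

    # One column per (sex, birth cohort); the scenario's rate family is
    # evaluated inline (incidence exponential-in-age with clipped linear
    # time trend, Gompertz m0, exponential excess trend) so that the 1e-3
    # step stays affordable.  Rates do not depend on the state, so the
    # stage values at the end of one step are reused at the start of the
    # next (RK4 needs only two fresh evaluations per step).
    sexes = scenario.sexes
    ncoh = births.size
    q = [scenario.params[s] for s in sexes]
    alpha_v = np.repeat([x.alpha for x in q], ncoh)
    beta_v = np.repeat([x.beta for x in q], ncoh)
    gamma_v = np.repeat([x.gamma for x in q], ncoh)
    ga_v = np.repeat([x.gompertz_a for x in q], ncoh)
    gb_v = np.repeat([x.gompertz_b for x in q], ncoh)
    d0_v = np.repeat([x.delta0 for x in q], ncoh)
    dtr_v = np.repeat([x.delta_trend for x in q], ncoh)
    b_off = np.tile(births - t0, len(sexes))

    def stage_rates(s: float):
        t_off = b_off + s
        trend = np.maximum(1.0 + gamma_v * t_off, 0.0)
        iv = alpha_v * np.exp(beta_v * s) * trend
        m0v = ga_v * np.exp(gb_v * s)
        dlv = d0_v * np.exp(dtr_v * t_off)
        return iv, m0v, dlv

    h = step
    h2 = h / 2.0
    p = np.zeros(alpha_v.size)
    S = np.ones(alpha_v.size)
    rec_p = np.empty((n_rec + 1, alpha_v.size))
    rec_S = np.empty((n_rec + 1, alpha_v.size))
    rec_p[0] = p
    rec_S[0] = S
    r0 = stage_rates(0.0)
    for k in range(n_steps):
        s0 = k * h
        rh = stage_rates(s0 + h2)
        r1 = stage_rates(s0 + h)
        iv0, m00, dl0 = r0
        ivh, m0h, dlh = rh
        iv1, m01, dl1 = r1
        k1p = (1.0 - p) * iv0 - p * (1.0 - p) * dl0
        k1S = -(m00 + p * dl0) * S
        p2 = p + h2 * k1p
        S2 = S + h2 * k1S
        k2p = (1.0 - p2) * ivh - p2 * (1.0 - p2) * dlh
        k2S = -(m0h + p2 * dlh) * S2
        p3 = p + h2 * k2p
        S3 = S + h2 * k2S
        k3p = (1.0 - p3) * ivh - p3 * (1.0 - p3) * dlh
        k3S = -(m0h + p3 * dlh) * S3
        p4 = p + h * k3p
        S4 = S + h * k3S
        k4p = (1.0 - p4) * iv1 - p4 * (1.0 - p4) * dl1
        k4S = -(m01 + p4 * dl1) * S4
        p = p + (h / 6.0) * (k1p + 2.0 * k2p + 2.0 * k3p + k4p)
        S = S + (h / 6.0) * (k1S + 2.0 * k2S + 2.0 * k3S + k4S)
        r0 = r1
        if (k + 1) % rec_every == 0:
            r = (k + 1) // rec_every
            rec_p[r] = p
            rec_S[r] = S

    p_star: dict = {}
    survival: dict = {}
    age_idx = np.arange(ages_fine.size)
    for si, sex in enumerate(sexes):
        grid_p = np.empty((years.size, ages_fine.size))
        grid_S = np.empty((years.size, ages_fine.size))
        for yi, t in enumerate(years):
            cidx = si * ncoh + np.round(
                (t - ages_fine - births[0]) / age_resolution
            ).astype(int)
            grid_p[yi] = rec_p[age_idx, cidx]
            grid_S[yi] = rec_S[age_idx, cidx]
        if np.any(grid_p >= 1.0) or np.any(grid_p < 0.0):
            bad = np.argwhere((grid_p >= 1.0) | (grid_p < 0.0))[0]
            raise ScenarioError(
                f"scenario {scenario.name!r} rejected: p* out of [0, 1) at "
                f"(sex={sex}, year={years[bad[0]]}, age={ages_fine[bad[1]]})"
            )
        p_star[sex] = grid_p
        survival[sex] = grid_S

    return TruthBundle(
        scenario=scenario, years=years, ages_fine=ages_fine,
        p_star=p_star, survival=survival, step=step,
    )


def _age_groups(a_max: int = 85, width: int = 5):
    groups = [(lo, lo + width - 1) for lo in range(0, a_max, width)]
    groups.append((a_max, OPEN_AGE_HIGH))
    return groups


def aggregate_to_groups(
    truth: TruthBundle, prevalence_min_age: int = 15
) -> dict:
    """Aggregate the truth into registry-style 5-year age-group tables.

    Group values are person-time-weighted averages (weights proportional to
    the cohort survival) of the truth over the group's age span; the open
    top group carries the value at the maximum age.  The initial-prevalence
    table covers only the start year and, emulating claims data, only ages
    >= ``prevalence_min_age``.  Returns a dict of
    :class:`~prevpde.tables.AgeGroupTable` keyed by quantity.
    """
    sc = truth.scenario
    ages = truth.ages_fine
    groups = _age_groups(sc.max_age)
    # composite-trapezoid quadrature of the person-time integral over
    # [L, H+1]; the open top group carries the value at the maximum age
    masks = []
    quad_w = []
    for lo, hi in groups:
        if hi == OPEN_AGE_HIGH:
            mask = ages >= sc.max_age
            w = np.ones(int(np.count_nonzero(mask)))
        else:
            mask = (ages >= lo) & (ages <= hi + 1)
            w = np.ones(int(np.count_nonzero(mask)))
            w[0] = 0.5
            w[-1] = 0.5
        masks.append(mask)
        quad_w.append(w)

    quantities = {
        "incidence": "rate",
        "general_mortality": "rate",
        "cause_specific_mortality": "rate",
        "diseased_mortality": "rate",
        "initial_prevalence": "proportion",
    }
    rows: dict = {q: [] for q in quantities}
    for sex in sc.sexes:
        tt = truth.years.astype(float)[:, None]
        aa = ages[None, :]
        i_vals = sc.incidence(sex)(tt, aa)
        m0_vals = sc.mortality_healthy(sex)(tt, aa)
        m1_vals = sc.mortality_ill(sex)(tt, aa)
        p = truth.p_star[sex]
        fields = {
            "incidence": i_vals,
            "general_mortality": p * m1_vals + (1.0 - p) * m0_vals,
            "cause_specific_mortality": p * (m1_vals - m0_vals),
            "diseased_mortality": m1_vals,
            "initial_prevalence": p,
        }
        w = truth.survival[sex]
        for yi, year in enumerate(truth.years):
            for (lo, hi), mask, qw in zip(groups, masks, quad_w):
                wk = w[yi, mask] * qw
                wk_sum = wk.sum()
                for q, vals in fields.items():
                    if q == "initial_prevalence" and (
                        year != sc.t0 or (hi != OPEN_AGE_HIGH and lo < prevalence_min_age)
                        or (hi == OPEN_AGE_HIGH and sc.max_age < prevalence_min_age)
                    ):
                        continue
                    avg = float(np.sum(wk * vals[yi, mask]) / wk_sum)
                    rows[q].append(
                        {"year": int(year), "sex": sex, "age_low": lo,
                         "age_high": hi, "value": avg}
                    )
    return {
        q: AgeGroupTable(pd.DataFrame(rows[q]), kind=kind)
        for q, kind in quantities.items()
    }


def make_population(
    truth: TruthBundle,
    base_cohort: float = 100_000.0,
    boom_year: int | None = None,
    boom_amplitude: float = 0.3,
    boom_width: float = 5.0,
) -> PopulationTable:
    """Deterministic synthetic population with the survivorship implied by
    the scenario's mortality.

    Each birth cohort starts at ``base_cohort`` persons (optionally bumped
    by a Gaussian baby-boom factor centred on ``boom_year``) and is thinned
    by the cohort survival S(t, a), so counts decrease with age whenever
    mortality is positive.
    """
    if base_cohort <= 0:
        raise ValueError("base_cohort must be positive")
    per = truth._per_year()
    rows = []
    ages = truth.ages_int
    for sex in truth.scenario.sexes:
        S = truth.survival[sex][:, ::per]
        for yi, year in enumerate(truth.years):
            births = year - ages
            base = np.full(ages.shape, float(base_cohort))
            if boom_year is not None:
                base *= 1.0 + boom_amplitude * np.exp(
                    -0.5 * ((births - boom_year) / boom_width) ** 2
                )
            counts = base * S[yi]
            for a, c in zip(ages, counts):
                rows.append({"year": int(year), "sex": sex, "age": int(a), "count": c})
    return PopulationTable(pd.DataFrame(rows))


def write_bundle(
    truth: TruthBundle,
    out_dir,
    base_cohort: float = 100_000.0,
    boom_year: int | None = None,
    prevalence_min_age: int = 15,
) -> dict:
    """Write a complete, ready-to-estimate input bundle to ``out_dir``.

    Emits the aggregated rate/prevalence tables, a synthetic population,
    the truth prevalence surface, the scenario parameters and an estimation
    config pointing at the files.  Returns the mapping of written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = aggregate_to_groups(truth, prevalence_min_age=prevalence_min_age)
    paths = {}
    for name, table in tables.items():
        p = out / f"{name}.csv"
        write_age_group_table(table, p)
        paths[name] = p
    pop = make_population(truth, base_cohort=base_cohort, boom_year=boom_year)
    paths["population"] = out / "population.csv"
    write_population(pop, paths["population"])
    paths["truth_prevalence"] = out / "truth_prevalence.csv"
    write_surface(truth.to_long_frame(), paths["truth_prevalence"])
    paths["scenario"] = out / "scenario.yaml"
    with open(paths["scenario"], "w") as fh:
        yaml.safe_dump(truth.scenario.to_dict(), fh, sort_keys=False)

    config = {
        "inputs": {
            "incidence": "incidence.csv",
            "general_mortality": "general_mortality.csv",
            "cause_specific_mortality": "cause_specific_mortality.csv",
            "diseased_mortality": "diseased_mortality.csv",
            "initial_prevalence": "initial_prevalence.csv",
            "population": "population.csv",
        },
        "t0": truth.scenario.t0,
        "t1": truth.scenario.t1,
        "max_age": truth.scenario.max_age,
        "mortality_mode": "cause_specific",
        "anchor_zero_at_birth": True,
        "scheme": "rk4",
        "step_size": 0.1,
    }
    paths["config"] = out / "estimate.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return paths
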