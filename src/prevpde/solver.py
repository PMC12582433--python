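"""Method-of-characteristics integration of the illness-death prevalence PDE.

In the three-state illness-death model (healthy -> ill, healthy -> dead,
ill -> dead, no remission) the lifetime prevalence p(t, a) obeys

    (d/dt + d/da) p = (1 - p) * i - p * (m1 - m)

where i is the incidence rate, m1 the all-cause mortality of the diseased
and m = p*m1 + (1-p)*m0 the general-population mortality.  Along a
characteristic line of constant (a - t) — i.e. following one birth cohort —
the PDE reduces to an ODE in the single variable s with t(s) = t0 + s,
a(s) = a0 + s, which is integrated here with a fixed-step Euler or
classical Runge-Kutta scheme.

The excess-mortality term p*(m1 - m) can be supplied in three equivalent
parameterisations, matching what data are available:

* explicit m1 and m (mode A);
* explicit m0 and m1, using m1 - m = (1 - p)(m1 - m0) (used for synthetic
  truth where both transition rates are known);
* cause-specific mortality mu_c and m (mode B), deriving m1 pointwise from
  the mixing relation; at p = 0 the analytic limit p*(m1 - m) -> mu_c is
  used.  A "reduced" variant evaluates the algebraically simplified form
  mu_c*(1 - p) directly; the two variants agree to rounding error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .rates import RateSurface

__all__ = [
    "SolverSettings",
    "PrevalenceSurface",
    "Trajectory",
    "SolverError",
    "pde_rhs",
    "closed_form_constant_rates",
    "hazards_from_m1",
    "hazards_from_m0_m1",
    "hazards_from_cause_specific",
    "solve_characteristic",
    "solve_surface",
    "integrate_fixed_span",
]


class SolverError(RuntimeError):
    """Numerical failure during characteristic integration."""


def pde_rhs(p, i, m1, m):
    """Right-hand side (1 - p)*i - p*(m1 - m) of the prevalence PDE."""
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr < 0) or np.any(p_arr >= 1):
        raise ValueError("p must lie in [0, 1)")
    out = (1.0 - p_arr) * np.asarray(i, float) - p_arr * (
        np.asarray(m1, float) - np.asarray(m, float)
    )
    return float(out) if out.ndim == 0 else out


def closed_form_constant_rates(i, a):
    """Exact solution p(a) = 1 - exp(-i*a) for constant incidence,
    no excess mortality (m1 = m0) and p(0) = 0."""
    return -np.expm1(-np.asarray(i, dtype=float) * np.asarray(a, dtype=float))


@dataclass(frozen=True)
class SolverSettings:
    """Numerical settings for the characteristic integrator.

    ``step_size`` (years) must divide 1.0 evenly so that integration steps
    align with the integer-age output grid.  ``clamp_epsilon`` bounds output
    values away from 1; clamping is applied only at output and counted.
    """

    step_size: float = 0.1
    scheme: str = "rk4"
    clamp_epsilon: float = 1e-9

    def __post_init__(self) -> None:
        n = round(1.0 / self.step_size)
        if n < 1 or abs(n * self.step_size - 1.0) > 1e-9:
            raise ValueError(f"step_size {self.step_size} does not divide 1.0 evenly")
        if self.scheme not in ("euler", "rk4"):
            raise ValueError(f"scheme must be 'euler' or 'rk4', got {self.scheme!r}")
        if not (0 < self.clamp_epsilon <= 1e-6):
            raise ValueError("clamp_epsilon must lie in (0, 1e-6]")

    @property
    def substeps_per_year(self) -> int:
        return round(1.0 / self.step_size)


class Hazards:
    """Incidence plus an excess-mortality evaluator for the PDE."""

    def __init__(self, incidence: Callable, excess: Callable, mode: str):
        self.incidence = incidence
        self._excess = excess
        self.mode = mode
        self.counters = {"negative_excess": 0}

    def excess(self, t, a, p):
        out = self._excess(t, a, p)
        neg = int(np.count_nonzero(np.asarray(out) < 0))
        if neg:
            self.counters["negative_excess"] += neg
        return out

    def rhs(self, t, a, p):
        return (1.0 - p) * self.incidence(t, a) - self.excess(t, a, p)


def hazards_from_m1(i: Callable, m1: Callable, m: Callable) -> Hazards:
    """Mode A hazards: explicit diseased mortality m1 and general m."""

    def excess(t, a, p):
        return p * (m1(t, a) - m(t, a))

    return Hazards(i, excess, mode="m1")


def hazards_from_m0_m1(i: Callable, m0: Callable, m1: Callable) -> Hazards:
    """Hazards from the two transition mortalities; since
    m = p*m1 + (1-p)*m0, the excess term is p*(1-p)*(m1 - m0)."""

    def excess(t, a, p):
        return p * (1.0 - p) * (m1(t, a) - m0(t, a))

    return Hazards(i, excess, mode="m0_m1")


def hazards_from_cause_specific(
    i: Callable, mu_c: Callable, m: Callable, form: str = "via_m1"
) -> Hazards:
    """Mode B hazards from population cause-specific mortality.

    ``form='via_m1'`` derives m1 = mu_c/p + m - mu_c pointwise at the
    current prevalence and evaluates p*(m1 - m); at p = 0 the analytic
    limit mu_c is used.  ``form='reduced'`` evaluates the simplified
    expression mu_c*(1 - p).
    """
    if form not in ("via_m1", "reduced"):
        raise ValueError(f"form must be 'via_m1' or 'reduced', got {form!r}")

    if form == "reduced":

        def excess(t, a, p):
            return mu_c(t, a) * (1.0 - p)

    else:

        def excess(t, a, p):
            mu = np.asarray(mu_c(t, a), dtype=float)
            mv = np.asarray(m(t, a), dtype=float)
            p_arr = np.asarray(p, dtype=float)
            pos = p_arr > 0
            p_safe = np.where(pos, p_arr, 1.0)
            m1 = mu / p_safe + mv - mu
            return np.where(pos, p_arr * (m1 - mv), mu)

    return Hazards(i, excess, mode=f"cause_specific:{form}")


def _rk4_step(hz: Hazards, t, a, p, h: float):
    k1 = hz.rhs(t, a, p)
    k2 = hz.rhs(t + h / 2.0, a + h / 2.0, p + (h / 2.0) * k1)
    k3 = hz.rhs(t + h / 2.0, a + h / 2.0, p + (h / 2.0) * k2)
    k4 = hz.rhs(t + h, a + h, p + h * k3)
    return p + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def _euler_step(hz: Hazards, t, a, p, h: float):
    return p + h * hz.rhs(t, a, p)


def _integrate_batch(
    t_start: np.ndarray,
    a_start: np.ndarray,
    p_start: np.ndarray,
    end_age: np.ndarray,
    hazards: Hazards,
    settings: SolverSettings,
) -> np.ndarray:
    """Integrate a batch of characteristics with integer start ages.

    Returns an array of shape (max_segments + 1, k) holding the trajectory
    of each column sampled at integer ages (NaN beyond a column's end age).
    Row r of column j corresponds to (t_start[j] + r, a_start[j] + r).
    """
    t_start = np.asarray(t_start, dtype=float)
    a_start = np.asarray(a_start, dtype=float)
    end_age = np.asarray(end_age, dtype=float)
    p = np.array(p_start, dtype=float, copy=True)
    if np.any(p < 0) or np.any(p >= 1):
        raise ValueError("start prevalence must lie in [0, 1)")
    if np.any(end_age < a_start):
        raise ValueError("end_age must be >= start age")
    step = _rk4_step if settings.scheme == "rk4" else _euler_step
    h = settings.step_size
    n_sub = settings.substeps_per_year
    max_seg = int(round(np.max(end_age - a_start)))
    records = np.full((max_seg + 1, p.size), np.nan)
    records[0] = p
    for seg in range(max_seg):
        idx = np.flatnonzero(end_age > a_start + seg)
        pj = p[idx]
        tj = t_start[idx] + seg
        aj = a_start[idx] + seg
        for q in range(n_sub):
            s0 = q * h
            pj = step(hazards, tj + s0, aj + s0, pj, h)
        if not np.all(np.isfinite(pj)):
            bad = idx[np.flatnonzero(~np.isfinite(pj))[0]]
            raise SolverError(
                f"non-finite prevalence at (t={t_start[bad] + seg + 1}, "
                f"a={a_start[bad] + seg + 1})"
            )
        p[idx] = pj
        records[seg + 1, idx] = pj
    return records


@dataclass
class Trajectory:
    """One characteristic sampled at integer ages."""

    years: np.ndarray
    ages: np.ndarray
    p: np.ndarray
    clamp_events: int = 0


def _clamp(values: np.ndarray, eps: float):
    finite = np.isfinite(values)
    low = finite & (values < 0.0)
    high = finite & (values > 1.0 - eps)
    n_events = int(np.count_nonzero(low) + np.count_nonzero(high))
    out = values.copy()
    out[low] = 0.0
    out[high] = 1.0 - eps
    return out, n_events


def solve_characteristic(
    p_start: float,
    start: tuple,
    end_age: float,
    hazards: Hazards,
    settings: SolverSettings | None = None,
) -> Trajectory:
    """Integrate one characteristic from (year, age) = ``start`` up to
    ``end_age``, sampling the prevalence at integer ages."""
    settings = settings or SolverSettings()
    t0, a0 = start
    if a0 != int(a0) or end_age != int(end_age):
        raise ValueError("start age and end_age must be integers (output grid)")
    rec = _integrate_batch(
        np.array([t0], float),
        np.array([a0], float),
        np.array([p_start], float),
        np.array([end_age], float),
        hazards,
        settings,
    )[:, 0]
    values, n_clamped = _clamp(rec, settings.clamp_epsilon)
    steps = np.arange(rec.size)
    return Trajectory(
        years=t0 + steps, ages=a0 + steps, p=values, clamp_events=n_clamped
    )


@dataclass
class PrevalenceSurface:
    """Prevalence p(t, a) on an integer year x integer age output grid."""

    sex: str
    years: np.ndarray  # integers t0..t1
    ages: np.ndarray  # integers 0..max_age
    values: np.ndarray  # shape (n_years, n_ages), in [0, 1)
    metadata: dict = field(default_factory=dict)

    def value_at(self, year: int, age: int) -> float:
        yi = int(year - self.years[0])
        ai = int(age - self.ages[0])
        return float(self.values[yi, ai])

    def to_long_frame(self) -> pd.DataFrame:
        yy, aa = np.meshgrid(self.years, self.ages, indexing="ij")
        return pd.DataFrame(
            {
                "year": yy.ravel(),
                "sex": self.sex,
                "age": aa.ravel(),
                "value": self.values.ravel(),
            }
        )

    def as_rate_surface(self) -> RateSurface:
        return RateSurface(
            quantity="initial_prevalence",
            sex=self.sex,
            years=self.years.astype(float),
            ages=self.ages.astype(float),
            values=self.values,
        )


def solve_surface(
    p0,
    hazards: Hazards,
    year_range: tuple,
    age_range: tuple = (0, 85),
    settings: SolverSettings | None = None,
    sex: str = "female",
) -> PrevalenceSurface:
    """Solve the PDE over [t0, t1] x [a_min, a_max].

    ``p0`` supplies the initial profile at t0: a callable of (t, a) (e.g. a
    :class:`~prevpde.rates.RateSurface`), or an array over the output ages.
    Cells with a - (t - t0) >= a_min are reached from the initial profile;
    younger cells are reached from the healthy-at-birth boundary p = 0 at
    age a_min of later cohorts, so p(t, 0) = 0 for all t > t0 when
    a_min = 0.
    """
    settings = settings or SolverSettings()
    t0, t1 = (int(year_range[0]), int(year_range[1]))
    a_min, a_max = (int(age_range[0]), int(age_range[1]))
    if t1 < t0 or a_max < a_min:
        raise ValueError("year_range and age_range must be non-decreasing")
    ages = np.arange(a_min, a_max + 1)
    years = np.arange(t0, t1 + 1)
    if callable(p0):
        p0_vals = np.asarray(p0(np.full(ages.shape, float(t0)), ages.astype(float)))
    else:
        p0_vals = np.asarray(p0, dtype=float)
        if p0_vals.shape != ages.shape:
            raise ValueError("p0 array must match the output age grid")
    if np.any(p0_vals < 0) or np.any(p0_vals >= 1):
        raise ValueError("initial profile must lie in [0, 1)")

    # characteristics seeded on the initial year ...
    starts_t = [float(t0)] * ages.size
    starts_a = [float(a) for a in ages]
    starts_p = list(p0_vals)
    ends = [float(min(a_max, a + (t1 - t0))) for a in ages]
    # ... and on the birth boundary of cohorts born after t0
    for tb in range(t0 + 1, t1 + 1):
        starts_t.append(float(tb))
        starts_a.append(float(a_min))
        starts_p.append(0.0)
        ends.append(float(min(a_max, a_min + (t1 - tb))))

    rec = _integrate_batch(
        np.array(starts_t),
        np.array(starts_a),
        np.array(starts_p),
        np.array(ends),
        hazards,
        settings,
    )
    values = np.full((years.size, ages.size), np.nan)
    for j in range(len(starts_t)):
        n_rec = int(round(ends[j] - starts_a[j]))
        for r in range(n_rec + 1):
            t = int(starts_t[j]) + r
            a = int(starts_a[j]) + r
            if t0 <= t <= t1 and a_min <= a <= a_max:
                values[t - t0, a - a_min] = rec[r, j]
    if np.any(np.isnan(values)):
        raise SolverError("output grid not fully covered by characteristics")
    values, n_clamped = _clamp(values, settings.clamp_epsilon)
    metadata = {
        "step_size": settings.step_size,
        "scheme": settings.scheme,
        "clamp_events": n_clamped,
        "negative_excess": hazards.counters["negative_excess"],
        "mode": hazards.mode,
    }
    return PrevalenceSurface(sex=sex, years=years, ages=ages, values=values, metadata=metadata)


def integrate_fixed_span(
    p_start: float,
    start: tuple,
    span: float,
    step: float,
    hazards: Hazards,
    scheme: str = "rk4",
) -> float:
    """Integrate one characteristic over an arbitrary span with an
    arbitrary (uniform) step and return the final prevalence.

    Unlike :func:`solve_characteristic` this does not sample intermediate
    integer ages, so the step need not divide one year; it is the tool for
    step-refinement (convergence-order) studies.
    """
    n = round(span / step)
    if n < 1 or abs(n * step - span) > 1e-9 * max(1.0, span):
        raise ValueError("step must divide the span evenly")
    stepper = _rk4_step if scheme == "rk4" else _euler_step
    t, a = float(start[0]), float(start[1])
    p = np.array([float(p_start)])
    tv = np.array([t])
    av = np.array([a])
    for k in range(n):
        s0 = k * step
        p = stepper(hazards, tv + s0, av + s0, p, step)
    if not np.isfinite(p[0]):
        raise SolverError("non-finite prevalence in fixed-span integration")
    return float(p[0])


def reference_solution(
    p_start: float,
    start: tuple,
    span: float,
    step: float,
    i_fn: Callable,
    diff_fn: Callable,
    form: str = "m0_m1",
) -> float:
    """High-resolution fixed-step RK4 reference for one characteristic.

    Rate functions are evaluated once on the half-step grid (vectorised)
    and the integration runs on plain floats, which makes very small steps
    (1e-3 .. 1e-4) affordable.  ``form`` selects the excess
    parameterisation: ``'m0_m1'`` takes ``diff_fn`` = m1 - m0 and uses
    excess = p*(1-p)*diff; ``'m1_m'`` takes ``diff_fn`` = m1 - m and uses
    excess = p*diff.
    """
    if form not in ("m0_m1", "m1_m"):
        raise ValueError(f"unknown form {form!r}")
    n = round(span / step)
    if n < 1 or abs(n * step - span) > 1e-9 * max(1.0, span):
        raise ValueError("step must divide the span evenly")
    t0, a0 = float(start[0]), float(start[1])
    s = np.arange(2 * n + 1) * (step / 2.0)
    iv = np.broadcast_to(np.asarray(i_fn(t0 + s, a0 + s), float), s.shape).tolist()
    dv = np.broadcast_to(np.asarray(diff_fn(t0 + s, a0 + s), float), s.shape).tolist()
    bilinear = form == "m0_m1"
    p = float(p_start)
    h = step
    for k in range(n):
        j = 2 * k
        i0, i1, i2 = iv[j], iv[j + 1], iv[j + 2]
        d0, d1, d2 = dv[j], dv[j + 1], dv[j + 2]
        if bilinear:
            k1 = (1.0 - p) * i0 - p * (1.0 - p) * d0
            q = p + 0.5 * h * k1
            k2 = (1.0 - q) * i1 - q * (1.0 - q) * d1
            q = p + 0.5 * h * k2
            k3 = (1.0 - q) * i1 - q * (1.0 - q) * d1
            q = p + h * k3
            k4 = (1.0 - q) * i2 - q * (1.0 - q) * d2
        else:
            k1 = (1.0 - p) * i0 - p * d0
            q = p + 0.5 * h * k1
            k2 = (1.0 - q) * i1 - q * d1
            q = p + 0.5 * h * k2
            k3 = (1.0 - q) * i1 - q * d1
            q = p + h * k3
            k4 = (1.0 - q) * i2 - q * d2
        p += (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    return p
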