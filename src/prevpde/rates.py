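"""Continuous rate surfaces from aggregated age-group tables.

The estimation PDE needs the incidence rate i(t, a), the general-population
mortality m(t, a) and the mortality of the diseased m1(t, a) as continuous
functions of calendar time and age.  Registries publish them on 5-year age
groups, so each closed group [L, H] is anchored at its continuous-age
midpoint (L + H + 1) / 2 and values are interpolated bilinearly in (year,
age); outside the grid hull the nearest value is used (constant
extrapolation), which in particular freezes rates above the oldest midpoint
— the open 85+ group contributes no node of its own.

Two routes to the diseased mortality m1 are supported:

* mode A (direct): a table of diseased all-cause mortality is interpolated
  as-is;
* mode B (cause-specific): cause-of-death statistics give the population
  cause-specific rate mu_c; assuming all cause-specific deaths occur among
  the diseased and the diseased die of other causes at the same rate as the
  non-diseased (m0 = m - mu_c), the mixing relation
  m = p*m1 + (1-p)*m0 pins down m1 = mu_c/p + m - mu_c.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .tables import OPEN_AGE_HIGH, AgeGroupTable, ValidationError

#: quantities a surface may hold
QUANTITIES = (
    "incidence",
    "general_mortality",
    "diseased_mortality",
    "cause_specific_mortality",
    "initial_prevalence",
    "rate",
    "proportion",
)


def _linear_weights(grid: np.ndarray, x: np.ndarray):
    """Interval indices and weights for 1-d linear interpolation with
    constant (nearest-node) extrapolation outside the grid."""
    x = np.clip(x, grid[0], grid[-1])
    if grid.size == 1:
        idx = np.zeros(np.shape(x), dtype=np.intp)
        return idx, np.zeros(np.shape(x))
    idx = np.clip(np.searchsorted(grid, x, side="right") - 1, 0, grid.size - 2)
    w = (x - grid[idx]) / (grid[idx + 1] - grid[idx])
    return idx, w


@dataclass(frozen=True)
class RateSurface:
    """A rate (or proportion) as a continuous function of (year, age).

    Evaluation is bilinear inside the grid hull and constant outside; a
    grid node evaluates to its stored value exactly.  Calling the surface
    with arrays broadcasts.
    """

    quantity: str
    sex: str
    years: np.ndarray
    ages: np.ndarray
    values: np.ndarray  # shape (len(years), len(ages))

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=float)
        ages = np.asarray(self.ages, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if self.quantity not in QUANTITIES:
            raise ValueError(f"unknown quantity {self.quantity!r}")
        if values.shape != (years.size, ages.size):
            raise ValueError(
                f"values shape {values.shape} != (n_years, n_ages) = "
                f"({years.size}, {ages.size})"
            )
        if years.size == 0 or ages.size == 0:
            raise ValueError("empty grid")
        if np.any(np.diff(years) <= 0) or np.any(np.diff(ages) <= 0):
            raise ValueError("grid axes must be strictly increasing")
        if np.any(values < 0):
            raise ValidationError(f"{self.quantity} surface has negative values")
        if self.quantity in ("initial_prevalence", "proportion") and np.any(values >= 1):
            raise ValidationError("prevalence surface has values >= 1")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "values", values)

    def __call__(self, t, a):
        t = np.asarray(t, dtype=float)
        a = np.asarray(a, dtype=float)
        scalar = t.ndim == 0 and a.ndim == 0
        t, a = np.broadcast_arrays(t, a)
        it, wt = _linear_weights(self.years, t)
        ia, wa = _linear_weights(self.ages, a)
        it2 = np.minimum(it + 1, self.years.size - 1)
        ia2 = np.minimum(ia + 1, self.ages.size - 1)
        v = self.values
        row0 = v[it, ia] * (1.0 - wa) + v[it, ia2] * wa
        row1 = v[it2, ia] * (1.0 - wa) + v[it2, ia2] * wa
        out = row0 * (1.0 - wt) + row1 * wt
        return float(out) if scalar else out


def _stratum_nodes(table: AgeGroupTable, year: int, sex: str):
    closed = table.closed_groups(year, sex)
    if len(closed) < 2:
        raise ValidationError(
            f"stratum ({year}, {sex}): need at least two closed age groups, "
            f"got {len(closed)}"
        )
    mids = (closed["age_low"].to_numpy() + closed["age_high"].to_numpy() + 1) / 2.0
    return mids, closed["value"].to_numpy(dtype=float)


def interpolate_groups(
    table: AgeGroupTable,
    anchor_zero_at_birth: bool = False,
    sex: str | None = None,
    quantity: str | None = None,
) -> RateSurface:
    """Build a :class:`RateSurface` from an age-group table.

    Each closed group [L, H] contributes a node at age (L + H + 1)/2 with
    the group value; the open top group contributes no node, so ages above
    the oldest midpoint use constant extrapolation.  With
    ``anchor_zero_at_birth`` an extra node (age 0, value 0) is added per
    year, which encodes the healthy-at-birth assumption for tables that do
    not cover the youngest ages (e.g. claims prevalence from age 15).
    """
    if sex is None:
        if len(table.sexes) != 1:
            raise ValueError("table holds several sexes; pass sex=...")
        sex = table.sexes[0]
    sub = table.for_sex(sex)
    years = sub.years
    ref_mids = None
    rows = []
    for year in years:
        mids, vals = _stratum_nodes(sub, int(year), sex)
        if ref_mids is None:
            ref_mids = mids
        elif mids.shape != ref_mids.shape or not np.array_equal(mids, ref_mids):
            raise ValidationError(
                f"stratum ({year}, {sex}): age-group scheme differs across years"
            )
        rows.append(vals)
    ages = np.asarray(ref_mids, dtype=float)
    values = np.asarray(rows, dtype=float)
    if anchor_zero_at_birth:
        if ages[0] <= 0:
            raise ValidationError("cannot anchor at birth: first midpoint is at age 0")
        ages = np.concatenate(([0.0], ages))
        values = np.concatenate((np.zeros((len(years), 1)), values), axis=1)
    if quantity is None:
        quantity = "proportion" if table.kind == "proportion" else "rate"
    return RateSurface(
        quantity=quantity, sex=sex, years=np.asarray(years, float), ages=ages, values=values
    )


def derive_m1_direct(
    m1_table: AgeGroupTable, sex: str | None = None, anchor_zero_at_birth: bool = False
) -> RateSurface:
    """Mode A: interpolate a table of diseased all-cause mortality as m1."""
    return interpolate_groups(
        m1_table, anchor_zero_at_birth=anchor_zero_at_birth, sex=sex,
        quantity="diseased_mortality",
    )


def derive_m1_from_cause_specific(mu_c, m, p, t=None, a=None, warn: bool = True):
    """Mode B: m1 from cause-specific mortality via the mixing relation.

    Under the assumptions that (i) all cause-specific deaths occur among
    the diseased and (ii) the diseased die of other causes at the
    non-diseased rate m0 = m - mu_c, the unique m1 satisfying
    p*m1 + (1-p)*m0 = m is::

        m1 = mu_c / p + m - mu_c

    ``mu_c`` and ``m`` may be numbers, arrays, or callables of (t, a) — in
    the latter case ``t`` and ``a`` must be given.  ``p`` must lie strictly
    inside (0, 1).  ``mu_c > m`` is a data inconsistency: a warning is
    emitted but the value is still computed.
    """
    if callable(mu_c):
        mu_c = mu_c(t, a)
    if callable(m):
        m = m(t, a)
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr <= 0) or np.any(p_arr >= 1):
        raise ValueError("p must lie strictly in (0, 1)")
    mu_arr = np.asarray(mu_c, dtype=float)
    m_arr = np.asarray(m, dtype=float)
    if warn and np.any(mu_arr > m_arr):
        warnings.warn(
            "cause-specific mortality exceeds general mortality somewhere; "
            "inconsistent input data",
            RuntimeWarning,
            stacklevel=2,
        )
    out = mu_arr / p_arr + m_arr - mu_arr
    return float(out) if out.ndim == 0 else out


def excess_term(p, m1, m):
    """The excess-mortality drag p * (m1 - m) of the prevalence PDE.

    May be negative when m1 < m (noisy inputs); it is returned as-is —
    clamping here would silently bias prevalence upward.
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any(p_arr < 0) or np.any(p_arr >= 1):
        raise ValueError("p must lie in [0, 1)")
    out = p_arr * (np.asarray(m1, float) - np.asarray(m, float))
    return float(out) if out.ndim == 0 else out
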