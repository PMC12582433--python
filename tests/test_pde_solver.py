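"""Characteristic integration of the illness-death prevalence PDE."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import prevpde as pp
from prevpde.solver import SolverSettings


def const(v):
    return lambda t, a: np.broadcast_arrays(np.asarray(v, float), t)[0]


class TestRhsAndClosedForm:
    def test_rhs_examples(self):
        assert pp.pde_rhs(0.0, 0.02, 0.5, 0.1) == pytest.approx(0.02)
        assert pp.pde_rhs(0.5, 0.0, 0.04, 0.04) == 0.0
        assert pp.pde_rhs(0.2, 0.01, 0.05, 0.03) == pytest.approx(0.004)

    @pytest.mark.parametrize("p", [-0.01, 1.0, 1.2])
    def test_rhs_domain_error(self, p):
        with pytest.raises(ValueError):
            pp.pde_rhs(p, 0.01, 0.02, 0.02)

    def test_closed_form_values(self):
        assert pp.closed_form_constant_rates(0.0, 40.0) == 0.0
        assert pp.closed_form_constant_rates(0.01, 50.0) == pytest.approx(
            0.393469, abs=1e-6
        )
        assert pp.closed_form_constant_rates(0.1, 10.0) == pytest.approx(
            0.632121, abs=1e-6
        )


class TestSolveCharacteristic:
    def test_constant_incidence_matches_exponential(self):
        hz = pp.hazards_from_m0_m1(const(0.01), const(0.02), const(0.02))
        traj = pp.solve_characteristic(0.0, (2010, 0), 50, hz)
        expected = pp.closed_form_constant_rates(0.01, traj.ages.astype(float))
        assert np.max(np.abs(traj.p - expected)) < 1e-6
        assert traj.ages[-1] == 50 and traj.years[-1] == 2060

    def test_no_incidence_no_excess_conserves_prevalence(self):
        hz = pp.hazards_from_m1(const(0.0), const(0.05), const(0.05))
        traj = pp.solve_characteristic(0.3, (2010, 20), 60, hz)
        np.testing.assert_allclose(traj.p, 0.3, rtol=1e-14)

    def test_pure_excess_decay_matches_high_resolution_reference(self):
        # i = 0, m1 - m = 0.02 constant: p decays; oracle = RK4 at step 1e-4
        hz = pp.hazards_from_m1(const(0.0), const(0.07), const(0.05))
        traj = pp.solve_characteristic(0.3, (2010, 40), 50, hz)
        ref = pp.reference_solution(
            0.3, (2010, 40), 10.0, 1e-4, const(0.0), const(0.02), form="m1_m"
        )
        assert traj.p[-1] == pytest.approx(ref, abs=1e-9)

    def test_non_integer_start_age_rejected(self):
        hz = pp.hazards_from_m1(const(0.0), const(0.0), const(0.0))
        with pytest.raises(ValueError, match="integer"):
            pp.solve_characteristic(0.0, (2010, 0.5), 10, hz)

    def test_clamping_counted_on_overshoot(self):
        # Euler with a huge rate overshoots past 1 in one step
        hz = pp.hazards_from_m1(const(50.0), const(0.0), const(0.0))
        traj = pp.solve_characteristic(
            0.0, (2010, 0), 1, hz, SolverSettings(step_size=0.5, scheme="euler")
        )
        assert traj.clamp_events >= 1
        assert np.all(traj.p < 1.0)


class TestSolveSurface:
    def test_null_inputs_give_null_surface(self):
        hz = pp.hazards_from_m1(const(0.0), const(0.0), const(0.0))
        surf = pp.solve_surface(np.zeros(86), hz, (2010, 2019))
        assert np.all(surf.values == 0.0)
        assert surf.metadata["clamp_events"] == 0

    def test_post_t0_cohorts_follow_closed_form(self):
        hz = pp.hazards_from_m0_m1(const(0.02), const(0.01), const(0.01))
        surf = pp.solve_surface(np.zeros(86), hz, (2010, 2019))
        # cohort born 2012: at year 2010+k its age is k-2 (k >= 2)
        for year in range(2013, 2020):
            age = year - 2012
            expected = pp.closed_form_constant_rates(0.02, age)
            assert surf.value_at(year, age) == pytest.approx(expected, abs=1e-7)

    def test_birth_boundary_is_zero_after_t0(self):
        hz = pp.hazards_from_m0_m1(const(0.05), const(0.01), const(0.02))
        surf = pp.solve_surface(np.full(86, 0.1), hz, (2010, 2019))
        assert np.all(surf.values[1:, 0] == 0.0)

    def test_initial_year_equals_supplied_profile(self):
        p0 = np.linspace(0.0, 0.4, 86)
        hz = pp.hazards_from_m0_m1(const(0.05), const(0.01), const(0.02))
        surf = pp.solve_surface(p0, hz, (2010, 2019))
        np.testing.assert_array_equal(surf.values[0], p0)

    def test_cells_agree_with_individually_solved_characteristics(self):
        """Characteristics are independent: the surface solve must equal
        solving each characteristic on its own."""
        hz1 = pp.hazards_from_m0_m1(const(0.03), const(0.01), const(0.03))
        p0 = np.linspace(0.0, 0.3, 86)
        surf = pp.solve_surface(p0, hz1, (2010, 2019))
        # initial-profile characteristic through (2010, 40)
        hz2 = pp.hazards_from_m0_m1(const(0.03), const(0.01), const(0.03))
        traj = pp.solve_characteristic(p0[40], (2010, 40), 49, hz2)
        for year, age, val in zip(traj.years, traj.ages, traj.p):
            assert surf.value_at(year, age) == val
        # birth characteristic of the 2015 cohort
        traj_b = pp.solve_characteristic(0.0, (2015, 0), 4, hz2)
        for year, age, val in zip(traj_b.years, traj_b.ages, traj_b.p):
            assert surf.value_at(year, age) == val

    def test_mode_b_forms_agree_on_rhs_to_machine_precision(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0.0, 0.99, 500)
        mu = rng.uniform(0.0, 0.05, 500)
        m = mu + rng.uniform(0.0, 0.05, 500)
        via = pp.hazards_from_cause_specific(const(0.0), lambda t, a: mu, lambda t, a: m)
        red = pp.hazards_from_cause_specific(
            const(0.0), lambda t, a: mu, lambda t, a: m, form="reduced"
        )
        e1 = via.excess(0.0, 0.0, p)
        e2 = red.excess(0.0, 0.0, p)
        np.testing.assert_allclose(e1, e2, rtol=1e-13, atol=1e-18)
        np.testing.assert_allclose(e1, mu * (1 - p), rtol=1e-13, atol=1e-18)

    def test_monotone_in_age_without_excess(self, default_scenario):
        """With m1 = m0 and positive incidence, prevalence strictly
        increases in age along every characteristic."""
        sc = default_scenario
        hz = pp.hazards_from_m0_m1(
            sc.incidence("female"),
            sc.mortality_healthy("female"),
            sc.mortality_healthy("female"),
        )
        traj = pp.solve_characteristic(0.0, (sc.t0, 0), 85, hz)
        assert np.all(np.diff(traj.p) > 0)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(
        i=st.floats(min_value=0.0, max_value=0.5),
        m0=st.floats(min_value=0.0, max_value=0.5),
        excess=st.floats(min_value=0.0, max_value=0.5),
        p_start=st.floats(min_value=0.0, max_value=0.9),
    )
    def test_bounded_for_nonneg_rates_with_stable_step(self, i, m0, excess, p_start):
        """0 <= p < 1 without clamping when step <= 0.25 / max rate."""
        max_rate = max(i, m0 + excess, 1e-9)
        n = max(4, int(np.ceil(4 * max_rate)))
        settings = SolverSettings(step_size=1.0 / n, scheme="rk4")
        hz = pp.hazards_from_m0_m1(const(i), const(m0), const(m0 + excess))
        traj = pp.solve_characteristic(p_start, (2010, 0), 40, hz, settings)
        assert traj.clamp_events == 0
        assert np.all((traj.p >= 0.0) & (traj.p < 1.0))


class TestSolverSettings:
    @pytest.mark.parametrize("step", [0.3, 0.4, 0.7])
    def test_step_must_divide_one_year(self, step):
        with pytest.raises(ValueError, match="divide"):
            SolverSettings(step_size=step)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError, match="scheme"):
            SolverSettings(scheme="heun")
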