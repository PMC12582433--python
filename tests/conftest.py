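import numpy as np
import pytest

import prevpde as pp


@pytest.fixture(scope="session")
def default_scenario():
    return pp.get_scenario("default")


@pytest.fixture(scope="session")
def default_truth(default_scenario):
    """Reference-integrated truth of the default scenario (step 1e-3)."""
    return pp.build_truth(default_scenario, step=1e-3)


@pytest.fixture(scope="session")
def default_tables(default_truth):
    """Registry-style aggregated tables implied by the default truth."""
    return pp.aggregate_to_groups(default_truth)


@pytest.fixture(scope="session")
def analytic_surfaces(default_scenario, default_truth):
    """PDE solution per sex using the scenario's analytic rates and the
    exact truth profile at t0 (isolates solver error from interpolation)."""
    sc = default_scenario
    out = {}
    for sex in sc.sexes:
        hz = pp.hazards_from_m0_m1(
            sc.incidence(sex), sc.mortality_healthy(sex), sc.mortality_ill(sex)
        )
        out[sex] = pp.solve_surface(
            default_truth.p0_profile(sex), hz, (sc.t0, sc.t1), (0, sc.max_age), sex=sex
        )
    return out


@pytest.fixture(scope="session")
def microsim_grid(default_scenario):
    """Full-scale stochastic oracle run (200k individuals per sex)."""
    import time

    t = time.perf_counter()
    grid = pp.simulate_grid(default_scenario, n_per_sex=200_000, seed=101, dt=0.05)
    grid.elapsed_s = time.perf_counter() - t
    return grid


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory, default_truth):
    """A complete synthetic input bundle written to disk."""
    out = tmp_path_factory.mktemp("bundle")
    pp.write_bundle(default_truth, out, base_cohort=100_000.0, boom_year=1964)
    return out


@pytest.fixture
def tiny_rate_table():
    """Two strata, two years, minimal valid rate table."""
    import pandas as pd

    rows = []
    for year in (2010, 2011):
        for sex in ("female", "male"):
            rows += [
                {"year": year, "sex": sex, "age_low": 50, "age_high": 54, "value": 0.010},
                {"year": year, "sex": sex, "age_low": 55, "age_high": 59, "value": 0.020},
                {"year": year, "sex": sex, "age_low": 60, "age_high": -1, "value": 0.030},
            ]
    return pp.AgeGroupTable(pd.DataFrame(rows), kind="rate")
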