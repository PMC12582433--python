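"""Schema validation and round-trip fidelity of the table I/O layer."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import prevpde as pp
from prevpde.tables import SchemaError, ValidationError


def _table(rows, kind="rate"):
    return pp.AgeGroupTable(pd.DataFrame(rows), kind=kind)


def _row(year=2010, sex="female", lo=50, hi=54, value=0.004):
    return {"year": year, "sex": sex, "age_low": lo, "age_high": hi, "value": value}


class TestAgeGroupValidation:
    def test_valid_single_row_accepted(self):
        t = _table([_row()])
        assert len(t.data) == 1
        assert t.sexes == ("female",)

    @pytest.mark.parametrize(
        "rows, match",
        [
            ([_row(value=-0.1)], "negative value"),
            ([_row(), _row(lo=52, hi=56)], "overlap"),
            ([_row(), _row(lo=57, hi=59)], "non-contiguous"),
            ([_row(lo=54, hi=50)], "age_low > age_high"),
            ([_row(sex="other")], "sex"),
            ([_row(hi=-1), _row(lo=55, hi=-1)], "multiple open"),
            ([_row(), _row(lo=53, hi=-1)], "open group overlaps"),
            ([_row(), _row(lo=60, hi=-1)], "open group not contiguous"),
            ([], "no rows"),
        ],
    )
    def test_invalid_tables_rejected(self, rows, match):
        df = pd.DataFrame(rows, columns=list(pp.tables.AGE_GROUP_COLUMNS))
        with pytest.raises(ValidationError, match=match):
            pp.AgeGroupTable(df, kind="rate")

    def test_proportion_kind_rejects_values_at_or_above_one(self):
        with pytest.raises(ValidationError, match="proportion >= 1"):
            _table([_row(value=1.0)], kind="proportion")
        # the same value is fine as a rate
        assert _table([_row(value=1.0)], kind="rate").data["value"].iloc[0] == 1.0

    def test_rows_in_different_strata_do_not_interact(self):
        # same age span in different years/sexes is not an overlap
        t = _table([_row(), _row(year=2011), _row(sex="male")])
        assert len(t.data) == 3


class TestReaders:
    def test_read_age_group_table_roundtrip(self, tmp_path, tiny_rate_table):
        path = tmp_path / "rates.csv"
        pp.write_age_group_table(tiny_rate_table, path)
        back = pp.read_age_group_table(path, kind="rate")
        pd.testing.assert_frame_equal(back.data, tiny_rate_table.data)

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("year,sex,age_low,value\n2010,female,50,0.1\n")
        with pytest.raises(SchemaError, match="age_high"):
            pp.read_age_group_table(path, kind="rate")

    def test_population_full_age_range(self, tmp_path):
        rows = [
            {"year": 2019, "sex": sex, "age": a, "count": 1000.0}
            for sex in ("female", "male")
            for a in range(86)
        ]
        path = tmp_path / "pop.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        pop = pp.read_population(path)
        assert len(pop.data) == 2 * 86

    def test_population_duplicate_key_rejected(self):
        rows = [
            {"year": 2019, "sex": "male", "age": 40, "count": 10.0},
            {"year": 2019, "sex": "male", "age": 40, "count": 11.0},
        ]
        with pytest.raises(ValidationError, match="duplicate"):
            pp.PopulationTable(pd.DataFrame(rows))

    def test_population_negative_count_rejected(self):
        with pytest.raises(ValidationError, match="negative count"):
            pp.PopulationTable(
                pd.DataFrame([{"year": 2019, "sex": "male", "age": 0, "count": -1.0}])
            )

    def test_empty_population_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("year,sex,age,count\n")
        with pytest.raises(ValidationError, match="no rows"):
            pp.read_population(path)


class TestSurfaceWriter:
    def test_two_row_surface_yields_three_line_file(self, tmp_path):
        df = pd.DataFrame(
            {"year": [2010, 2010], "sex": ["female", "female"], "age": [0, 1],
             "value": [0.0, 0.125]}
        )
        path = tmp_path / "surface.csv"
        pp.write_surface(df, path)
        assert len(path.read_text().strip().splitlines()) == 3

    def test_output_sorted_by_sex_year_age(self, tmp_path):
        df = pd.DataFrame(
            {"year": [2011, 2010, 2010], "sex": ["male", "male", "female"],
             "age": [5, 3, 7], "value": [0.3, 0.2, 0.1]}
        )
        path = tmp_path / "surface.csv"
        pp.write_surface(df, path)
        back = pd.read_csv(path)
        assert list(back["sex"]) == ["female", "male", "male"]
        assert list(back["year"]) == [2010, 2010, 2011]

    def test_roundtrip_preserves_values_bit_exactly(self, tmp_path):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {"year": 2010, "sex": "female", "age": np.arange(20),
             "value": rng.random(20)}
        )
        path = tmp_path / "surface.csv"
        pp.write_surface(df, path)
        back = pp.read_surface(path)
        assert np.array_equal(back["value"].to_numpy(), df["value"].to_numpy())


# -- property: read(write(x)) == x over random valid tables ------------------

@st.composite
def age_group_tables(draw):
    n_groups = draw(st.integers(min_value=2, max_value=6))
    width = draw(st.integers(min_value=1, max_value=10))
    start = draw(st.integers(min_value=0, max_value=30))
    has_open = draw(st.booleans())
    years = sorted(draw(st.sets(st.integers(2000, 2020), min_size=1, max_size=3)))
    sexes = draw(st.sampled_from([("female",), ("male",), ("female", "male")]))
    values = st.floats(min_value=0.0, max_value=10.0, allow_nan=False)
    rows = []
    for year in years:
        for sex in sexes:
            lo = start
            for _ in range(n_groups):
                rows.append(
                    {"year": year, "sex": sex, "age_low": lo,
                     "age_high": lo + width - 1, "value": draw(values)}
                )
                lo += width
            if has_open:
                rows.append(
                    {"year": year, "sex": sex, "age_low": lo, "age_high": -1,
                     "value": draw(values)}
                )
    return pp.AgeGroupTable(pd.DataFrame(rows), kind="rate")


@settings(max_examples=25, derandomize=True, deadline=None)
@given(table=age_group_tables())
def test_age_group_roundtrip_identity(table, tmp_path_factory):
    path = tmp_path_factory.mktemp("prop") / "t.csv"
    pp.write_age_group_table(table, path)
    back = pp.read_age_group_table(path, kind="rate")
    pd.testing.assert_frame_equal(back.data, table.data)


@settings(max_examples=25, derandomize=True, deadline=None)
@given(
    counts=st.lists(st.floats(min_value=0, max_value=1e8, allow_nan=False),
                    min_size=1, max_size=30)
)
def test_population_roundtrip_identity(counts, tmp_path_factory):
    df = pd.DataFrame(
        {"year": 2010, "sex": "female", "age": np.arange(len(counts)),
         "count": counts}
    )
    pop = pp.PopulationTable(df)
    path = tmp_path_factory.mktemp("prop") / "p.csv"
    pp.write_population(pop, path)
    back = pp.read_population(path)
    pd.testing.assert_frame_equal(back.data, pop.data)
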