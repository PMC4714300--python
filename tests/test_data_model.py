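"""Containers, CSV round-trips, weekly-to-monthly conversion, normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kdepi.data_model import (
    AdjacencyMatrix,
    AgeBinnedCounts,
    AgeGroupScheme,
    CaseSeries,
    ValidationError,
    WeeklySeries,
    normalize_to_max,
    read_adjacency,
    read_counts,
    weekly_to_monthly,
    write_adjacency,
    write_counts,
)


class TestAgeGroupScheme:
    def test_default_has_11_bins_with_midpoints(self, scheme):
        assert scheme.k == 11
        assert scheme.midpoints[0] == 0.25
        assert scheme.midpoints[-1] == (9 + 15) / 2

    def test_rejects_overlapping_bins(self):
        with pytest.raises(ValidationError):
            AgeGroupScheme(labels=("a", "b"), lower=(0, 0.4), upper=(0.5, 1.0))

    def test_rejects_single_bin(self):
        with pytest.raises(ValidationError):
            AgeGroupScheme(labels=("a",), lower=(0,), upper=(15,))

    def test_bin_ages_maps_to_half_open_intervals(self, scheme):
        idx = scheme.bin_ages([0.0, 0.49, 0.5, 8.99, 9.0, 14.99, 15.0, -1.0])
        assert list(idx) == [0, 0, 1, 9, 10, 10, -1, -1]


class TestCounts:
    def test_read_well_formed(self, tmp_path, scheme):
        p = tmp_path / "c.csv"
        p.write_text(
            "disease,region,year,age_group,count\n"
            "kd,r00,2000,0-<0.5,3\nkd,r00,2000,0.5-<1,4\nkd,r00,2001,1-<2,5\n"
        )
        c = read_counts(p, scheme)
        assert len(c) == 3
        assert c.table["count"].sum() == 12

    def test_negative_count_names_row(self, tmp_path, scheme):
        p = tmp_path / "c.csv"
        p.write_text(
            "disease,region,year,age_group,count\n"
            "kd,r00,2000,0-<0.5,3\nkd,r00,2000,0.5-<1,-1\n"
        )
        with pytest.raises(ValidationError, match="row.*3"):
            read_counts(p, scheme)

    def test_unknown_age_group_rejected(self, scheme):
        df = pd.DataFrame(
            [("kd", "r00", 2000, "99-<100", 1)],
            columns=["disease", "region", "year", "age_group", "count"],
        )
        with pytest.raises(ValidationError, match="unknown age group"):
            AgeBinnedCounts(table=df, scheme=scheme)

    def test_non_contiguous_years_rejected(self, scheme):
        df = pd.DataFrame(
            [("kd", "r00", 2000, "0-<0.5", 1), ("kd", "r00", 2002, "0-<0.5", 1)],
            columns=["disease", "region", "year", "age_group", "count"],
        )
        with pytest.raises(ValidationError, match="contiguous"):
            AgeBinnedCounts(table=df, scheme=scheme)

    def test_write_read_round_trip(self, tmp_path, small_counts, scheme):
        p = tmp_path / "c.csv"
        write_counts(small_counts, p)
        back = read_counts(p, scheme)
        pd.testing.assert_frame_equal(
            back.table[small_counts.table.columns], small_counts.table
        )


class TestWeeklyToMonthly:
    def _weekly(self, starts, counts):
        return WeeklySeries(
            disease="d",
            table=pd.DataFrame({"week_start": pd.to_datetime(starts), "count": counts}),
        )

    def test_week_inside_one_month(self):
        m = weekly_to_monthly(self._weekly(["2005-03-07"], [7]))
        assert m.values[pd.Period("2005-03", "M")] == 7

    def test_week_split_3_4_across_months(self):
        # week starting 29 March: 3 days in March, 4 in April
        m = weekly_to_monthly(self._weekly(["2005-03-29"], [7]))
        assert m.values[pd.Period("2005-03", "M")] == pytest.approx(3.0)
        assert m.values[pd.Period("2005-04", "M")] == pytest.approx(4.0)

    def test_total_conserved_over_a_year(self):
        starts = pd.date_range("2004-01-05", periods=52, freq="7D")
        m = weekly_to_monthly(self._weekly(starts, [1] * 52))
        assert m.values.sum() == pytest.approx(52.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        counts=st.lists(st.integers(0, 500), min_size=1, max_size=60),
        offset=st.integers(0, 6),
    )
    def test_conservation_property(self, counts, offset):
        starts = pd.date_range("2003-01-01", periods=len(counts), freq="7D")
        starts = starts + pd.Timedelta(days=offset)
        m = weekly_to_monthly(self._weekly(starts, counts))
        assert m.values.sum() == pytest.approx(sum(counts))

    def test_duplicate_weeks_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            self._weekly(["2005-03-07", "2005-03-07"], [1, 1])

    def test_overlapping_weeks_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            self._weekly(["2005-03-07", "2005-03-10"], [1, 1])


class TestNormalizeToMax:
    def _series(self, vals):
        idx = pd.period_range("2000-01", periods=len(vals), freq="M")
        return CaseSeries(disease="d", values=pd.Series(vals, index=idx, dtype=float))

    def test_example(self):
        out = normalize_to_max(self._series([2, 4, 8]))
        assert list(out.values) == [0.25, 0.5, 1.0]
        assert out.kind == "proportion-of-maximum"

    def test_constant_series(self):
        out = normalize_to_max(self._series([5, 5]))
        assert list(out.values) == [1.0, 1.0]

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError, match="positive"):
            normalize_to_max(self._series([0, 0, 0]))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(0, 1e6), min_size=2, max_size=50).filter(lambda v: max(v) > 0))
    def test_max_is_one_and_idempotent(self, vals):
        out = normalize_to_max(self._series(vals))
        assert np.max(out.values) == 1.0
        again = normalize_to_max(out)
        assert np.allclose(out.values, again.values)


class TestAdjacency:
    def test_validation(self):
        with pytest.raises(ValidationError, match="symmetric"):
            AdjacencyMatrix(matrix=np.array([[0, 1], [0, 0]]), regions=("a", "b"))
        with pytest.raises(ValidationError, match="diagonal"):
            AdjacencyMatrix(matrix=np.eye(2), regions=("a", "b"))

    def test_edge_list_round_trip(self, tmp_path):
        u = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        adj = AdjacencyMatrix(matrix=u, regions=("a", "b", "c"))
        p = tmp_path / "adj.csv"
        write_adjacency(adj, p)
        back = read_adjacency(p, regions=("a", "b", "c"))
        assert np.array_equal(back.matrix, u)

    def test_row_standardized_rows_sum_to_one(self):
        u = np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]], dtype=float)
        w = AdjacencyMatrix(matrix=u, regions=("a", "b", "c")).row_standardized()
        assert np.allclose(w.sum(axis=1), 1.0)
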