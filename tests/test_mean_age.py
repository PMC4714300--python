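"""Crude/adjusted/national mean patient age against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from kdepi.data_model import AgeBinnedCounts, Demography, ValidationError
from kdepi.mean_age import (
    UndefinedMeanAgeError,
    adjusted_mean_age,
    crude_mean_age,
    mean_age_table,
    national_mean_age,
)


def _counts(scheme, rows):
    return AgeBinnedCounts(
        table=pd.DataFrame(
            rows, columns=["disease", "region", "year", "age_group", "count"]
        ),
        scheme=scheme,
    )


def _loop_crude(df, mids):
    """Explicit loop oracle for the crude mean."""
    num = den = 0.0
    for _, row in df.iterrows():
        num += mids[row["age_group"]] * row["count"]
        den += row["count"]
    return num / den


class TestCrude:
    def test_all_cases_in_one_group(self, scheme):
        c = _counts(scheme, [("kd", "r00", 2000, "2-<3", 17)])
        assert crude_mean_age(c, scheme, "kd", "r00") == 2.5

    def test_symmetric_two_groups(self, scheme):
        c = _counts(
            scheme, [("kd", "r00", 2000, "0-<0.5", 10), ("kd", "r00", 2000, "4-<5", 10)]
        )
        assert crude_mean_age(c, scheme, "kd", "r00") == pytest.approx(
            (0.25 + 4.5) / 2
        )

    def test_matches_loop_oracle_on_random_table(self, scheme, small_counts):
        mids = dict(zip(scheme.labels, scheme.midpoints))
        df = small_counts.subset(disease="kd", region="r01")
        expect = _loop_crude(df, mids)
        got = crude_mean_age(small_counts, scheme, "kd", "r01")
        assert got == pytest.approx(expect, abs=1e-12)

    def test_zero_cases_is_an_error(self, scheme):
        c = _counts(scheme, [("kd", "r00", 2000, "2-<3", 0)])
        with pytest.raises(UndefinedMeanAgeError):
            crude_mean_age(c, scheme, "kd", "r00")

    def test_bounds(self, scheme, small_counts):
        v = crude_mean_age(small_counts, scheme, "hfmd", "r00")
        assert min(scheme.midpoints) <= v <= max(scheme.midpoints)


class TestAdjusted:
    def test_identity_when_structure_equals_standard(
        self, scheme, small_counts, uniform_demography
    ):
        crude = crude_mean_age(small_counts, scheme, "kd", "r00")
        adj = adjusted_mean_age(small_counts, uniform_demography, scheme, "kd", "r00")
        assert adj == pytest.approx(crude, abs=1e-12)

    def test_single_group_gives_its_midpoint(self, scheme, skewed_demography):
        c = _counts(scheme, [("kd", "r00", 2000, "3-<4", 9)])
        adj = adjusted_mean_age(c, skewed_demography, scheme, "kd", "r00")
        assert adj == pytest.approx(3.5, abs=1e-12)

    def test_two_group_hand_computed_standardization(self, scheme, skewed_demography):
        c = _counts(
            scheme,
            [("kd", "r00", 2000, "1-<2", 20), ("kd", "r00", 2000, "5-<6", 10)],
        )
        cc = skewed_demography.proportions("r00", 2000)
        s = skewed_demography.standard
        w1 = s["1-<2"] * 20 / cc["1-<2"]
        w2 = s["5-<6"] * 10 / cc["5-<6"]
        expect = (1.5 * w1 + 5.5 * w2) / (w1 + w2)
        got = adjusted_mean_age(c, skewed_demography, scheme, "kd", "r00")
        assert got == pytest.approx(expect, abs=1e-12)

    def test_zero_population_share_with_cases_errors(self, scheme, skewed_demography):
        c = _counts(scheme, [("kd", "r00", 1999, "1-<2", 5)])
        with pytest.raises(ValidationError, match="r00"):
            adjusted_mean_age(c, skewed_demography, scheme, "kd", "r00")


class TestNational:
    def test_single_region_equals_regional_value(
        self, scheme, small_counts, skewed_demography
    ):
        only = AgeBinnedCounts(
            table=small_counts.subset(disease="kd", region="r00").assign(),
            scheme=scheme,
        )
        nat = national_mean_age(only, skewed_demography, scheme, "kd", "crude")
        reg = crude_mean_age(only, scheme, "kd", "r00")
        assert nat == pytest.approx(reg, abs=1e-12)

    def test_two_identical_regions_equal_either(self, scheme, uniform_demography):
        rows = []
        for r in ("r00", "r01"):
            rows += [("kd", r, 2000, "1-<2", 10), ("kd", r, 2000, "6-<7", 5)]
        c = _counts(scheme, rows)
        nat = national_mean_age(c, uniform_demography, scheme, "kd", "crude")
        assert nat == pytest.approx(crude_mean_age(c, scheme, "kd", "r00"), abs=1e-12)

    def test_pooled_crude_matches_brute_force(self, scheme, small_counts):
        mids = dict(zip(scheme.labels, scheme.midpoints))
        df = small_counts.subset(disease="hfmd")
        expect = _loop_crude(df, mids)
        got = national_mean_age(small_counts, None, scheme, "hfmd", "crude")
        assert got == pytest.approx(expect, abs=1e-12)

    def test_pooling_consistency_case_weighted_regional_means(
        self, scheme, small_counts
    ):
        """National crude mean equals the case-weighted mean of regional means."""
        parts = []
        for r in ("r00", "r01"):
            n = small_counts.subset(disease="kd", region=r)["count"].sum()
            parts.append((crude_mean_age(small_counts, scheme, "kd", r), n))
        expect = sum(v * n for v, n in parts) / sum(n for _, n in parts)
        got = national_mean_age(small_counts, None, scheme, "kd", "crude")
        assert got == pytest.approx(expect, abs=1e-12)

    def test_adjusted_pooled_and_averaged_variants_close(
        self, scheme, small_counts, skewed_demography
    ):
        pooled = national_mean_age(
            small_counts, skewed_demography, scheme, "kd", "adjusted", pooling="pooled"
        )
        averaged = national_mean_age(
            small_counts, skewed_demography, scheme, "kd", "adjusted", pooling="averaged"
        )
        assert min(scheme.midpoints) <= pooled <= max(scheme.midpoints)
        assert min(scheme.midpoints) <= averaged <= max(scheme.midpoints)
        # the two pooling conventions agree to well under an age-group width
        assert pooled == pytest.approx(averaged, abs=1.0)


def test_mean_age_table_covers_all_diseases_and_regions(
    scheme, small_counts, skewed_demography
):
    t = mean_age_table(small_counts, skewed_demography, scheme)
    assert set(t["disease"]) == {"kd", "hfmd"}
    assert set(t["region"]) == {"r00", "r01", "national"}
    assert (t["crude"] >= min(scheme.midpoints)).all()
    assert (t["crude"] <= max(scheme.midpoints)).all()
    assert t["n_cases"].gt(0).all()
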