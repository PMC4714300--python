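"""Crude and demography-adjusted mean patient age from age-binned counts.

The crude mean patient age for disease *i* in region *j* pools case counts
over the study years and averages the age-group midpoints M_k weighted by
cases:

    cA_ij = sum_{k,m} M_k N_ijkm / sum_{k,m} N_ijkm

The adjusted mean removes interference from the regional demographic
structure by direct age-standardization: age-specific rates N_ijkm / C_jkm
are reweighted to a standard population structure S_k,

    w_k   = S_k * sum_m N_ijkm / C_jkm
    aA_ij = sum_k M_k w_k / sum_k w_k

so that two regions with identical age-specific risk but different age
pyramids report identical adjusted mean ages. When a region's age structure
equals the standard structure the adjustment is exactly the identity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data_model import AgeBinnedCounts, AgeGroupScheme, Demography, ValidationError

__all__ = [
    "crude_mean_age",
    "adjusted_mean_age",
    "national_mean_age",
    "mean_age_table",
]


class UndefinedMeanAgeError(ValueError):
    """Raised when a mean age is requested for zero total cases."""


def _pooled(counts: AgeBinnedCounts, disease, region, years) -> pd.DataFrame:
    df = counts.subset(disease=disease, region=region, years=years)
    if df.empty or df["count"].sum() <= 0:
        raise UndefinedMeanAgeError(
            f"no cases for disease={disease!r} region={region!r}"
        )
    return df


def crude_mean_age(
    counts: AgeBinnedCounts,
    scheme: AgeGroupScheme,
    disease: str,
    region: str,
    years=None,
) -> float:
    """Case-weighted mean of age-group midpoints, pooled over years."""
    df = _pooled(counts, disease, region, years)
    by_group = df.groupby("age_group")["count"].sum()
    mid = scheme.midpoint_series().reindex(by_group.index)
    return float((mid * by_group).sum() / by_group.sum())


def adjusted_mean_age(
    counts: AgeBinnedCounts,
    demography: Demography,
    scheme: AgeGroupScheme,
    disease: str,
    region: str,
    years=None,
) -> float:
    """Directly age-standardized mean patient age for one region."""
    df = _pooled(counts, disease, region, years)
    struct = demography.structure
    struct = struct[struct["region"] == region]
    c = struct.set_index(["year", "age_group"])["proportion"]

    rate_sum = pd.Series(0.0, index=list(scheme.labels))
    for (year, group), n in df.groupby(["year", "age_group"])["count"].sum().items():
        if n == 0:
            continue
        key = (year, group)
        if key not in c.index or c.loc[key] <= 0:
            raise ValidationError(
                f"zero or missing population share for region={region!r}, "
                f"age_group={group!r}, year={year} with {n} cases"
            )
        rate_sum[group] += n / c.loc[key]

    s = demography.standard.reindex(rate_sum.index)
    w = s * rate_sum
    mid = scheme.midpoint_series().reindex(rate_sum.index)
    return float((mid * w).sum() / w.sum())


def national_mean_age(
    counts: AgeBinnedCounts,
    demography: Demography,
    scheme: AgeGroupScheme,
    disease: str,
    mode: str = "crude",
    years=None,
    pooling: str = "pooled",
) -> float:
    """National-level mean patient age pooled over all regions.

    mode="crude" pools counts over every region; mode="adjusted" standardizes
    against a national age structure pooled across regions per (age group,
    year) — population-weighted when region-year population totals are
    available, otherwise unweighted ("pooled"), or, as a sensitivity variant,
    the case-weighted mean of the regional adjusted means ("averaged").
    """
    df = _pooled(counts, disease, None, years)
    if mode == "crude":
        by_group = df.groupby("age_group")["count"].sum()
        mid = scheme.midpoint_series().reindex(by_group.index)
        return float((mid * by_group).sum() / by_group.sum())
    if mode != "adjusted":
        raise ValueError("mode must be 'crude' or 'adjusted'")

    if pooling == "averaged":
        per_region = {
            r: adjusted_mean_age(counts, demography, scheme, disease, r, years)
            for r in df["region"].unique()
        }
        wts = df.groupby("region")["count"].sum()
        vals = pd.Series(per_region).reindex(wts.index)
        return float((vals * wts).sum() / wts.sum())
    if pooling != "pooled":
        raise ValueError("pooling must be 'pooled' or 'averaged'")

    struct = demography.structure
    if "population" in struct.columns:
        wt = struct["population"]
    else:
        wt = pd.Series(1.0, index=struct.index)
    num = (struct["proportion"] * wt).groupby(
        [struct["year"], struct["age_group"]]
    ).sum()
    den = wt.groupby([struct["year"], struct["region"]]).first().groupby("year").sum()
    c_nat = num / den.reindex(num.index.get_level_values("year")).to_numpy()

    rate_sum = pd.Series(0.0, index=list(scheme.labels))
    for (year, group), n in df.groupby(["year", "age_group"])["count"].sum().items():
        if n == 0:
            continue
        key = (year, group)
        if key not in c_nat.index or c_nat.loc[key] <= 0:
            raise ValidationError(
                f"zero national population share for age_group={group!r}, year={year}"
            )
        rate_sum[group] += n / c_nat.loc[key]
    s = demography.standard.reindex(rate_sum.index)
    w = s * rate_sum
    mid = scheme.midpoint_series().reindex(rate_sum.index)
    return float((mid * w).sum() / w.sum())


def mean_age_table(
    counts: AgeBinnedCounts,
    demography: Demography,
    scheme: AgeGroupScheme,
    years=None,
) -> pd.DataFrame:
    """Crude and adjusted mean ages for every (disease, region), plus national rows.

    Returns a tidy frame with columns disease, region, crude, adjusted,
    n_cases; the national rows use region id "national".
    """
    rows = []
    for disease in counts.diseases():
        for region in sorted(counts.subset(disease=disease)["region"].unique()):
            df = counts.subset(disease=disease, region=region, years=years)
            n = int(df["count"].sum())
            if n == 0:
                continue
            rows.append(
                dict(
                    disease=disease,
                    region=region,
                    crude=crude_mean_age(counts, scheme, disease, region, years),
                    adjusted=adjusted_mean_age(
                        counts, demography, scheme, disease, region, years
                    ),
                    n_cases=n,
                )
            )
        nat_n = int(counts.subset(disease=disease, years=years)["count"].sum())
        rows.append(
            dict(
                disease=disease,
                region="national",
                crude=national_mean_age(
                    counts, demography, scheme, disease, "crude", years
                ),
                adjusted=national_mean_age(
                    counts, demography, scheme, disease, "adjusted", years
                ),
                n_cases=nat_n,
            )
        )
    return pd.DataFrame(rows, columns=["disease", "region", "crude", "adjusted", "n_cases"])
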