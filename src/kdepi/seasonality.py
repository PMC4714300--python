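"""Within-year seasonal profiles and peak-structure classification.

For each complete calendar year the monthly share of that year's cases is
computed; the profile is the across-year mean with its standard deviation.
Profiles can be reported April-first to match the Japanese school year.
Peak structure (unimodal / bimodal / trimodal / other) is read off circular
local maxima whose prominence exceeds a configurable fraction of annual
cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .data_model import CaseSeries

__all__ = ["SeasonalProfile", "seasonal_profile", "classify_modality"]

log = logging.getLogger(__name__)

_CAL_MONTHS = list(range(1, 13))


@dataclass
class SeasonalProfile:
    """Mean (and SD) proportion of annual cases falling in each month."""

    months: tuple[int, ...]  # calendar month numbers in display order
    mean: np.ndarray
    sd: np.ndarray
    april_start: bool
    n_years: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"month": self.months, "mean_proportion": self.mean, "sd": self.sd}
        )


def seasonal_profile(
    series: CaseSeries, years=None, april_start: bool = False
) -> SeasonalProfile:
    """Average monthly proportions of annual cases across years.

    Years with a zero annual total are excluded with a logged warning; at
    least one complete calendar year of monthly data is required.
    """
    vals = series.values
    df = pd.DataFrame(
        {"year": vals.index.year, "month": vals.index.month, "count": np.asarray(vals)}
    )
    if years is not None:
        df = df[df["year"].isin(list(years))]
    complete = [
        y for y, g in df.groupby("year") if set(g["month"]) == set(_CAL_MONTHS)
    ]
    if not complete:
        raise ValueError("need at least one complete calendar year of monthly data")
    props = []
    for y in complete:
        g = df[df["year"] == y].set_index("month")["count"].reindex(_CAL_MONTHS)
        total = g.sum()
        if total <= 0:
            log.warning("year %s has zero annual total; excluded from profile", y)
            continue
        props.append((g / total).to_numpy())
    if not props:
        raise ValueError("every candidate year had zero annual cases")
    arr = np.vstack(props)
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=0)
    months = _CAL_MONTHS
    if april_start:
        order = list(range(3, 12)) + list(range(0, 3))  # Apr..Dec, Jan..Mar
        mean, sd = mean[order], sd[order]
        months = [_CAL_MONTHS[i] for i in order]
    return SeasonalProfile(
        months=tuple(months),
        mean=mean,
        sd=sd,
        april_start=april_start,
        n_years=len(props),
    )


def classify_modality(
    profile: SeasonalProfile, min_prominence: float = 0.01
) -> dict:
    """Count circular local maxima with prominence above ``min_prominence``.

    Returns the peak count, a label (unimodal/bimodal/trimodal/other), and
    the calendar months of the peaks in descending height order.  Prominence
    is measured on the circle by tiling the 12-month profile three times and
    keeping peaks from the central copy, so rotating the month ordering
    rotates the peaks identically.
    """
    x = np.asarray(profile.mean, dtype=float)
    n = len(x)
    tiled = np.tile(x, 3)
    idx, info = find_peaks(tiled, prominence=min_prominence)
    central = [(i - n, info["prominences"][j]) for j, i in enumerate(idx) if n <= i < 2 * n]
    central.sort(key=lambda p: -x[p[0]])
    months = [profile.months[i] for i, _ in central]
    count = len(central)
    label = {0: "none", 1: "unimodal", 2: "bimodal", 3: "trimodal"}.get(count, "other")
    return {"n_peaks": count, "label": label, "peak_months": months}
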