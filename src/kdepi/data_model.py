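"""Core surveillance data containers and delimited-text I/O.

The analysis consumes four kinds of tables, all plain CSV with a header row:

* age-binned case counts (disease, region, year, age_group, count),
* population age structures per region and year plus a standard structure,
* weekly or monthly case time series,
* a region-level covariate table and a binary region adjacency matrix
  (stored as an edge list).

Everything is keyed by explicit string identifiers, never positional order;
the adjacency matrix carries its region ordering explicitly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AgeGroupScheme",
    "AgeBinnedCounts",
    "Demography",
    "CaseSeries",
    "WeeklySeries",
    "CovariateTable",
    "AdjacencyMatrix",
    "read_counts",
    "write_counts",
    "read_demography",
    "write_demography",
    "read_covariates",
    "write_covariates",
    "read_adjacency",
    "write_adjacency",
    "weekly_to_monthly",
    "normalize_to_max",
]


class ValidationError(ValueError):
    """Raised when an input table violates its contract."""


# ---------------------------------------------------------------------------
# Age-group scheme
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgeGroupScheme:
    """Half-open age bins [lower, upper) with midpoint ages in years.

    The default scheme has 11 paediatric bins: two half-year bins under one
    year of age, yearly bins to age nine, and a 9-<15 y tail — the midpoints
    M_k are what the mean patient age is computed from.
    """

    labels: tuple[str, ...]
    lower: tuple[float, ...]
    upper: tuple[float, ...]
    midpoints: tuple[float, ...] = field(default=())

    def __post_init__(self):
        k = len(self.labels)
        if k < 2:
            raise ValidationError("age-group scheme needs at least 2 groups")
        if not (len(self.lower) == len(self.upper) == k):
            raise ValidationError("labels/lower/upper length mismatch")
        lo, up = np.asarray(self.lower), np.asarray(self.upper)
        if not np.all(up > lo):
            raise ValidationError("each upper bound must exceed its lower bound")
        if not (np.all(np.diff(lo) > 0) and np.all(lo[1:] >= up[:-1])):
            raise ValidationError("age bins must be increasing and non-overlapping")
        if not self.midpoints:
            object.__setattr__(self, "midpoints", tuple((lo + up) / 2.0))
        elif len(self.midpoints) != k:
            raise ValidationError("midpoints length mismatch")

    @property
    def k(self) -> int:
        return len(self.labels)

    def midpoint_series(self) -> pd.Series:
        return pd.Series(self.midpoints, index=list(self.labels), name="midpoint")

    def bin_ages(self, ages) -> np.ndarray:
        """Map ages (years) to group indices; ages outside all bins get -1."""
        ages = np.asarray(ages, dtype=float)
        edges = np.append(self.lower, self.upper[-1])
        idx = np.searchsorted(edges, ages, side="right") - 1
        idx[(ages < self.lower[0]) | (ages >= self.upper[-1])] = -1
        return idx

    @classmethod
    def default(cls) -> "AgeGroupScheme":
        lower = (0.0, 0.5, 1, 2, 3, 4, 5, 6, 7, 8, 9)
        upper = (0.5, 1.0, 2, 3, 4, 5, 6, 7, 8, 9, 15)
        labels = tuple(
            f"{lo:g}-<{up:g}" for lo, up in zip(lower, upper)
        )
        return cls(labels=labels, lower=lower, upper=upper)


# ---------------------------------------------------------------------------
# Age-binned case counts
# ---------------------------------------------------------------------------

_COUNT_COLS = ["disease", "region", "year", "age_group", "count"]


@dataclass
class AgeBinnedCounts:
    """Long-format case counts N_ijkm by disease, region, age group and year."""

    table: pd.DataFrame
    scheme: AgeGroupScheme

    def __post_init__(self):
        df = self.table
        missing = [c for c in _COUNT_COLS if c not in df.columns]
        if missing:
            raise ValidationError(f"counts table missing columns: {missing}")
        bad = df.index[df["count"] < 0]
        if len(bad):
            raise ValidationError(
                f"negative count at row(s) {list(bad[:5])}"
            )
        known = set(self.scheme.labels)
        unknown = set(df["age_group"].astype(str)) - known
        if unknown:
            raise ValidationError(f"unknown age group(s): {sorted(unknown)}")
        for (d, r), g in df.groupby(["disease", "region"], sort=False):
            yrs = np.sort(g["year"].unique())
            if len(yrs) > 1 and np.any(np.diff(yrs) != 1):
                raise ValidationError(
                    f"years not contiguous for disease={d!r} region={r!r}"
                )

    def __len__(self) -> int:
        return len(self.table)

    def diseases(self) -> list[str]:
        return sorted(self.table["disease"].unique())

    def regions(self) -> list[str]:
        return sorted(self.table["region"].unique())

    def subset(self, disease=None, region=None, years=None) -> pd.DataFrame:
        df = self.table
        if disease is not None:
            df = df[df["disease"] == disease]
        if region is not None:
            df = df[df["region"] == region]
        if years is not None:
            df = df[df["year"].isin(list(years))]
        return df


def read_counts(path, scheme: AgeGroupScheme) -> AgeBinnedCounts:
    df = pd.read_csv(path)
    missing = [c for c in _COUNT_COLS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    df["age_group"] = df["age_group"].astype(str)
    df["region"] = df["region"].astype(str)
    df["disease"] = df["disease"].astype(str)
    neg = df.index[df["count"] < 0]
    if len(neg):
        # +2: header line and 1-based numbering, so the message names file rows
        raise ValidationError(
            f"{path}: negative count at file row(s) {[int(i) + 2 for i in neg[:5]]}"
        )
    return AgeBinnedCounts(table=df.reset_index(drop=True), scheme=scheme)


def write_counts(counts: AgeBinnedCounts, path) -> None:
    cols = _COUNT_COLS + [c for c in counts.table.columns if c not in _COUNT_COLS]
    counts.table[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Demography
# ---------------------------------------------------------------------------

@dataclass
class Demography:
    """Region-year age structures C_jkm plus the standard structure S_k.

    ``structure`` is long format (region, year, age_group, proportion,
    optionally population — the region-year total used for national pooling);
    ``standard`` maps age_group -> S_k.
    """

    structure: pd.DataFrame
    standard: pd.Series

    def __post_init__(self):
        need = {"region", "year", "age_group", "proportion"}
        if not need <= set(self.structure.columns):
            raise ValidationError(f"demography table needs columns {sorted(need)}")
        p = self.structure["proportion"]
        if not np.all((p > 0) & (p <= 1)):
            raise ValidationError("age-structure proportions must lie in (0, 1]")
        sums = self.structure.groupby(["region", "year"])["proportion"].sum()
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = sums[~np.isclose(sums, 1.0, atol=1e-9)]
            raise ValidationError(
                f"age-structure proportions must sum to 1 per (region, year); "
                f"offending: {bad.index[:3].tolist()}"
            )
        s = np.asarray(self.standard, dtype=float)
        if not np.isclose(s.sum(), 1.0, atol=1e-9) or not np.all((s > 0) & (s <= 1)):
            raise ValidationError("standard structure must be proportions summing to 1")

    def proportions(self, region, year) -> pd.Series:
        g = self.structure[
            (self.structure["region"] == region) & (self.structure["year"] == year)
        ]
        return g.set_index("age_group")["proportion"]


def read_demography(structure_path, standard_path) -> Demography:
    struct = pd.read_csv(structure_path)
    struct["region"] = struct["region"].astype(str)
    struct["age_group"] = struct["age_group"].astype(str)
    std = pd.read_csv(standard_path)
    if not {"age_group", "proportion"} <= set(std.columns):
        raise ValidationError("standard structure needs age_group, proportion columns")
    standard = std.set_index(std["age_group"].astype(str))["proportion"]
    return Demography(structure=struct, standard=standard)


def write_demography(demog: Demography, structure_path, standard_path) -> None:
    demog.structure.to_csv(structure_path, index=False)
    demog.standard.rename("proportion").rename_axis("age_group").reset_index().to_csv(
        standard_path, index=False
    )


# ---------------------------------------------------------------------------
# Case time series
# ---------------------------------------------------------------------------

@dataclass
class WeeklySeries:
    """Weekly case counts for one disease; each week carries its start date."""

    disease: str
    table: pd.DataFrame  # columns: week_start (datetime), count

    def __post_init__(self):
        t = self.table
        if not {"week_start", "count"} <= set(t.columns):
            raise ValidationError("weekly series needs week_start, count columns")
        t["week_start"] = pd.to_datetime(t["week_start"])
        if t["week_start"].duplicated().any():
            raise ValidationError("duplicate weeks in weekly series")
        starts = t["week_start"].sort_values().to_numpy()
        if len(starts) > 1:
            gaps = np.diff(starts) / np.timedelta64(1, "D")
            if np.any(gaps < 7):
                raise ValidationError("overlapping weeks in weekly series")
        if (t["count"] < 0).any():
            raise ValidationError("negative weekly count")


@dataclass
class CaseSeries:
    """Monthly case series, either raw counts or proportion-of-maximum."""

    disease: str
    values: pd.Series  # index: pd.PeriodIndex (monthly)
    kind: str = "raw"  # "raw" | "proportion-of-maximum"

    def __post_init__(self):
        if not isinstance(self.values.index, pd.PeriodIndex):
            raise ValidationError("monthly series must be indexed by pandas Periods")
        v = np.asarray(self.values, dtype=float)
        if self.kind == "raw":
            if np.any(v < 0):
                raise ValidationError("raw counts must be non-negative")
        elif self.kind == "proportion-of-maximum":
            if np.any((v < 0) | (v > 1)) or not np.isclose(v.max(), 1.0):
                raise ValidationError(
                    "normalized series must lie in [0,1] with maximum exactly 1"
                )
        else:
            raise ValidationError(f"unknown series kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.values)


def weekly_to_monthly(weekly: WeeklySeries) -> CaseSeries:
    """Convert a weekly series to monthly by day-count apportionment.

    Each week's count is split across the calendar months it overlaps in
    proportion to the number of the week's seven days falling in each month,
    so the monthly totals conserve the weekly grand total exactly (up to
    floating rationals n/7).
    """
    t = weekly.table.sort_values("week_start")
    acc: dict[pd.Period, float] = {}
    for start, count in zip(t["week_start"], t["count"]):
        days = pd.date_range(start, periods=7, freq="D")
        for per, n_days in days.to_period("M").value_counts().items():
            acc[per] = acc.get(per, 0.0) + count * (n_days / 7.0)
    idx = pd.period_range(min(acc), max(acc), freq="M")
    vals = pd.Series([acc.get(p, 0.0) for p in idx], index=idx, name="count")
    return CaseSeries(disease=weekly.disease, values=vals, kind="raw")


def normalize_to_max(series: CaseSeries) -> CaseSeries:
    """Express a series as the proportion of its maximum value (max becomes 1)."""
    v = np.asarray(series.values, dtype=float)
    m = v.max() if len(v) else 0.0
    if m <= 0:
        raise ValidationError("cannot normalize a series with no positive value")
    out = pd.Series(v / m, index=series.values.index, name="proportion")
    return CaseSeries(disease=series.disease, values=out, kind="proportion-of-maximum")


# ---------------------------------------------------------------------------
# Covariates and adjacency
# ---------------------------------------------------------------------------

@dataclass
class CovariateTable:
    """One row per region; named real-valued covariates (the columns of X)."""

    table: pd.DataFrame  # index: region id

    def __post_init__(self):
        if self.table.index.duplicated().any():
            raise ValidationError("duplicate region rows in covariate table")
        if self.table.isna().any().any():
            bad = self.table.columns[self.table.isna().any()].tolist()
            raise ValidationError(
                f"missing covariate cells in columns {bad}; impute explicitly"
            )

    @property
    def regions(self) -> list[str]:
        return list(self.table.index)

    @property
    def names(self) -> list[str]:
        return list(self.table.columns)


def read_covariates(path) -> CovariateTable:
    df = pd.read_csv(path)
    if "region" not in df.columns:
        raise ValidationError("covariate table needs a region column")
    df["region"] = df["region"].astype(str)
    return CovariateTable(table=df.set_index("region"))


def write_covariates(cov: CovariateTable, path) -> None:
    cov.table.rename_axis("region").reset_index().to_csv(path, index=False)


@dataclass
class AdjacencyMatrix:
    """Binary symmetric region contiguity matrix with explicit region order."""

    matrix: np.ndarray
    regions: tuple[str, ...]

    def __post_init__(self):
        u = np.asarray(self.matrix)
        n = len(self.regions)
        if u.shape != (n, n):
            raise ValidationError("adjacency shape does not match region list")
        if not np.array_equal(u, u.T):
            raise ValidationError("adjacency must be symmetric")
        if np.any(np.diag(u) != 0):
            raise ValidationError("adjacency diagonal must be zero")
        if not np.isin(u, (0, 1)).all():
            raise ValidationError("adjacency entries must be 0 or 1")
        self.matrix = u.astype(float)

    def row_standardized(self) -> np.ndarray:
        """Row-standardized weight matrix (rows sum to 1; isolated rows stay 0)."""
        u = self.matrix.copy()
        deg = u.sum(axis=1, keepdims=True)
        np.divide(u, deg, out=u, where=deg > 0)
        return u

    def reorder(self, regions) -> np.ndarray:
        idx = [self.regions.index(r) for r in regions]
        return self.matrix[np.ix_(idx, idx)]


def read_adjacency(path, regions=None) -> AdjacencyMatrix:
    """Load adjacency from an edge-list CSV (columns region_a, region_b)."""
    df = pd.read_csv(path)
    if not {"region_a", "region_b"} <= set(df.columns):
        raise ValidationError("adjacency edge list needs region_a, region_b columns")
    a = df["region_a"].astype(str)
    b = df["region_b"].astype(str)
    if regions is None:
        regions = sorted(set(a) | set(b))
    regions = tuple(str(r) for r in regions)
    pos = {r: i for i, r in enumerate(regions)}
    u = np.zeros((len(regions), len(regions)))
    for x, y in zip(a, b):
        if x not in pos or y not in pos:
            raise ValidationError(f"edge ({x}, {y}) references unknown region")
        u[pos[x], pos[y]] = u[pos[y], pos[x]] = 1.0
    return AdjacencyMatrix(matrix=u, regions=regions)


def write_adjacency(adj: AdjacencyMatrix, path) -> None:
    rows = []
    n = len(adj.regions)
    for i in range(n):
        for j in range(i + 1, n):
            if adj.matrix[i, j]:
                rows.append((adj.regions[i], adj.regions[j]))
    pd.DataFrame(rows, columns=["region_a", "region_b"]).to_csv(path, index=False)
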