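"""Synthetic sentinel-surveillance generator.

Real national KD surveillance and sentinel clinic records are not
redistributable, so every downstream stage is exercised on simulated data
with the statistical structure the analysis assumes:

* a seasonally forced stochastic SEIR metapopulation (Euler-binomial
  updates, demographic turnover, reporting thinning) whose incident
  infections carry an age at infection, so mean patient age, force of
  infection and inter-epidemic periodicity are all emergent;
* i.i.d. exponential infection ages at a known constant force of infection,
  the textbook limit the mean-age estimator should invert;
* a spatial-lag regression fixture Y = (I - rho U)^(-1) (X beta + e) with
  recorded truth for parameter-recovery experiments.

Default conditions mirror the study design: 47 regions, an eleven-year
recording window (2000-2010), weekly reporting aggregated from daily
dynamics, and a fertility covariate that drives regional birth rates (and
hence the force of infection, the sibling-contact mechanism).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_model import (
    AdjacencyMatrix,
    AgeBinnedCounts,
    AgeGroupScheme,
    CaseSeries,
    CovariateTable,
    Demography,
    WeeklySeries,
)

__all__ = [
    "SEIRConfig",
    "SyntheticBundle",
    "simulate_seir",
    "simulate_diseases",
    "make_ages_constant_foi",
    "ages_to_counts",
    "make_regression_fixture",
    "make_covariates",
    "grid_adjacency",
]

_DAYS_PER_YEAR = 365
_DT = 1.0 / _DAYS_PER_YEAR


# ---------------------------------------------------------------------------
# Configuration and bundle containers
# ---------------------------------------------------------------------------

@dataclass
class SEIRConfig:
    """One disease's simulation setup.

    ``r0`` sets the per-region transmission scale (beta0_j = r0_j / infectious
    period); regional birth rates are ``population / life_expectancy`` scaled
    by the fertility covariate, which is the mechanism that differentiates the
    force of infection across regions.
    """

    disease: str = "disease"
    n_regions: int = 47
    population: float = 3e5            # per region (children+adults tracked to track_age)
    r0: float | np.ndarray = 12.0      # basic reproduction number per region
    seasonal_amplitude: float = 0.08   # epsilon in beta(t) = beta0 (1 + eps * term(t))
    forcing: str = "sinusoidal"        # "sinusoidal" | "school"
    incubation_years: float = 10.0 / 365.0      # D
    infectious_years: float = 0.02               # D'
    life_expectancy: float = 80.0
    fertility_scale: float | np.ndarray = 1.0    # multiplies the birth rate
    birth_trend: float | np.ndarray = 0.0        # relative birth-rate drift per year
    reporting_fraction: float = 1.0
    import_rate: float = 1e-3          # external per-susceptible hazard, 1/year
    burn_in_years: int = 5
    record_years: int = 11
    start_year: int = 2000
    track_age: float = 40.0            # susceptibles aged out beyond this (years)
    age_cohort_width: float = 1.0 / 12.0
    seed: int = 0
    scheme: AgeGroupScheme = field(default_factory=AgeGroupScheme.default)

    def __post_init__(self):
        if self.incubation_years <= 0 or self.infectious_years <= 0:
            raise ValueError("incubation and infectious periods must be positive")
        if not (0 <= self.seasonal_amplitude < 1):
            raise ValueError("seasonal amplitude must lie in [0, 1)")
        if not (0 < self.reporting_fraction <= 1):
            raise ValueError("reporting fraction must lie in (0, 1]")
        if self.population <= 0 or self.life_expectancy <= 0:
            raise ValueError("population and life expectancy must be positive")


@dataclass
class SyntheticBundle:
    """Simulated surveillance plus the ground truth that produced it."""

    counts: AgeBinnedCounts
    weekly: dict                 # region id -> WeeklySeries; "pooled" -> national
    demography: Demography
    covariates: CovariateTable
    adjacency: AdjacencyMatrix
    truth: dict
    warnings: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Exponential infection ages (constant-FOI limit)
# ---------------------------------------------------------------------------

def make_ages_constant_foi(
    foi: float, n: int, seed: int | np.random.Generator = 0, max_age: float | None = None
) -> np.ndarray:
    """i.i.d. exponential(foi) infection ages, optionally truncated at max_age.

    Truncation samples from the conditional distribution on [0, max_age), so
    the sample mean falls below 1/foi when max_age is finite.
    """
    if foi <= 0 or n <= 0:
        raise ValueError("foi and n must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if max_age is None:
        return rng.exponential(1.0 / foi, size=n)
    u = rng.uniform(0.0, 1.0 - np.exp(-foi * max_age), size=n)
    return -np.log1p(-u) / foi


def ages_to_counts(
    ages,
    scheme: AgeGroupScheme,
    disease: str = "disease",
    region: str = "r00",
    year: int = 2000,
) -> AgeBinnedCounts:
    """Bin a sample of infection ages into an age-binned count table."""
    idx = scheme.bin_ages(np.asarray(ages, dtype=float))
    idx = idx[idx >= 0]
    counts = np.bincount(idx, minlength=scheme.k)
    df = pd.DataFrame(
        {
            "disease": disease,
            "region": region,
            "year": year,
            "age_group": list(scheme.labels),
            "count": counts,
        }
    )
    return AgeBinnedCounts(table=df, scheme=scheme)


# ---------------------------------------------------------------------------
# Covariates and adjacency
# ---------------------------------------------------------------------------

def make_covariates(n_regions: int = 47, seed: int = 0) -> CovariateTable:
    """Regional covariate table: fertility, health-service use, climate, noise.

    ``tfr`` is the covariate the SEIR generator couples to birth rates;
    ``insurance`` is mildly anti-correlated with it (as in the motivating
    setting); the remainder are independent distractors.
    """
    rng = np.random.default_rng(seed)
    regions = [f"r{j:02d}" for j in range(n_regions)]
    tfr = np.clip(rng.normal(1.45, 0.18, n_regions), 0.9, 2.2)
    insurance = np.clip(
        rng.normal(50.0, 6.0, n_regions) - 8.0 * (tfr - tfr.mean()), 20, 90
    )
    temperature = rng.normal(14.0, 3.0, n_regions)
    vaccine_uptake = np.clip(rng.normal(0.25, 0.08, n_regions), 0.02, 0.8)
    noise = rng.normal(0.0, 1.0, n_regions)
    return CovariateTable(
        table=pd.DataFrame(
            {
                "tfr": tfr,
                "insurance": insurance,
                "temperature": temperature,
                "vaccine_uptake": vaccine_uptake,
                "noise": noise,
            },
            index=pd.Index(regions, name="region"),
        )
    )


def grid_adjacency(n_regions: int = 47) -> AdjacencyMatrix:
    """Rook-contiguity adjacency on a near-square grid of regions.

    A compact planar stand-in for prefecture contiguity; the last partial
    grid row is simply shorter.
    """
    ncol = int(np.ceil(np.sqrt(n_regions)))
    u = np.zeros((n_regions, n_regions))
    for j in range(n_regions):
        r, c = divmod(j, ncol)
        for dr, dc in ((0, 1), (1, 0)):
            r2, c2 = r + dr, c + dc
            j2 = r2 * ncol + c2
            if c2 < ncol and j2 < n_regions:
                u[j, j2] = u[j2, j] = 1.0
    regions = tuple(f"r{j:02d}" for j in range(n_regions))
    return AdjacencyMatrix(matrix=u, regions=regions)


# ---------------------------------------------------------------------------
# Spatial-lag regression fixture
# ---------------------------------------------------------------------------

def make_regression_fixture(
    n_regions: int,
    beta: np.ndarray,
    rho: float,
    adjacency: AdjacencyMatrix | np.ndarray,
    noise_sd: float = 1.0,
    seed: int = 0,
    intercept: float = 0.0,
):
    """Draw (X, Y) from the spatial-lag model with known parameters.

    Y = (I - rho U)^(-1) (intercept + X beta + e), e ~ N(0, noise_sd^2).
    Columns of X are standardized.  ``rho`` must lie strictly inside the
    invertibility interval set by the eigenvalues of U.
    """
    rng = np.random.default_rng(seed)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    u = adjacency.matrix if isinstance(adjacency, AdjacencyMatrix) else np.asarray(adjacency, float)
    if u.shape != (n_regions, n_regions):
        raise ValueError("adjacency shape does not match n_regions")
    eigs = np.real(np.linalg.eigvals(u))
    lo = 1.0 / eigs.min() if eigs.min() < 0 else -np.inf
    hi = 1.0 / eigs.max() if eigs.max() > 0 else np.inf
    if not (lo < rho < hi):
        raise ValueError(
            f"rho={rho} outside the invertibility interval ({lo:.4g}, {hi:.4g})"
        )
    x = rng.normal(size=(n_regions, len(beta)))
    x = (x - x.mean(axis=0)) / x.std(axis=0)
    e = rng.normal(0.0, noise_sd, n_regions)
    a_inv = np.linalg.inv(np.eye(n_regions) - rho * u)
    y = a_inv @ (intercept + x @ beta + e)

    regions = (
        list(adjacency.regions)
        if isinstance(adjacency, AdjacencyMatrix)
        else [f"r{j:02d}" for j in range(n_regions)]
    )
    xdf = pd.DataFrame(
        x, index=pd.Index(regions, name="region"),
        columns=[f"x{i}" for i in range(len(beta))],
    )
    yser = pd.Series(y, index=xdf.index, name="y")
    truth = {"rho": rho, "beta": beta, "intercept": intercept, "noise_sd": noise_sd,
             "seed": seed}
    return CovariateTable(table=xdf), yser, truth


# ---------------------------------------------------------------------------
# Stochastic SEIR metapopulation
# ---------------------------------------------------------------------------

def _forcing_term(day_of_year: int, kind: str) -> float:
    if kind == "sinusoidal":
        return float(np.cos(2.0 * np.pi * day_of_year / _DAYS_PER_YEAR))
    # Japanese school calendar (April-start year): -1 during the spring,
    # summer and year-end breaks, +1 in term time.
    d = day_of_year
    holiday = (85 <= d < 100) or (205 <= d < 240) or (d >= 355) or (d < 7)
    return -1.0 if holiday else 1.0


def simulate_seir(config: SEIRConfig) -> SyntheticBundle:
    """Simulate one disease across the metapopulation and package surveillance.

    Daily Euler-binomial dynamics: infection totals are binomial draws against
    the current force of infection, latency and recovery are binomial exits,
    and susceptibles live in real-valued monthly age cohorts depleted
    proportionally (the age distribution of infections follows the cohort
    composition).  Reported counts are binomial thinnings at the configured
    reporting fraction.  Extinction (a region recording zero prevalence) is
    flagged, never silently resimulated.
    """
    cfg = config
    # separate streams: changing the reporting fraction must not perturb the
    # underlying epidemic trajectory at a fixed seed
    _dyn_ss, _rep_ss = np.random.SeedSequence(cfg.seed).spawn(2)
    rng = np.random.default_rng(_dyn_ss)
    rng_report = np.random.default_rng(_rep_ss)
    j = cfg.n_regions
    regions = [f"r{i:02d}" for i in range(j)]
    scheme = cfg.scheme

    n_coh = int(round(cfg.track_age / cfg.age_cohort_width))
    ages_mid = (np.arange(n_coh) + 0.5) * cfg.age_cohort_width

    r0 = np.broadcast_to(np.asarray(cfg.r0, dtype=float), (j,)).copy()
    covariates = make_covariates(j, seed=cfg.seed)
    fs = np.asarray(cfg.fertility_scale, dtype=float)
    if fs.ndim == 0:
        # couple birth rates to the generated fertility covariate (sibling-
        # contact mechanism): higher TFR => more births => higher FOI
        tfr = covariates.table["tfr"].to_numpy()
        fert = float(fs) * tfr / tfr.mean()
    else:
        fert = np.broadcast_to(fs, (j,)).copy()
        covariates.table["tfr"] = fert * 1.45  # keep the covariate consistent
    trend = np.broadcast_to(np.asarray(cfg.birth_trend, dtype=float), (j,)).copy()
    beta0 = r0 / cfg.infectious_years
    pop = float(cfg.population)
    births0 = pop / cfg.life_expectancy * fert      # per region-year

    # endemic-equilibrium initialization: lambda* = births * R0 / N
    lam0 = births0 * r0 / pop
    coh_births = births0[:, None] * cfg.age_cohort_width
    s = coh_births * np.exp(-lam0[:, None] * ages_mid[None, :])
    inc0 = lam0 * s.sum(axis=1)
    e_comp = np.maximum(np.rint(inc0 * cfg.incubation_years), 1).astype(np.int64)
    i_comp = np.maximum(np.rint(inc0 * cfg.infectious_years), 1).astype(np.int64)

    # total-population cohorts (for the demography tables); births only
    p_coh = births0[:, None] * cfg.age_cohort_width * np.ones((j, n_coh))

    p_e = 1.0 - np.exp(-_DT / cfg.incubation_years)
    p_i = 1.0 - np.exp(-_DT / cfg.infectious_years)

    total_years = cfg.burn_in_years + cfg.record_years
    n_days = total_years * _DAYS_PER_YEAR
    record_start_day = cfg.burn_in_years * _DAYS_PER_YEAR

    bin_idx = scheme.bin_ages(ages_mid)            # cohort -> age-group index (-1 if outside)
    n_bins = scheme.k
    bin_cohorts = [np.flatnonzero(bin_idx == b) for b in range(n_bins)]

    week_counts: list[np.ndarray] = []
    week_acc = np.zeros(j)
    week_day = 0
    year_bin_acc = np.zeros((j, n_bins))
    yearly_counts = {}                              # year -> (j, n_bins) int array
    demog_rows = []
    age_sum = np.zeros(j)
    inf_sum = np.zeros(j)
    sus_years = np.zeros(j)
    extinct = np.zeros(j, dtype=bool)
    month_acc = 0.0

    for day in range(n_days):
        doy = day % _DAYS_PER_YEAR
        year = cfg.start_year - cfg.burn_in_years + day // _DAYS_PER_YEAR
        recording = day >= record_start_day
        term = _forcing_term(doy, cfg.forcing)
        beta_t = beta0 * (1.0 + cfg.seasonal_amplitude * term)

        s_tot = s.sum(axis=1)
        lam = beta_t * i_comp / pop + cfg.import_rate
        p_inf = -np.expm1(-lam * _DT)
        new_inf = rng.binomial(np.maximum(np.rint(s_tot), 0).astype(np.int64), p_inf)

        if new_inf.any():
            frac = s / np.maximum(s_tot, 1e-12)[:, None]
            depletion = new_inf[:, None] * frac
            s -= depletion
            np.clip(s, 0.0, None, out=s)
            if recording:
                age_sum += (depletion * ages_mid[None, :]).sum(axis=1)
                inf_sum += new_inf
                # expected allocation of this day's infections to age groups
                for b, sel in enumerate(bin_cohorts):
                    if len(sel):
                        year_bin_acc[:, b] += depletion[:, sel].sum(axis=1)
        if recording:
            sus_years += s_tot * _DT
            week_acc += new_inf

        out_e = rng.binomial(e_comp, p_e)
        out_i = rng.binomial(i_comp, p_i)
        e_comp += new_inf - out_e
        i_comp += out_e - out_i
        if recording:
            extinct |= (e_comp + i_comp) == 0

        # births and aging
        s[:, 0] += births0 * (1.0 + trend * (day * _DT)) * _DT
        p_coh[:, 0] += births0 * (1.0 + trend * (day * _DT)) * _DT
        month_acc += _DT / cfg.age_cohort_width
        if month_acc >= 1.0:
            month_acc -= 1.0
            s[:, 1:] = s[:, :-1]
            s[:, 0] = 0.0
            p_coh[:, 1:] = p_coh[:, :-1]
            p_coh[:, 0] = 0.0

        if recording:
            week_day += 1
            if week_day == 7:
                reported = rng_report.binomial(
                    np.rint(week_acc).astype(np.int64), cfg.reporting_fraction
                )
                week_counts.append(reported)
                week_acc[:] = 0.0
                week_day = 0
            if doy == _DAYS_PER_YEAR - 1:
                yearly = np.zeros((j, n_bins), dtype=np.int64)
                for b in range(n_bins):
                    yearly[:, b] = rng_report.binomial(
                        np.rint(year_bin_acc[:, b]).astype(np.int64),
                        cfg.reporting_fraction,
                    )
                yearly_counts[year] = yearly
                year_bin_acc[:] = 0.0
                # demography snapshot: structure of the tracked child cohorts
                in_bins = bin_idx >= 0
                for ji, reg in enumerate(regions):
                    tot = p_coh[ji, in_bins].sum()
                    for b, sel in enumerate(bin_cohorts):
                        demog_rows.append(
                            (reg, year, scheme.labels[b], p_coh[ji, sel].sum() / tot, pop)
                        )

    # ---- package outputs -------------------------------------------------
    count_rows = []
    for year in sorted(yearly_counts):
        arr = yearly_counts[year]
        for ji, reg in enumerate(regions):
            for b in range(n_bins):
                count_rows.append(
                    (cfg.disease, reg, year, scheme.labels[b], int(arr[ji, b]))
                )
    counts = AgeBinnedCounts(
        table=pd.DataFrame(
            count_rows, columns=["disease", "region", "year", "age_group", "count"]
        ),
        scheme=scheme,
    )

    weeks = np.asarray(week_counts)                 # (n_weeks, j)
    week_starts = pd.date_range(
        f"{cfg.start_year}-01-01", periods=weeks.shape[0], freq="7D"
    )
    weekly = {
        reg: WeeklySeries(
            disease=cfg.disease,
            table=pd.DataFrame({"week_start": week_starts, "count": weeks[:, ji]}),
        )
        for ji, reg in enumerate(regions)
    }
    weekly["pooled"] = WeeklySeries(
        disease=cfg.disease,
        table=pd.DataFrame({"week_start": week_starts, "count": weeks.sum(axis=1)}),
    )

    demog_df = pd.DataFrame(
        demog_rows, columns=["region", "year", "age_group", "proportion", "population"]
    )
    first_year = min(yearly_counts)
    std = (
        demog_df[demog_df["year"] == first_year]
        .groupby("age_group", sort=False)["proportion"]
        .mean()
    )
    std = std / std.sum()
    demography = Demography(structure=demog_df, standard=std.reindex(list(scheme.labels)))

    adjacency = grid_adjacency(j)

    realized_foi = np.divide(inf_sum, sus_years, out=np.zeros(j), where=sus_years > 0)
    mean_age = np.divide(age_sum, inf_sum, out=np.full(j, np.nan), where=inf_sum > 0)
    truth = {
        "disease": cfg.disease,
        "seed": cfg.seed,
        "incubation_years": cfg.incubation_years,
        "infectious_years": cfg.infectious_years,
        "r0": r0,
        "beta0": beta0,
        "realized_foi": pd.Series(realized_foi, index=regions),
        "realized_mean_infection_age": pd.Series(mean_age, index=regions),
        "fertility_scale": pd.Series(fert, index=regions),
    }
    warn = (
        [f"extinction detected in regions: {[regions[i] for i in np.flatnonzero(extinct)]}"]
        if extinct.any()
        else []
    )
    return SyntheticBundle(
        counts=counts,
        weekly=weekly,
        demography=demography,
        covariates=covariates,
        adjacency=adjacency,
        truth=truth,
        warnings=warn,
    )


def simulate_diseases(base: SEIRConfig, diseases: dict) -> SyntheticBundle:
    """Simulate several diseases over one shared region set.

    ``diseases`` maps a disease id to a dict of SEIRConfig field overrides
    (e.g. r0, incubation/infectious periods).  Counts tables are concatenated;
    demography, covariates and adjacency are taken from the first disease
    (same region set by construction); weekly series are nested per disease.
    """
    fs = np.asarray(base.fertility_scale, dtype=float)
    if fs.ndim == 0:
        # one fertility draw shared by every disease, so regional FOI
        # differences line up with the exported covariate table
        tfr = make_covariates(base.n_regions, seed=base.seed).table["tfr"].to_numpy()
        shared_fert = float(fs) * tfr / tfr.mean()
    else:
        shared_fert = np.broadcast_to(fs, (base.n_regions,)).copy()
    bundles = {}
    for k, (name, overrides) in enumerate(diseases.items()):
        cfg = replace(
            base,
            disease=name,
            seed=base.seed + 1000 * k,
            fertility_scale=shared_fert,
            **overrides,
        )
        bundles[name] = simulate_seir(cfg)
    first = next(iter(bundles.values()))
    counts = AgeBinnedCounts(
        table=pd.concat([b.counts.table for b in bundles.values()], ignore_index=True),
        scheme=base.scheme,
    )
    weekly = {name: b.weekly for name, b in bundles.items()}
    truth = {name: b.truth for name, b in bundles.items()}
    warnings_ = [w for b in bundles.values() for w in b.warnings]
    return SyntheticBundle(
        counts=counts,
        weekly=weekly,
        demography=first.demography,
        covariates=first.covariates,
        adjacency=first.adjacency,
        truth=truth,
        warnings=warnings_,
    )
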