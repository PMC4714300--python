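import numpy as np
import pandas as pd
import pytest

from kdepi.data_model import (
    AgeBinnedCounts,
    AgeGroupScheme,
    CovariateTable,
    Demography,
)


@pytest.fixture(scope="session")
def scheme():
    return AgeGroupScheme.default()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts(scheme):
    """Two diseases, two regions, two years, counts spread over all bins."""
    rng = np.random.default_rng(7)
    rows = []
    for d in ("kd", "hfmd"):
        for r in ("r00", "r01"):
            for y in (2000, 2001):
                for g in scheme.labels:
                    rows.append((d, r, y, g, int(rng.integers(0, 50))))
    df = pd.DataFrame(rows, columns=["disease", "region", "year", "age_group", "count"])
    return AgeBinnedCounts(table=df, scheme=scheme)


@pytest.fixture
def uniform_demography(scheme, small_counts):
    """Every region-year has the standard structure (C == S)."""
    s = np.array([up - lo for lo, up in zip(scheme.lower, scheme.upper)], dtype=float)
    s = s / s.sum()
    rows = []
    for r in ("r00", "r01"):
        for y in (2000, 2001):
            for g, p in zip(scheme.labels, s):
                rows.append((r, y, g, p, 1e5))
    struct = pd.DataFrame(
        rows, columns=["region", "year", "age_group", "proportion", "population"]
    )
    standard = pd.Series(s, index=list(scheme.labels))
    return Demography(structure=struct, standard=standard)


@pytest.fixture
def skewed_demography(scheme):
    """Region-years with different, non-standard age structures."""
    rng = np.random.default_rng(11)
    k = scheme.k
    rows = []
    for r in ("r00", "r01"):
        for y in (2000, 2001):
            p = rng.dirichlet(np.arange(2, 2 + k)[::-1].astype(float))
            for g, pi in zip(scheme.labels, p):
                rows.append((r, y, g, pi, 1e5 * (1 + rng.uniform())))
    struct = pd.DataFrame(
        rows, columns=["region", "year", "age_group", "proportion", "population"]
    )
    s = rng.dirichlet(np.full(k, 5.0))
    standard = pd.Series(s, index=list(scheme.labels))
    return Demography(structure=struct, standard=standard)


@pytest.fixture
def covariates6():
    rng = np.random.default_rng(3)
    idx = pd.Index([f"r{j:02d}" for j in range(6)], name="region")
    return CovariateTable(
        table=pd.DataFrame(
            {"a": rng.normal(size=6), "b": rng.normal(size=6)}, index=idx
        )
    )
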