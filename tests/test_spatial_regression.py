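"""Screening, uniqueness, stepwise selection and the spatial-lag ML fit."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kdepi.data_model import CovariateTable
from kdepi.spatial_regression import (
    fit_spatial_lag,
    screen_covariates,
    stepwise_ols,
    uniqueness_scores,
)
from kdepi.synthetic_data import grid_adjacency, make_regression_fixture


def _cov(df):
    df.index.name = "region"
    return CovariateTable(table=df)


class TestScreening:
    def _ages(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        idx = pd.Index([f"r{j:02d}" for j in range(n)], name="region")
        return pd.DataFrame(
            {"kd": rng.uniform(2, 4, n), "hfmd": rng.uniform(5, 8, n)}, index=idx
        )

    def test_monotone_transform_retained_with_unit_rho(self):
        ages = self._ages()
        ages["hfmd"] = ages["kd"] ** 2  # shared monotone structure across diseases
        x = _cov(pd.DataFrame({"good": np.exp(-ages["kd"])}, index=ages.index))
        rep = screen_covariates(ages, x)
        assert abs(rep.rho("good", "kd")) == pytest.approx(1.0)
        assert abs(rep.rho("good", "hfmd")) == pytest.approx(1.0)
        assert "good" in rep.retained

    def test_constant_covariate_not_retained_with_reason(self):
        ages = self._ages()
        x = _cov(pd.DataFrame({"flat": np.ones(len(ages))}, index=ages.index))
        rep = screen_covariates(ages, x)
        assert "flat" not in rep.retained
        assert "constant" in rep.reasons["flat"]

    def test_matches_rank_then_pearson_oracle(self):
        """Spearman rho equals Pearson correlation of the rank vectors."""
        ages = self._ages(n=6, seed=3)
        rng = np.random.default_rng(4)
        x = _cov(pd.DataFrame({"v": rng.normal(size=6)}, index=ages.index))
        rep = screen_covariates(ages, x)
        for d in ("kd", "hfmd"):
            rx = stats.rankdata(x.table["v"])
            ry = stats.rankdata(ages[d])
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert rep.rho("v", d) == pytest.approx(oracle, abs=1e-12)

    def test_noise_covariate_rarely_retained(self):
        """Retention of pure noise requires P<alpha for every disease."""
        hits = 0
        n_rep = 200
        for s in range(n_rep):
            ages = self._ages(n=47, seed=s)
            rng = np.random.default_rng(10_000 + s)
            x = _cov(pd.DataFrame({"noise": rng.normal(size=47)}, index=ages.index))
            if "noise" in screen_covariates(ages, x).retained:
                hits += 1
        # two independent diseases: expected rate about 0.05^2
        assert hits / n_rep < 0.02


class TestUniqueness:
    def test_duplicated_pair_low_independent_high(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=60)
        df = pd.DataFrame(
            {
                "a": a,
                "a_copy": a + 1e-3 * rng.normal(size=60),
                "solo": rng.normal(size=60),
            },
            index=[f"r{j}" for j in range(60)],
        )
        u = uniqueness_scores(_cov(df))
        assert u["a"] < 0.1 and u["a_copy"] < 0.1
        assert u["solo"] > 0.5

    def test_orthogonal_covariates_near_one(self):
        rng = np.random.default_rng(1)
        q, _ = np.linalg.qr(rng.normal(size=(80, 3)))
        df = pd.DataFrame(q, columns=list("abc"), index=[f"r{j}" for j in range(80)])
        u = uniqueness_scores(_cov(df))
        assert (u > 0.6).all()

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            rng.normal(size=(30, 4)), columns=list("abcd"),
            index=[f"r{j}" for j in range(30)],
        )
        u = uniqueness_scores(_cov(df))
        assert ((u >= 0) & (u <= 1)).all()

    def test_singular_matrix_rejected(self):
        a = np.arange(10.0)
        df = pd.DataFrame({"a": a, "b": 2 * a}, index=[f"r{j}" for j in range(10)])
        with pytest.raises(np.linalg.LinAlgError):
            uniqueness_scores(_cov(df))


class TestStepwise:
    def test_single_admissible_candidate_equals_plain_ols(self):
        rng = np.random.default_rng(0)
        x = pd.DataFrame({"x0": rng.normal(size=30)}, index=[f"r{j}" for j in range(30)])
        y = pd.Series(2 * x["x0"].to_numpy() + 0.1 * rng.normal(size=30), index=x.index)
        selected, fit = stepwise_ols(y, x)
        assert selected == ["x0"]
        import statsmodels.api as sm

        direct = sm.OLS(y.to_numpy(), sm.add_constant(x)).fit()
        assert fit.params["x0"] == pytest.approx(direct.params["x0"], rel=1e-12)

    def test_true_predictor_found_among_noise(self):
        found = 0
        n_rep = 50
        for s in range(n_rep):
            rng = np.random.default_rng(s)
            x = pd.DataFrame(
                rng.normal(size=(47, 5)),
                columns=[f"x{i}" for i in range(5)],
                index=[f"r{j}" for j in range(47)],
            )
            y = pd.Series(
                1.5 * x["x2"].to_numpy() + rng.normal(size=47), index=x.index
            )
            selected, _ = stepwise_ols(y, x)
            found += "x2" in selected
        assert found / n_rep >= 0.95

    def test_pure_noise_often_intercept_only(self):
        empty = 0
        n_rep = 50
        for s in range(n_rep):
            rng = np.random.default_rng(1000 + s)
            x = pd.DataFrame(
                rng.normal(size=(47, 4)),
                columns=[f"x{i}" for i in range(4)],
                index=[f"r{j}" for j in range(47)],
            )
            y = pd.Series(rng.normal(size=47), index=x.index)
            selected, _ = stepwise_ols(y, x)
            empty += not selected
        # roughly (1 - alpha)^k of replicates keep nothing
        assert empty / n_rep > 0.6

    def test_forced_covariate_survives(self):
        rng = np.random.default_rng(3)
        x = pd.DataFrame(
            rng.normal(size=(40, 3)), columns=["a", "b", "c"],
            index=[f"r{j}" for j in range(40)],
        )
        y = pd.Series(rng.normal(size=40), index=x.index)
        selected, _ = stepwise_ols(y, x, forced=["b"])
        assert "b" in selected


class TestSpatialLag:
    def test_zero_adjacency_equals_ols(self):
        x, y, _ = make_regression_fixture(12, [1.0, -0.5], 0.0, np.zeros((12, 12)), seed=0)
        fit = fit_spatial_lag(y, x.table, np.zeros((12, 12)))
        assert fit.rho == 0.0
        assert np.allclose(
            fit.params.to_numpy(), fit.ols.params.to_numpy(), atol=1e-8
        )

    def test_profile_likelihood_maximized_at_rho_hat(self):
        w = grid_adjacency(25).row_standardized()
        x, y, _ = make_regression_fixture(25, [1.0], 0.3, w, seed=1)
        fit = fit_spatial_lag(y, x.table, w)
        from kdepi.spatial_regression import _loglik_parts
        import statsmodels.api as sm

        xv = sm.add_constant(x.table, has_constant="add").to_numpy()
        yv = y.to_numpy()
        eigs = np.linalg.eigvalsh(w @ np.eye(25)) if False else np.real(np.linalg.eigvals(w))
        uy = w @ yv
        ll = lambda r: _loglik_parts(r, yv, uy, xv, eigs)[0]
        assert ll(fit.rho) >= ll(fit.rho + 0.02) and ll(fit.rho) >= ll(fit.rho - 0.02)
        assert fit.loglik >= fit.loglik_at_zero

    def test_rho_inside_invertibility_interval(self):
        w = grid_adjacency(30)  # raw binary adjacency
        x, y, _ = make_regression_fixture(30, [2.0], 0.1, w.matrix, seed=2)
        fit = fit_spatial_lag(y, x.table, w)
        lo, hi = fit.rho_interval
        assert lo < fit.rho < hi

    def test_recovery_quick(self):
        """Short parameter-recovery check (full experiment in acceptance)."""
        w = grid_adjacency(47).row_standardized()
        rhos = []
        for s in range(25):
            x, y, _ = make_regression_fixture(47, [2.0, 1.0], 0.4, w, seed=s)
            rhos.append(fit_spatial_lag(y, x.table, w).rho)
        assert abs(np.mean(rhos) - 0.4) < 0.15
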