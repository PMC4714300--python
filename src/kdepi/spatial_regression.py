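"""Covariate screening, collinearity triage, stepwise OLS and the spatial-lag model.

The geographical analysis proceeds in four stages:

1. ``screen_covariates`` — Spearman rank correlation of each regional
   covariate with the (adjusted) mean patient age of every disease; a
   covariate is retained only if significant for all diseases.
2. ``uniqueness_scores`` — factor-analysis uniqueness (1 - communality) by
   iterated principal-axis factoring; low uniqueness flags a covariate as
   largely a linear combination of the others (multicollinearity risk).
3. ``stepwise_ols`` — forward addition / backward elimination multivariate
   linear regression with deterministic tie-breaking.
4. ``fit_spatial_lag`` — maximum likelihood for the simultaneous
   autoregressive (spatial-lag) model

       Y = rho U Y + X beta + e,   e ~ N(0, sigma^2 I)

   with the log-determinant ln|I - rho U| computed from the eigenvalues of
   the adjacency matrix U and rho profiled out by bounded scalar
   optimization inside the invertibility interval.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .data_model import AdjacencyMatrix, CovariateTable

__all__ = [
    "ScreeningReport",
    "SpatialLagFit",
    "screen_covariates",
    "uniqueness_scores",
    "stepwise_ols",
    "fit_spatial_lag",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# 1. Rank-correlation screening
# ---------------------------------------------------------------------------

@dataclass
class ScreeningReport:
    table: pd.DataFrame  # index covariate, columns MultiIndex (disease, rho|p)
    retained: list[str]
    alpha: float
    reasons: dict = field(default_factory=dict)

    def rho(self, covariate, disease) -> float:
        return float(self.table.loc[covariate, (disease, "rho")])


def screen_covariates(
    mean_ages: pd.DataFrame, covariates: CovariateTable, alpha: float = 0.05
) -> ScreeningReport:
    """Spearman screening: retain covariates significant for *every* disease.

    ``mean_ages`` has one row per region and one column per disease (the
    regional adjusted mean patient ages).  Constant covariates have undefined
    rank correlation and are reported as not retained with a reason.
    """
    regions = [r for r in mean_ages.index if r in covariates.table.index]
    if len(regions) < 5:
        raise ValueError("need at least 5 regions with both mean ages and covariates")
    ages = mean_ages.loc[regions]
    xs = covariates.table.loc[regions]

    rows, retained, reasons = {}, [], {}
    for cov in xs.columns:
        x = xs[cov].to_numpy(dtype=float)
        rec = {}
        if np.ptp(x) == 0:
            for d in ages.columns:
                rec[(d, "rho")] = np.nan
                rec[(d, "p")] = np.nan
            reasons[cov] = "constant covariate: rank correlation undefined"
            rows[cov] = rec
            continue
        ok = True
        for d in ages.columns:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rho, p = stats.spearmanr(x, ages[d].to_numpy(dtype=float))
            rec[(d, "rho")] = rho
            rec[(d, "p")] = p
            if not (np.isfinite(p) and p < alpha):
                ok = False
        rows[cov] = rec
        if ok:
            retained.append(cov)
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.columns = pd.MultiIndex.from_tuples(table.columns)
    return ScreeningReport(table=table, retained=retained, alpha=alpha, reasons=reasons)


# ---------------------------------------------------------------------------
# 2. Factor-analysis uniqueness
# ---------------------------------------------------------------------------

def uniqueness_scores(
    covariates: CovariateTable,
    subset=None,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> pd.Series:
    """Per-covariate uniqueness (1 - communality) from principal-axis factoring.

    The factor count follows the eigenvalue > 1 rule on the correlation
    matrix; communalities are initialized at squared multiple correlations
    and iterated to convergence.  A covariate with small uniqueness is
    largely explained by a linear combination of the others and is a
    multicollinearity risk.
    """
    cols = list(subset) if subset is not None else covariates.names
    if len(cols) < 2:
        raise ValueError("need at least 2 covariates for factor analysis")
    x = covariates.table[cols].to_numpy(dtype=float)
    if x.shape[0] <= x.shape[1]:
        raise ValueError("need more regions than covariates")
    r = np.corrcoef(x, rowvar=False)
    cond = np.linalg.cond(r)
    if cond > 1e10:
        raise np.linalg.LinAlgError(
            "correlation matrix is singular; exclude duplicated covariates first"
        )
    n_factors = max(1, int((np.linalg.eigvalsh(r) > 1.0).sum()))
    # initial communalities: squared multiple correlations
    rinv = np.linalg.inv(r)
    h2 = 1.0 - 1.0 / np.diag(rinv)
    for _ in range(max_iter):
        rr = r.copy()
        np.fill_diagonal(rr, h2)
        vals, vecs = np.linalg.eigh(rr)
        order = np.argsort(vals)[::-1][:n_factors]
        lam = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
        new_h2 = np.clip((lam**2).sum(axis=1), 0.0, 1.0)
        if np.max(np.abs(new_h2 - h2)) < tol:
            h2 = new_h2
            break
        h2 = new_h2
    return pd.Series(1.0 - h2, index=cols, name="uniqueness")


# ---------------------------------------------------------------------------
# 3. Stepwise OLS
# ---------------------------------------------------------------------------

def _ols(y: np.ndarray, x: pd.DataFrame):
    return sm.OLS(y, sm.add_constant(x, has_constant="add")).fit()


def stepwise_ols(
    y: pd.Series,
    x: pd.DataFrame,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    forced=(),
):
    """Forward-addition / backward-elimination variable selection.

    At each forward step the candidate with the smallest coefficient P below
    ``p_enter`` is added (ties broken by smaller P then covariate name); a
    backward pass then drops any selected non-forced variable whose P exceeds
    ``p_remove``.  Iterates to a fixed point.  Returns ``(selected, fit)``;
    with no admissible variable the intercept-only model is returned and
    flagged in the log.
    """
    if x.shape[0] <= x.shape[1] + 2:
        raise ValueError("need n regions > candidate count + 2")
    yv = y.to_numpy(dtype=float)
    selected = list(forced)
    candidates = [c for c in x.columns if c not in selected]
    while True:
        changed = False
        best = None
        for c in sorted(candidates):
            fit = _ols(yv, x[selected + [c]])
            p = fit.pvalues[c]
            if np.isfinite(p) and p < p_enter:
                if best is None or (p, c) < best[:2]:
                    best = (p, c)
        if best is not None:
            selected.append(best[1])
            candidates.remove(best[1])
            changed = True
        # backward elimination
        while True:
            if not selected:
                break
            fit = _ols(yv, x[selected])
            removable = {
                c: fit.pvalues[c]
                for c in selected
                if c not in forced and fit.pvalues[c] > p_remove
            }
            if not removable:
                break
            worst = max(sorted(removable), key=lambda c: (removable[c], c))
            selected.remove(worst)
            candidates.append(worst)
            changed = True
        if not changed:
            break
    if not selected:
        log.warning("stepwise selection retained no variables; intercept-only model")
        return [], _ols(yv, x[[]])
    return selected, _ols(yv, x[selected])


# ---------------------------------------------------------------------------
# 4. Spatial-lag (simultaneous autoregressive) model
# ---------------------------------------------------------------------------

@dataclass
class SpatialLagFit:
    rho: float
    params: pd.Series           # intercept + coefficients
    bse: pd.Series
    pvalues: pd.Series
    rho_se: float
    rho_pvalue: float
    sigma2: float
    loglik: float
    rho_interval: tuple[float, float]
    converged: bool
    ols: object                 # companion statsmodels OLS fit
    loglik_at_zero: float

    def summary_frame(self) -> pd.DataFrame:
        rows = [("rho", self.rho, self.rho_se, self.rho_pvalue)]
        rows += [
            (k, self.params[k], self.bse[k], self.pvalues[k]) for k in self.params.index
        ]
        return pd.DataFrame(rows, columns=["term", "estimate", "se", "p"])


def _loglik_parts(rho, y, uy, x, eigs):
    n = len(y)
    ay = y - rho * uy
    beta, *_ = np.linalg.lstsq(x, ay, rcond=None)
    resid = ay - x @ beta
    sigma2 = float(resid @ resid) / n
    logdet = float(np.sum(np.log(1.0 - rho * eigs)))
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet
    return ll, beta, sigma2


def fit_spatial_lag(
    y: pd.Series,
    x: pd.DataFrame,
    adjacency: AdjacencyMatrix | np.ndarray,
    row_standardize: bool = False,
) -> SpatialLagFit:
    """Maximum-likelihood fit of Y = rho U Y + X beta + e.

    ``adjacency`` may be an :class:`AdjacencyMatrix` (its rows are matched to
    the index of ``y``) or a raw weight matrix already in the right order.
    The default uses the raw binary contiguity matrix; ``row_standardize``
    rescales rows to sum to one.  An all-zero adjacency degenerates to OLS
    with rho fixed at 0 (warned).
    """
    regions = list(y.index)
    if isinstance(adjacency, AdjacencyMatrix):
        u = adjacency.reorder(regions) if list(adjacency.regions) != regions else adjacency.matrix
        if row_standardize:
            deg = u.sum(axis=1, keepdims=True)
            u = np.divide(u, deg, where=deg > 0, out=u.copy())
    else:
        u = np.asarray(adjacency, dtype=float)
    n = len(regions)
    if u.shape != (n, n):
        raise ValueError("adjacency shape does not match the response vector")
    if n <= x.shape[1] + 2:
        raise ValueError("need n regions > covariates + 2")

    yv = y.to_numpy(dtype=float)
    xm = sm.add_constant(x, has_constant="add")
    xv = xm.to_numpy(dtype=float)
    ols_fit = sm.OLS(yv, xm).fit()

    if not u.any():
        log.warning("all-zero adjacency: spatial-lag model reduces to OLS, rho=0")
        ll0 = float(ols_fit.llf)
        return SpatialLagFit(
            rho=0.0,
            params=pd.Series(ols_fit.params.to_numpy(), index=xm.columns),
            bse=pd.Series(ols_fit.bse.to_numpy(), index=xm.columns),
            pvalues=pd.Series(ols_fit.pvalues.to_numpy(), index=xm.columns),
            rho_se=np.nan,
            rho_pvalue=np.nan,
            sigma2=float(ols_fit.mse_resid * ols_fit.df_resid / n),
            loglik=ll0,
            rho_interval=(-np.inf, np.inf),
            converged=True,
            ols=ols_fit,
            loglik_at_zero=ll0,
        )

    eigs = np.linalg.eigvals(u)
    eigs = np.real(eigs)  # symmetric (possibly row-standardized) => real spectrum
    lo = 1.0 / eigs.min() if eigs.min() < 0 else -np.inf
    hi = 1.0 / eigs.max() if eigs.max() > 0 else np.inf
    eps = 1e-6
    lo_b = lo + eps * (hi - lo) if np.isfinite(lo) else -5.0
    hi_b = hi - eps * (hi - lo) if np.isfinite(hi) else 5.0

    uy = u @ yv

    def neg_ll(rho):
        return -_loglik_parts(rho, yv, uy, xv, eigs)[0]

    res = optimize.minimize_scalar(neg_ll, bounds=(lo_b, hi_b), method="bounded")
    rho_hat = float(res.x)
    span = hi_b - lo_b
    converged = res.success and (rho_hat - lo_b) > 1e-4 * span and (hi_b - rho_hat) > 1e-4 * span
    if not converged:
        raise RuntimeError(
            f"spatial-lag ML did not converge in the interior of ({lo:.4g}, {hi:.4g})"
        )
    ll_hat, beta_hat, sigma2_hat = _loglik_parts(rho_hat, yv, uy, xv, eigs)
    ll_zero, *_ = _loglik_parts(0.0, yv, uy, xv, eigs)

    # asymptotic covariance from the numerical Hessian of the full likelihood
    k = xv.shape[1]

    def full_ll(theta):
        beta, rho, logs2 = theta[:k], theta[k], theta[k + 1]
        s2 = np.exp(logs2)
        if not (lo_b < rho < hi_b):
            return -np.inf
        resid = yv - rho * uy - xv @ beta
        logdet = np.sum(np.log(1.0 - rho * eigs))
        return -0.5 * n * np.log(2 * np.pi * s2) + logdet - 0.5 * resid @ resid / s2

    theta = np.concatenate([beta_hat, [rho_hat, np.log(sigma2_hat)]])
    hess = _num_hessian(full_ll, theta)
    try:
        cov = np.linalg.inv(-hess)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(k + 2, np.nan)
    beta_se = se[:k]
    rho_se = se[k]
    z_beta = np.divide(beta_hat, beta_se, out=np.full(k, np.nan), where=beta_se > 0)
    p_beta = 2.0 * stats.norm.sf(np.abs(z_beta))
    z_rho = rho_hat / rho_se if rho_se > 0 else np.nan
    p_rho = 2.0 * stats.norm.sf(abs(z_rho)) if np.isfinite(z_rho) else np.nan

    return SpatialLagFit(
        rho=rho_hat,
        params=pd.Series(beta_hat, index=xm.columns),
        bse=pd.Series(beta_se, index=xm.columns),
        pvalues=pd.Series(p_beta, index=xm.columns),
        rho_se=float(rho_se),
        rho_pvalue=float(p_rho),
        sigma2=sigma2_hat,
        loglik=float(ll_hat),
        rho_interval=(float(lo), float(hi)),
        converged=True,
        ols=ols_fit,
        loglik_at_zero=float(ll_zero),
    )


def _num_hessian(f, x0, h: float = 1e-5):
    p = len(x0)
    hess = np.zeros((p, p))
    f0 = f(x0)
    steps = h * np.maximum(np.abs(x0), 1.0)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = steps[i]
            ej = np.zeros(p); ej[j] = steps[j]
            fpp = f(x0 + ei + ej)
            fpm = f(x0 + ei - ej)
            fmp = f(x0 - ei + ej)
            fmm = f(x0 - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    return hess
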