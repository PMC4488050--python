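"""Goodness-of-fit statistics and the pass/fail assessment rule.

The chi-square fit statistic compares the fitted model's likelihood with
the saturated (unrestricted mean/covariance) model over the same variables
and rows; RMSEA, CFI and SRMR are derived summaries.  A model is assessed
as fitting well when the chi-square p-value is above 5 % (strictly), RMSEA
below 5 %, CFI above 0.95 and SRMR below 0.08 — each criterion is also
reported separately.

Pinned formula conventions (unit-tested against hand calculations):
RMSEA uses an (n - 1) denominator; CFI's denominator takes the max with
the model's own (T - df); SRMR averages squared standardized residuals
over the lower triangle including the diagonal and excludes means.  With
missing data the "sample" moments are the FIML-estimated saturated moments
(EM), so the complete and incomplete code paths agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
from scipy import stats

from .data import as_frame
from .estimation import FitResult, mvn_pattern_loglik, pattern_statistics

__all__ = [
    "FitIndices",
    "saturated_moments",
    "saturated_loglik",
    "independence_loglik",
    "chi_square",
    "rmsea",
    "cfi",
    "srmr",
    "compute_fit_indices",
    "assess",
]


@dataclass
class FitIndices:
    chi2: float
    df: int
    p: float
    rmsea: float
    cfi: float
    srmr: float
    baseline_chi2: float
    baseline_df: int
    n: int

    def summary(self) -> str:
        """One-line footnote in the conventional reporting style."""
        p = "<= 0.01" if self.p <= 0.01 else f"{self.p:.2f}"
        r = "<= 0.01" if self.rmsea <= 0.01 else f"{self.rmsea:.2f}"
        return (f"chi2-test P: {p}, RMSEA: {r}, "
                f"CFI: {self.cfi:.2f}, SRMR: {self.srmr:.2f}")


# --------------------------------------------------------------------- #
# saturated and independence models
# --------------------------------------------------------------------- #
def saturated_moments(data, variables, tol=1e-10, max_iter=1000):
    """FIML estimates of the unrestricted mean/covariance model.

    Closed form (ML denominators) on complete data; EM otherwise.

    Returns (mu, sigma, loglik, n_used).
    """
    patterns, n_used, _ = pattern_statistics(data, variables)
    p = len(variables)
    if n_used <= p:
        raise ValueError(
            f"need more than {p} rows for a positive-definite covariance")

    complete = len(patterns) == 1 and len(patterns[0][0]) == p
    X = as_frame(data).loc[:, list(variables)].to_numpy(dtype=float)
    if complete:
        oi, n_g, mean_g, scatter_g = patterns[0]
        mu = mean_g.copy()
        sigma = scatter_g / n_g
        ll = mvn_pattern_loglik(mu, sigma, patterns)
        return mu, sigma, ll, n_used

    # EM initialisation from available-case moments
    mu = np.array([np.nanmean(X[:, j]) for j in range(p)])
    sigma = np.zeros((p, p))
    for i in range(p):
        for j in range(i, p):
            ok = np.isfinite(X[:, i]) & np.isfinite(X[:, j])
            if ok.sum() > 1:
                sigma[i, j] = sigma[j, i] = np.cov(X[ok, i], X[ok, j], bias=True)[0, 1]
    w, V = np.linalg.eigh(sigma)
    floor = 1e-6 * max(w.max(), 1.0)
    sigma = (V * np.maximum(w, floor)) @ V.T

    ll_old = -np.inf
    for _ in range(max_iter):
        t1 = np.zeros(p)
        t2 = np.zeros((p, p))
        n_tot = 0
        for oi, n_g, mean_g, scatter_g in patterns:
            mi = np.setdiff1d(np.arange(p), oi)
            n_tot += n_g
            s_oo = sigma[np.ix_(oi, oi)]
            c = sla.cho_factor(s_oo, lower=True, check_finite=False)
            # observed-part contribution
            exx_oo = scatter_g + n_g * np.outer(mean_g, mean_g)
            t1[oi] += n_g * mean_g
            t2[np.ix_(oi, oi)] += exx_oo
            if mi.size:
                s_mo = sigma[np.ix_(mi, oi)]
                beta = sla.cho_solve(c, s_mo.T, check_finite=False).T  # mi x oi
                cond_cov = sigma[np.ix_(mi, mi)] - beta @ s_mo.T
                # conditional means: mu_m + beta (x_o - mu_o), via pattern stats
                dbar = mean_g - mu[oi]
                em_mean = mu[mi] + beta @ dbar
                t1[mi] += n_g * em_mean
                # E sum x_m x_o' = n*em_mean*mean_o' + beta * scatter_oo
                cross = n_g * np.outer(em_mean, mean_g) + beta @ scatter_g
                t2[np.ix_(mi, oi)] += cross
                t2[np.ix_(oi, mi)] += cross.T
                # E sum x_m x_m'
                mm = (n_g * (cond_cov + np.outer(em_mean, em_mean))
                      + beta @ scatter_g @ beta.T)
                t2[np.ix_(mi, mi)] += mm
        mu = t1 / n_tot
        sigma = t2 / n_tot - np.outer(mu, mu)
        sigma = (sigma + sigma.T) / 2
        ll = mvn_pattern_loglik(mu, sigma, patterns)
        if np.isfinite(ll) and abs(ll - ll_old) <= tol * max(1.0, abs(ll)):
            break
        ll_old = ll
    return mu, sigma, ll, n_used


def saturated_loglik(data, variables) -> float:
    """FIML-maximized log-likelihood of the unrestricted moment model."""
    return saturated_moments(data, variables)[2]


def independence_loglik(data, variables) -> float:
    """Maximized log-likelihood of the independence (baseline) model.

    Variables are mutually independent normals with free means and
    variances, so the FIML maximum factorizes into per-column univariate
    MLEs over each column's observed cells.
    """
    # restrict to the rows the other models use (>= 1 modeled cell observed)
    df = as_frame(data).loc[:, list(variables)]
    keep = np.isfinite(df.to_numpy(dtype=float)).any(axis=1)
    X = df.to_numpy(dtype=float)[keep]
    ll = 0.0
    for j in range(X.shape[1]):
        x = X[:, j]
        x = x[np.isfinite(x)]
        n_j = x.size
        if n_j < 2:
            raise ValueError(f"column {variables[j]!r} has fewer than 2 observed cells")
        v = float(x.var())
        ll += -0.5 * n_j * (np.log(2 * np.pi) + np.log(v) + 1.0)
    return ll


# --------------------------------------------------------------------- #
# index formulas
# --------------------------------------------------------------------- #
def chi_square(fit: FitResult, sat_ll: float):
    """Likelihood-ratio fit statistic against the saturated model."""
    raw = 2.0 * (sat_ll - fit.loglik)
    if raw < -1e-6 * max(1.0, abs(sat_ll)):
        import warnings
        warnings.warn(f"fit log-likelihood exceeds the saturated model by "
                      f"{-raw:.3g}: likely convergence failure")
    T = max(0.0, raw)
    df = fit.spec.model_df()
    p = float(stats.chi2.sf(T, df)) if df > 0 else 1.0
    return {"T": T, "df": df, "p": p}


def rmsea(T: float, df: int, n: int) -> float:
    """Root mean squared error of approximation: lack of fit per df.

    sqrt(max(0, (T - df) / (df (n - 1)))); undefined (NaN) at df = 0.
    """
    if df < 1:
        return np.nan
    if n < 2:
        raise ValueError("rmsea requires n >= 2")
    return float(np.sqrt(max(0.0, (T - df) / (df * (n - 1)))))


def cfi(T: float, df: int, T0: float, df0: int) -> float:
    """Bentler comparative fit index against the independence baseline."""
    if df0 <= df:
        raise ValueError(f"baseline df ({df0}) must exceed model df ({df})")
    num = max(T - df, 0.0)
    den = max(T0 - df0, T - df, 0.0)
    if den == 0.0:
        return 1.0
    return 1.0 - num / den


def srmr(sample_cov, implied_cov) -> float:
    """Standardized root mean square residual over the lower triangle + diagonal."""
    s = np.asarray(sample_cov, dtype=float)
    m = np.asarray(implied_cov, dtype=float)
    if s.shape != m.shape or s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("sample and implied covariance shapes differ")
    d = np.sqrt(np.diag(s))
    if np.any(~(d > 0)):
        raise ValueError("sample covariance has nonpositive diagonal entries")
    resid = (s - m) / np.outer(d, d)
    iu = np.tril_indices(s.shape[0])
    return float(np.sqrt(np.mean(resid[iu] ** 2)))


def compute_fit_indices(fit: FitResult, data) -> FitIndices:
    """Assemble chi-square, RMSEA, CFI and SRMR for a converged fit."""
    variables = fit.spec.observed_names
    mu_s, sigma_s, sat_ll, n_used = saturated_moments(data, variables)
    cs = chi_square(fit, sat_ll)
    ind_ll = independence_loglik(data, variables)
    p = len(variables)
    T0 = max(0.0, 2.0 * (sat_ll - ind_ll))
    df0 = p * (p + 3) // 2 - 2 * p
    mom = fit.spec.implied_moments(fit.theta)
    order = [variables.index(nm) for nm in mom.names]
    return FitIndices(
        chi2=cs["T"], df=cs["df"], p=cs["p"],
        rmsea=rmsea(cs["T"], cs["df"], n_used),
        cfi=cfi(cs["T"], cs["df"], T0, df0),
        srmr=srmr(sigma_s[np.ix_(order, order)], mom.sigma),
        baseline_chi2=T0, baseline_df=df0, n=n_used)


def assess(indices: FitIndices):
    """Apply the four pass/fail thresholds; report each criterion and the conjunction.

    The chi-square criterion requires p strictly above 0.05; RMSEA strictly
    below 0.05, CFI strictly above 0.95, SRMR strictly below 0.08.
    """
    criteria = {
        "chi2_p_above_0.05": bool(indices.p > 0.05),
        "rmsea_below_0.05": bool(indices.rmsea < 0.05) if np.isfinite(indices.rmsea) else False,
        "cfi_above_0.95": bool(indices.cfi > 0.95),
        "srmr_below_0.08": bool(indices.srmr < 0.08),
    }
    return {"pass": all(criteria.values()), "criteria": criteria}
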