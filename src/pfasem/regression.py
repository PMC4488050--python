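"""Covariate-adjusted log2 linear regressions and the spline linearity check.

These are the standard analyses the SEMs are compared against: ordinary
least squares of a log2 antibody concentration on a single log2 PFAS
concentration plus covariates (listwise deletion), and a dose-response
linearity check in which the exposure enters through a natural cubic
regression-spline basis with three interior knots.

Because a single error-prone exposure measurement is used directly, the
OLS slope is attenuated toward zero by the indicator's reliability — the
comparison that motivates the latent-variable models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import prepare_model_frame
from .effects import EffectEstimate, percent_change_per_doubling

__all__ = [
    "RegressionResult",
    "SplineCheck",
    "fit_naive_regression",
    "spline_linearity_check",
    "natural_cubic_basis",
]


@dataclass
class RegressionResult:
    coef_table: pd.DataFrame
    effect: EffectEstimate
    n_used: int
    n_excluded_nonpositive: int
    r2: float


@dataclass
class SplineCheck:
    """Spline-vs-linear comparison for one exposure-outcome pair."""

    knots: np.ndarray          # interior knots (log2 exposure scale)
    boundary: tuple            # boundary knots
    loglik_linear: float
    loglik_spline: float
    f_stat: float
    f_df: tuple
    p_nonlinearity: float
    curve: pd.DataFrame        # grid, fit, lower, upper (log2 outcome scale)


def _design(df, exposure_cols, covariates):
    X = pd.concat([df[list(exposure_cols)], df[list(covariates)]], axis=1)
    return sm.add_constant(X, has_constant="add")


def fit_naive_regression(data, exposure, outcome, covariates,
                         level: float = 0.95) -> RegressionResult:
    """OLS of log2 outcome on log2 exposure plus covariates (listwise).

    Zero or negative concentrations cannot be log-transformed; such cells
    are flagged, counted and excluded.
    """
    df, n_bad = prepare_model_frame(data, [exposure, outcome], covariates)
    cols = [outcome, exposure, *covariates]
    work = df[cols].dropna()
    k = len(covariates) + 2
    if len(work) < k + 2:
        raise ValueError(
            f"only {len(work)} complete-case rows for {k} parameters")
    X = _design(work, [exposure], covariates)
    res = sm.OLS(work[outcome], X).fit()
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    table = pd.DataFrame({
        "label": res.params.index,
        "estimate": res.params.to_numpy(),
        "se": res.bse.to_numpy(),
        "t": res.tvalues.to_numpy(),
        "p": res.pvalues.to_numpy(),
    })
    eff = percent_change_per_doubling(float(res.params[exposure]),
                                      float(res.bse[exposure]), level)
    return RegressionResult(coef_table=table, effect=eff,
                            n_used=int(res.nobs),
                            n_excluded_nonpositive=n_bad,
                            r2=float(res.rsquared))


def natural_cubic_basis(x, interior_knots, boundary):
    """Natural cubic regression-spline basis (linear beyond the boundary).

    Truncated-power construction with the natural constraints absorbed:
    for knots xi_1 < ... < xi_K (interior plus the two boundary knots) the
    basis is x together with K - 2 curvature terms d_k(x) - d_{K-1}(x),
    d_k(x) = [(x - xi_k)_+^3 - (x - xi_K)_+^3] / (xi_K - xi_k).

    Returns an (n, K - 1) array whose first column is x itself.
    """
    knots = np.sort(np.concatenate([[boundary[0]], np.asarray(interior_knots,
                                                              dtype=float),
                                    [boundary[1]]]))
    if np.unique(knots).size != knots.size:
        raise ValueError("knots must be distinct")
    x = np.asarray(x, dtype=float)
    K = knots.size

    def d(k):
        return (np.clip(x - knots[k], 0, None) ** 3
                - np.clip(x - knots[K - 1], 0, None) ** 3) / (knots[K - 1] - knots[k])

    cols = [x] + [d(k) - d(K - 2) for k in range(K - 2)]
    return np.column_stack(cols)


def spline_linearity_check(data, exposure, outcome, covariates,
                           n_grid: int = 100, level: float = 0.95) -> SplineCheck:
    """Test linearity of the dose-response with a 3-knot natural cubic spline.

    Interior knots sit at the 25th/50th/75th percentiles of the observed
    log2 exposure; boundary knots at its range.  The spline model nests the
    linear model, so the added curvature terms are tested with an F-test.
    Also returns the fitted dose-response curve on a grid with a pointwise
    confidence band, evaluated at covariate means.
    """
    df, _ = prepare_model_frame(data, [exposure, outcome], covariates)
    cols = [outcome, exposure, *covariates]
    work = df[cols].dropna()
    xv = work[exposure].to_numpy()
    interior = np.quantile(xv, [0.25, 0.50, 0.75])
    boundary = (xv.min(), xv.max())
    if np.unique(np.concatenate([interior, boundary])).size < 5:
        raise ValueError("too few distinct exposure values to place 3 knots")

    basis = natural_cubic_basis(xv, interior, boundary)
    names = [exposure] + [f"{exposure}_ns{j}" for j in range(1, basis.shape[1])]
    spl = work.copy()
    for j, nm in enumerate(names):
        spl[nm] = basis[:, j]

    X_lin = _design(spl, [exposure], covariates)
    X_spl = _design(spl, names, covariates)
    res_lin = sm.OLS(spl[outcome], X_lin).fit()
    res_spl = sm.OLS(spl[outcome], X_spl).fit()
    f_stat, f_p, f_df = res_spl.compare_f_test(res_lin)

    grid = np.linspace(boundary[0], boundary[1], n_grid)
    gb = natural_cubic_basis(grid, interior, boundary)
    gdf = pd.DataFrame(gb, columns=names)
    for c in covariates:
        gdf[c] = float(work[c].mean())
    Xg = sm.add_constant(gdf[[*names, *covariates]], has_constant="add")
    pred = res_spl.get_prediction(Xg).summary_frame(alpha=1 - level)
    curve = pd.DataFrame({
        "exposure": grid,
        "fit": pred["mean"].to_numpy(),
        "lower": pred["mean_ci_lower"].to_numpy(),
        "upper": pred["mean_ci_upper"].to_numpy(),
    })
    return SplineCheck(knots=interior, boundary=boundary,
                       loglik_linear=float(res_lin.llf),
                       loglik_spline=float(res_spl.llf),
                       f_stat=float(f_stat),
                       f_df=(int(f_df), int(res_spl.df_resid)),
                       p_nonlinearity=float(f_p), curve=curve)
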