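"""scikit-learn-style estimator front end for FIML SEM fitting."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .data import as_frame
from .estimation import FitOptions, fiml_loglik, fit_sem
from .spec import SEMSpec

__all__ = ["SEMEstimator"]


class SEMEstimator(BaseEstimator):
    """Fit a declarative linear Gaussian SEM by full-information ML.

    Composes with scikit-learn tooling: hyperparameters are plain
    constructor arguments (``get_params``/``set_params`` work), fitting
    populates trailing-underscore attributes, and ``score`` returns the
    average per-row FIML log-likelihood (higher is better).

    Parameters
    ----------
    spec : SEMSpec
        The model to fit.  Column names in ``X`` must cover the spec's
        observed variables; cells may be missing (NaN) under MAR.
    tol, gtol, max_iter : float, float, int
        Convergence tolerances and iteration cap of the quasi-Newton fit.
    restarts : int
        Seeded random restarts around the moment-based start values.
    random_state : int
        Seed for the restart perturbations (ignored when ``restarts=0``).

    Attributes
    ----------
    params_ : pandas.Series
        Free-parameter estimates, labelled.
    loglik_ : float
        Maximized FIML log-likelihood.
    converged_ : bool
    n_used_, n_dropped_ : int
        Rows entering the likelihood / rows missing all modeled variables.
    result_ : FitResult
        The full fit object (standard errors, parameter covariance, spec).

    Examples
    --------
    >>> est = SEMEstimator(spec).fit(frame)
    >>> est.params_["beta_diphtheria"]
    """

    def __init__(self, spec: SEMSpec | None = None, *, tol: float = 1e-8,
                 gtol: float = 1e-5, max_iter: int = 5000, restarts: int = 0,
                 random_state: int = 0, start: str = "moments"):
        self.spec = spec
        self.tol = tol
        self.gtol = gtol
        self.max_iter = max_iter
        self.restarts = restarts
        self.random_state = random_state
        self.start = start

    def _options(self) -> FitOptions:
        return FitOptions(tol=self.tol, gtol=self.gtol, max_iter=self.max_iter,
                          restarts=self.restarts,
                          restart_seed=self.random_state, start=self.start)

    def _validate_X(self, X) -> pd.DataFrame:
        if self.spec is None:
            raise ValueError("SEMEstimator requires a spec")
        df = as_frame(X)
        missing = [c for c in self.spec.observed_names if c not in df.columns]
        if missing:
            raise ValueError(f"X lacks modeled column(s): {missing}")
        return df

    def fit(self, X, y=None):
        df = self._validate_X(X)
        self.result_ = fit_sem(self.spec, df, self._options())
        self.params_ = self.result_.estimates
        self.loglik_ = self.result_.loglik
        self.converged_ = self.result_.converged
        self.n_used_ = self.result_.n_used
        self.n_dropped_ = self.result_.n_dropped
        self.n_features_in_ = len(self.spec.observed_names)
        return self

    def score(self, X, y=None) -> float:
        """Average per-row FIML log-likelihood of X under the fitted model."""
        if not hasattr(self, "result_"):
            raise ValueError("estimator is not fitted")
        df = self._validate_X(X)
        ll = fiml_loglik(self.spec, self.result_.theta, df)
        n = int(np.isfinite(
            df[self.spec.observed_names].to_numpy(float)).any(axis=1).sum())
        return ll / max(n, 1)

    def se_(self) -> pd.Series:
        return self.result_.se()

    def param_table(self) -> pd.DataFrame:
        return self.result_.param_table()
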