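"""Full-information maximum likelihood estimation of linear Gaussian SEMs.

Each child contributes the multivariate-normal log-density of exactly the
variables they were measured on, with the matching sub-mean and
sub-covariance of the model-implied moments — the standard FIML treatment
of missing data, valid when missingness is at random (MAR).

Rows are grouped by missingness pattern and reduced to per-pattern
sufficient statistics (count, mean, scatter), so one likelihood evaluation
costs O(patterns x p^3) regardless of the number of rows.  Optimization is
quasi-Newton (L-BFGS-B) on an unconstrained scale with variances
log-parameterized to enforce positivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.optimize as sopt
from scipy import stats

from .data import as_frame
from .spec import SEMSpec

__all__ = [
    "FitOptions",
    "FitResult",
    "EstimationError",
    "pattern_statistics",
    "fiml_loglik",
    "fit_sem",
    "vcov_observed_information",
    "likelihood_ratio_test",
]

_LOG2PI = np.log(2.0 * np.pi)
_PENALTY = 1e12


class EstimationError(RuntimeError):
    """Estimation could not produce a usable result."""


@dataclass
class FitOptions:
    """Optimizer settings.

    ``tol`` is the relative log-likelihood convergence tolerance, ``gtol``
    the gradient max-norm at which a solution is declared converged.
    ``restarts`` adds seeded random perturbations of the start values;
    with ``restarts=0`` the fit is fully deterministic with no RNG at all.
    """

    tol: float = 1e-8
    gtol: float = 1e-5
    max_iter: int = 5000
    restarts: int = 0
    restart_seed: int = 0
    restart_scale: float = 0.25
    start: str = "moments"  # "moments" (refine from data) or "spec" (as given)

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class FitResult:
    """A fitted SEM: estimates, log-likelihood and convergence diagnostics."""

    spec: SEMSpec
    theta: np.ndarray
    labels: list
    loglik: float
    converged: bool
    n_iter: int
    grad_norm: float
    n_used: int
    n_dropped: int
    message: str = ""
    options: FitOptions | None = None
    _vcov: np.ndarray | None = field(default=None, repr=False)
    _patterns: list | None = field(default=None, repr=False)

    @property
    def estimates(self) -> pd.Series:
        return pd.Series(self.theta, index=self.labels, name="estimate")

    def vcov(self) -> np.ndarray:
        if self._vcov is None:
            self._vcov = vcov_observed_information(self)
        return self._vcov

    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov())), index=self.labels,
                         name="se")

    def param_table(self) -> pd.DataFrame:
        """Flat table of (label, estimate, SE, z, p)."""
        est = self.theta
        try:
            se = np.sqrt(np.diag(self.vcov()))
        except EstimationError:
            se = np.full_like(est, np.nan)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = est / se
        p = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {"label": self.labels, "estimate": est, "se": se, "z": z, "p": p})

    def __getitem__(self, label: str) -> float:
        return float(self.theta[self.labels.index(label)])


# --------------------------------------------------------------------- #
# missingness-pattern sufficient statistics
# --------------------------------------------------------------------- #
def pattern_statistics(data, columns):
    """Group rows by missingness pattern and reduce to sufficient statistics.

    Returns
    -------
    patterns : list of (obs_idx, n_g, mean_g, scatter_g)
        ``obs_idx`` indexes the observed subset of ``columns``;
        ``scatter_g`` is the *unnormalized* centred cross-product matrix.
    n_used, n_dropped : int
        Rows entering the likelihood / rows missing all modeled variables.
    """
    df = as_frame(data)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise KeyError(f"data lacks modeled column(s): {missing}")
    X = df.loc[:, list(columns)].to_numpy(dtype=float)
    obs_mask = np.isfinite(X)
    keep = obs_mask.any(axis=1)
    n_dropped = int((~keep).sum())
    X, obs_mask = X[keep], obs_mask[keep]

    # encode each row's pattern as bytes for grouping
    codes = np.packbits(obs_mask, axis=1)
    order = np.lexsort(codes.T[::-1])
    codes_sorted = codes[order]
    boundaries = np.flatnonzero(
        np.any(codes_sorted[1:] != codes_sorted[:-1], axis=1)) + 1
    groups = np.split(order, boundaries)

    patterns = []
    for g in groups:
        oi = np.flatnonzero(obs_mask[g[0]])
        sub = X[np.ix_(g, oi)]
        n_g = sub.shape[0]
        mean_g = sub.mean(axis=0)
        centred = sub - mean_g
        scatter_g = centred.T @ centred
        patterns.append((oi, n_g, mean_g, scatter_g))
    return patterns, int(keep.sum()), n_dropped


def mvn_pattern_loglik(mu, sigma, patterns):
    """MVN log-likelihood of pattern sufficient statistics at (mu, sigma).

    Returns -inf if any observed sub-covariance is not positive definite.
    """
    total = 0.0
    for oi, n_g, mean_g, scatter_g in patterns:
        sub = sigma[np.ix_(oi, oi)]
        try:
            c, low = sla.cho_factor(sub, lower=True, check_finite=False)
        except sla.LinAlgError:
            return -np.inf
        logdet = 2.0 * np.log(np.diag(c)).sum()
        diff = mean_g - mu[oi]
        sinv_scatter = sla.cho_solve((c, low), scatter_g, check_finite=False)
        quad = float(diff @ sla.cho_solve((c, low), diff, check_finite=False))
        total += -0.5 * (n_g * (len(oi) * _LOG2PI + logdet + quad)
                         + np.trace(sinv_scatter))
    return total


def fiml_loglik(spec: SEMSpec, theta, data) -> float:
    """FIML log-likelihood of the data at theta.

    Rows missing every modeled variable are dropped.  An inadmissible theta
    (some observed sub-block of the implied covariance not positive
    definite) yields ``-inf`` rather than an exception, so optimizers can
    treat it as a barrier.
    """
    patterns, _, _ = pattern_statistics(data, spec.observed_names)
    mom = spec.implied_moments(theta)
    return mvn_pattern_loglik(mom.mu, mom.sigma, patterns)


class _LoglikEngine:
    """FIML log-likelihood and its analytic gradient for one spec + dataset.

    The gradient chains the standard multivariate-normal derivatives with
    respect to (mu, Sigma) through the linear-system parameterization
    mu = B m, Sigma = B S B', B = (I - A)^-1:

        dl/dm = B' g_mu
        dl/dS = B' G_sigma B          (off-diagonal entries doubled)
        dl/dA = (B' g_mu) mu' + 2 B' G_sigma Sigma

    where g_mu and G_sigma accumulate the per-pattern MVN derivatives over
    the observed rows/columns.
    """

    def __init__(self, spec: SEMSpec, patterns):
        self.spec = spec
        self.patterns = patterns
        self.comp = spec._compile()

    def value(self, theta):
        mom = self.spec.implied_moments(theta)
        return mvn_pattern_loglik(mom.mu, mom.sigma, self.patterns)

    def value_and_grad(self, theta):
        spec, comp = self.spec, self.comp
        A, S, m = spec.matrices(theta)
        k = A.shape[0]
        B = np.linalg.solve(np.eye(k) - A, np.eye(k))
        mu_f = B @ m
        sigma_f = B @ S @ B.T
        obs = comp["obs_idx"]
        mu = mu_f[obs]
        sigma = sigma_f[np.ix_(obs, obs)]

        ll = 0.0
        g_mu = np.zeros(k)
        G_sig = np.zeros((k, k))
        for oi, n_g, mean_g, scatter_g in self.patterns:
            sub = sigma[np.ix_(oi, oi)]
            try:
                c = sla.cho_factor(sub, lower=True, check_finite=False)
            except sla.LinAlgError:
                return -np.inf, np.zeros(theta.size)
            sinv = sla.cho_solve(c, np.eye(len(oi)), check_finite=False)
            logdet = 2.0 * np.log(np.diag(c[0])).sum()
            d = mean_g - mu[oi]
            sd = sinv @ d
            sw = sinv @ scatter_g
            ll += -0.5 * (n_g * (len(oi) * _LOG2PI + logdet + d @ sd)
                          + np.trace(sw))
            gi = obs[oi]
            g_mu[gi] += n_g * sd
            G_sig[np.ix_(gi, gi)] += -0.5 * (
                n_g * sinv - n_g * np.outer(sd, sd) - sw @ sinv)

        bt_gmu = B.T @ g_mu
        dS = B.T @ G_sig @ B
        dA = np.outer(bt_gmu, mu_f) + 2.0 * B.T @ G_sig @ sigma_f
        dm = bt_gmu

        grad = np.zeros(theta.size)
        e = comp["A"]
        fr = e["slot"] >= 0
        np.add.at(grad, e["slot"][fr], dA[e["rows"][fr], e["cols"][fr]])
        e = comp["S"]
        fr = e["slot"] >= 0
        vals = dS[e["rows"][fr], e["cols"][fr]]
        off = e["rows"][fr] != e["cols"][fr]
        vals = np.where(off, 2.0 * vals, vals)
        np.add.at(grad, e["slot"][fr], vals)
        e = comp["m"]
        fr = e["slot"] >= 0
        np.add.at(grad, e["slot"][fr], dm[e["rows"][fr]])
        return ll, grad


# --------------------------------------------------------------------- #
# start values
# --------------------------------------------------------------------- #
def _moment_starts(spec: SEMSpec, data) -> np.ndarray:
    """Refine the spec's start values from pairwise-complete data moments.

    Deterministic: free observed variances start at the column variance
    (halved when the variable loads on a latent), latent variances at half
    the anchor indicator's variance, covariate covariances at pairwise
    moments, intercepts at (adjusted) column means; loadings and structural
    coefficients keep their spec starts.
    """
    df = as_frame(data)
    theta = spec.start_theta()
    labels = spec.free_labels
    slot = {lab: i for i, lab in enumerate(labels)}

    col_mean, col_var = {}, {}
    for name in spec.observed_names:
        x = df[name].to_numpy(dtype=float)
        x = x[np.isfinite(x)]
        col_mean[name] = float(x.mean()) if x.size else 0.0
        v = float(x.var()) if x.size > 1 else 1.0
        col_var[name] = v if v > 0 else 1.0

    latent_parents = {}      # var -> [(latent, loading start)]
    for s, t, p in spec.directed:
        if spec.variable(s).kind == "latent":
            latent_parents.setdefault(t, []).append((s, p.value))
    anchor_of = {}           # latent -> first indicator with a fixed loading
    for s, t, p in spec.directed:
        if spec.variable(s).kind == "latent" and not p.free and s not in anchor_of:
            if spec.variable(t).kind == "observed":
                anchor_of[s] = t

    def key(p):
        return p.group if p.group is not None else p.label

    # variances and covariances
    for a, b, p in spec.bidirected:
        if not p.free or key(p) not in slot:
            continue
        i = slot[key(p)]
        va, vb = spec.variable(a), spec.variable(b)
        if a == b:
            if va.kind == "observed":
                theta[i] = col_var[a] * (0.5 if a in latent_parents else 1.0)
            else:
                anchor = anchor_of.get(a)
                theta[i] = 0.5 * col_var[anchor] if anchor else max(p.value, 0.5)
        elif va.kind == "observed" and vb.kind == "observed":
            xy = df[[a, b]].to_numpy(dtype=float)
            ok = np.isfinite(xy).all(axis=1)
            if va.role == "covariate" and vb.role == "covariate" and ok.sum() > 2:
                theta[i] = float(np.cov(xy[ok, 0], xy[ok, 1])[0, 1])
            else:
                theta[i] = 0.0

    # latent means: start at the mean of the anchor indicator
    latent_mean_start = {}
    for n, p in spec.intercepts.items():
        if spec.variable(n).kind == "latent" and p.free and key(p) in slot:
            anchor = anchor_of.get(n)
            val = col_mean.get(anchor, 0.0)
            theta[slot[key(p)]] = val
            latent_mean_start[n] = val
        elif spec.variable(n).kind == "latent":
            latent_mean_start[n] = p.value

    # observed intercepts: column mean net of latent-parent contributions
    for n, p in spec.intercepts.items():
        if spec.variable(n).kind != "observed" or not p.free or key(p) not in slot:
            continue
        adj = sum(lam * latent_mean_start.get(s, 0.0)
                  for s, lam in latent_parents.get(n, []))
        theta[slot[key(p)]] = col_mean[n] - adj
    return theta


# --------------------------------------------------------------------- #
# fitting
# --------------------------------------------------------------------- #
def _make_objective(spec, patterns):
    vmask = spec.variance_mask
    engine = _LoglikEngine(spec, patterns)

    def to_natural(z):
        theta = z.copy()
        theta[vmask] = np.exp(z[vmask])
        return theta

    def to_unconstrained(theta):
        z = np.asarray(theta, dtype=float).copy()
        if np.any(theta[vmask] <= 0):
            raise ValueError("variance start values must be positive")
        z[vmask] = np.log(theta[vmask])
        return z

    def negll_grad(z):
        theta = to_natural(z)
        try:
            ll, grad = engine.value_and_grad(theta)
        except ValueError:
            return _PENALTY, np.zeros(z.size)
        if not np.isfinite(ll):
            return _PENALTY, np.zeros(z.size)
        # chain rule for the log-variance reparameterization
        gz = grad.copy()
        gz[vmask] *= theta[vmask]
        return -ll, -gz

    return negll_grad, to_natural, to_unconstrained, engine


def fit_sem(spec: SEMSpec, data, options: FitOptions | None = None) -> FitResult:
    """Maximize the FIML log-likelihood of a spec on data.

    Quasi-Newton (L-BFGS-B) iteration with analytic gradients from
    moment-based start values; optional seeded random restarts.
    Non-convergence is reported in the result flag, never silently ignored.
    """
    options = options or FitOptions()
    problems = spec.validate()
    if problems:
        raise EstimationError("invalid spec: " + "; ".join(problems))
    patterns, n_used, n_dropped = pattern_statistics(data, spec.observed_names)
    negll_grad, to_natural, to_unconstrained, _ = _make_objective(spec, patterns)

    theta0 = (_moment_starts(spec, data) if options.start == "moments"
              else spec.start_theta())
    vmask = spec.variance_mask
    theta0[vmask] = np.maximum(theta0[vmask], 1e-3)
    z0 = to_unconstrained(theta0)

    if options.max_iter == 0:
        return FitResult(spec, theta0, spec.free_labels, -negll_grad(z0)[0],
                         converged=False, n_iter=0, grad_norm=np.inf,
                         n_used=n_used, n_dropped=n_dropped,
                         message="max_iter=0: start values returned",
                         options=options, _patterns=patterns)

    starts = [z0]
    if options.restarts > 0:
        rng = np.random.default_rng(options.restart_seed)
        for _ in range(options.restarts):
            starts.append(z0 + options.restart_scale * rng.standard_normal(z0.size))

    best = None
    best_nit = 0
    for z_start in starts:
        res = sopt.minimize(
            negll_grad, z_start, method="L-BFGS-B", jac=True,
            options={"maxiter": options.max_iter, "maxfun": 10 ** 6,
                     "ftol": options.tol * 1e-1, "gtol": options.gtol * 1e-3})
        if best is None or res.fun < best.fun:
            best = res
            best_nit = int(res.nit)

    # quasi-Newton often stalls on flat ridges before the gradient criterion
    # is met; a few Newton steps (FD Hessian of the analytic gradient) finish
    z_hat, fval, grad, polish_it = _newton_polish(
        negll_grad, best.x, float(best.fun),
        gtol=options.gtol * max(1.0, abs(best.fun)))
    grad_norm = float(np.abs(grad).max())
    converged = bool(fval < _PENALTY / 2) and (
        grad_norm <= options.gtol * max(1.0, abs(fval)))
    theta_hat = to_natural(z_hat)
    return FitResult(spec, theta_hat, spec.free_labels, -float(fval),
                     converged=converged, n_iter=best_nit + polish_it,
                     grad_norm=grad_norm, n_used=n_used, n_dropped=n_dropped,
                     message=str(best.message), options=options,
                     _patterns=patterns)


def _newton_polish(negll_grad, z, f0, gtol, max_steps=20):
    """Newton refinement of a quasi-Newton solution.

    Uses a central-difference Hessian of the analytic gradient with ridge
    escalation and backtracking; stops once the gradient max-norm is below
    gtol or no further improvement is possible.
    """
    f, g = negll_grad(z)
    q = z.size
    steps = 0
    for _ in range(max_steps):
        if np.abs(g).max() <= gtol:
            break
        H = np.empty((q, q))
        for i in range(q):
            h = 1e-5 * max(abs(z[i]), 1.0)
            zp, zm = z.copy(), z.copy()
            zp[i] += h
            zm[i] -= h
            H[i] = (negll_grad(zp)[1] - negll_grad(zm)[1]) / (2 * h)
        H = (H + H.T) / 2
        step = None
        for ridge in (0.0, 1e-8, 1e-6, 1e-4, 1e-2, 1.0):
            try:
                c = sla.cho_factor(H + ridge * np.eye(q))
                step = sla.cho_solve(c, g)
                break
            except sla.LinAlgError:
                continue
        if step is None:
            break
        t, improved = 1.0, False
        while t > 1e-8:
            f2, g2 = negll_grad(z - t * step)
            if f2 < f:
                z, f, g = z - t * step, f2, g2
                improved = True
                break
            t /= 2
        steps += 1
        if not improved:
            break
    return z, f, g, steps


# --------------------------------------------------------------------- #
# inference
# --------------------------------------------------------------------- #
def vcov_observed_information(fit: FitResult) -> np.ndarray:
    """Parameter covariance from the observed information at the optimum.

    The Hessian of the FIML log-likelihood with respect to the *natural*-
    scale parameters is obtained by central differencing of the analytic
    gradient, negated and inverted.  A non-invertible or indefinite Hessian
    raises EstimationError (no silent pseudo-inverse): it typically signals
    an under-identified model.
    """
    if not fit.converged:
        warnings.warn("computing observed information at a non-converged fit")
    if fit._patterns is None:
        raise EstimationError("fit carries no data patterns")
    spec = fit.spec
    engine = _LoglikEngine(spec, fit._patterns)

    theta = fit.theta
    q = theta.size
    vmask = spec.variance_mask
    h = 1e-5 * np.maximum(np.abs(theta), 0.1)
    # keep variance steps inside the admissible region
    h[vmask] = np.minimum(h[vmask], theta[vmask] / 3)

    if not np.isfinite(engine.value(theta)):
        raise EstimationError("log-likelihood not finite at the estimate")
    H = np.empty((q, q))
    for i in range(q):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h[i]
        tm[i] -= h[i]
        _, gp = engine.value_and_grad(tp)
        _, gm = engine.value_and_grad(tm)
        H[i] = (gp - gm) / (2 * h[i])
    info = -(H + H.T) / 2
    try:
        c, low = sla.cho_factor(info)
    except sla.LinAlgError as exc:
        raise EstimationError(
            "observed information is not positive definite "
            "(model may be under-identified)") from exc
    vcov = sla.cho_solve((c, low), np.eye(q))
    return (vcov + vcov.T) / 2


def likelihood_ratio_test(fit_constrained: FitResult, fit_full: FitResult):
    """LRT of a nested (constrained) model against the full model.

    Returns a dict with the chi-square statistic (clipped at zero), the
    difference in free-parameter counts, and the upper-tail p-value.
    """
    q_c = fit_constrained.spec.free_parameter_count()
    q_f = fit_full.spec.free_parameter_count()
    if q_c >= q_f:
        raise ValueError("constrained model must have strictly fewer free "
                         f"parameters ({q_c} >= {q_f})")
    if fit_constrained.n_used != fit_full.n_used:
        raise ValueError("fits use different numbers of rows; "
                         "the test requires the same data")
    df = q_f - q_c
    stat = max(0.0, 2.0 * (fit_full.loglik - fit_constrained.loglik))
    return {"stat": stat, "df": df, "p": float(stats.chi2.sf(stat, df))}
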