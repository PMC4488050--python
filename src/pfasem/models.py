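"""Builders for the five latent-exposure SEM variants and the analysis driver.

The variants form a ladder of increasingly comprehensive measurement models
for serum-PFAS exposure (all variables on the log2 scale):

1. one chemical per model — its age-5 and age-7 concentrations are two
   error-prone indicators of a latent long-term exposure (both loadings
   fixed to 1; a free intercept on the age-7 indicator absorbs the general
   concentration change between ages);
2. the three single-chemical models merged, latent exposures freely
   intercorrelated and mutually adjusted in the outcome equations;
3. one latent overall PFAS exposure at a single age, measured by the three
   same-age concentrations (PFOS loading anchored to 1, so "a doubling of
   latent PFAS" is a doubling on the PFOS scale);
4. the age-5 and age-7 latent PFAS variables of model 3 together, mutually
   adjusted;
5. a single latent childhood PFAS exposure measured by all six
   concentrations, with local dependence handled by Year-5/Year-7 factors
   (same-age residual association, equally strong at both ages) and a
   residual covariance between the two ages of each chemical.

Covariates (age, sex, booster type) predict the latent exposure(s) and the
antibody outcomes; their own means and covariances are freely estimated so
the covariate block is saturated and FIML covers missing covariate cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .data import as_frame, prepare_model_frame
from .effects import joint_effect, percent_change_per_doubling, test_equal_effects
from .estimation import FitOptions, fit_sem
from .indices import assess, compute_fit_indices
from .regression import fit_naive_regression, spline_linearity_check
from .spec import Parameter, SEMSpec, Variable, build_spec, fixed, free

__all__ = [
    "AnalysisConfig",
    "CHEMICALS",
    "ANTIBODIES",
    "model1_single_pfas",
    "model2_mutually_adjusted",
    "model3_joint_latent",
    "model4_both_ages",
    "model5_childhood",
    "canonicalize_local_factor_sign",
    "run_full_analysis",
    "AnalysisReport",
    "exclude_extra_booster",
]

CHEMICALS = ("pfos", "pfoa", "pfhxs")
ANTIBODIES = ("diphtheria", "tetanus")


@dataclass
class AnalysisConfig:
    """Which models to run and which optional adjustments to apply."""

    models: tuple = (1, 2, 3, 4, 5)
    covariates: tuple = ("age", "sex", "booster_type")
    albumin: bool = False           # albumin -> observed indicators
    bmi: bool = False               # BMI -> observed indicators
    pre_booster: bool = False       # age-5 pre-booster antibody -> outcome
    level: float = 0.95
    fit_options: FitOptions = field(default_factory=FitOptions)


def _outcome(antibody: str) -> str:
    if antibody not in ANTIBODIES:
        raise ValueError(f"unknown antibody {antibody!r}")
    return f"anti_{antibody}_7"


def _pre_col(antibody: str) -> str:
    return f"anti_{antibody}_5_pre"


class _Builder:
    """Accumulates variables/edges and renders a validated SEMSpec."""

    def __init__(self):
        self.variables = []
        self.directed = []
        self.bidirected = []
        self.intercepts = {}

    def var(self, name, kind="observed", role="other"):
        self.variables.append(Variable(name, kind, role))
        return name

    def path(self, src, dst, param):
        self.directed.append((src, dst, param))

    def cov(self, a, b, param):
        self.bidirected.append((a, b, param))

    def mean(self, name, param):
        self.intercepts[name] = param

    def build(self) -> SEMSpec:
        return build_spec(self.variables, self.directed, self.bidirected,
                          self.intercepts)


def _exogenous_names(config: AnalysisConfig, antibodies=()):
    """Covariate-block columns implied by the config flags."""
    names = list(config.covariates)
    if config.albumin:
        names.append("albumin_7")
    if config.bmi:
        names.append("bmi")
    if config.pre_booster:
        names += [_pre_col(a) for a in antibodies]
    return names


def _add_exogenous_block(b: _Builder, names):
    """Saturated moment model for the exogenous covariates.

    Free means, variances and pairwise covariances: the block contributes
    p_c means + p_c(p_c+1)/2 moments on both sides of the df count, so it
    is df-neutral, and FIML handles missing covariate cells.
    """
    for c in names:
        b.var(c, "observed", "covariate")
        b.mean(c, free(f"mu_{c}", 0.0))
        b.cov(c, c, free(f"var_{c}", 1.0))
    for i, a in enumerate(names):
        for c in names[i + 1:]:
            b.cov(a, c, free(f"cov_{a}_{c}", 0.0))


def _add_outcome(b: _Builder, antibody, latents, config, betas=None,
                 equal_group=None):
    """Outcome equation: latent exposure(s) + covariates (+ pre-booster)."""
    y = b.var(_outcome(antibody), "observed", "outcome")
    b.mean(y, free(f"mu_{y}", 0.0))
    b.cov(y, y, free(f"var_eps_{antibody}", 1.0))
    for lat in latents:
        label = (betas or {}).get(lat, f"beta_{antibody}"
                 if len(latents) == 1 else f"beta_{antibody}_{lat}")
        b.path(lat, y, Parameter(label, free=True, value=0.0,
                                 group=equal_group))
    for c in config.covariates:
        b.path(c, y, free(f"gamma_{y}_{c}", 0.0))
    if config.pre_booster:
        b.path(_pre_col(antibody), y, free(f"gamma_{y}_pre", 0.0))
    return y


def _measurement_error_cov(b: _Builder, names, config):
    """Optional albumin/BMI paths into observed indicators."""
    for x in names:
        if config.albumin:
            b.path("albumin_7", x, free(f"delta_alb_{x}", 0.0))
        if config.bmi:
            b.path("bmi", x, free(f"delta_bmi_{x}", 0.0))


# --------------------------------------------------------------------- #
# model 1: single chemical, single antibody
# --------------------------------------------------------------------- #
def model1_single_pfas(chemical: str, antibody: str,
                       config: AnalysisConfig | None = None) -> SEMSpec:
    """Latent single-chemical exposure measured at ages 5 and 7.

    Both loadings are fixed to 1; the age-5 indicator has intercept 0 and
    the latent mean is free, while the free age-7 intercept captures the
    systematic concentration change between the ages.  Measurement-error
    variances at the two ages are separate free parameters.

    Free parameters of the covariate-free core (3 observed variables, 9
    moments): 2 error variances, the latent variance and mean, the age-7
    intercept, the outcome coefficient, intercept and residual variance —
    8 in total, hence df = 1.
    """
    config = config or AnalysisConfig()
    if chemical not in CHEMICALS:
        raise ValueError(f"unknown chemical {chemical!r}")
    b = _Builder()
    x5, x7 = f"{chemical}_5", f"{chemical}_7"
    lat = f"latent_{chemical}"
    b.var(x5, "observed", "indicator")
    b.var(x7, "observed", "indicator")
    b.var(lat, "latent", "latent-exposure")
    b.path(lat, x5, fixed(f"lambda_{x5}", 1.0))
    b.path(lat, x7, fixed(f"lambda_{x7}", 1.0))
    b.mean(x5, fixed(f"mu_{x5}", 0.0))
    b.mean(x7, free(f"alpha_{chemical}", 0.0))
    b.mean(lat, free(f"mu_{lat}", 0.0))
    b.cov(x5, x5, free(f"var_eps_{x5}", 0.1))
    b.cov(x7, x7, free(f"var_eps_{x7}", 0.1))
    b.cov(lat, lat, free(f"var_{lat}", 0.2))
    _measurement_error_cov(b, [x5, x7], config)
    _add_outcome(b, antibody, [lat], config)
    for c in config.covariates:
        b.path(c, lat, free(f"gamma_{lat}_{c}", 0.0))
    _add_exogenous_block(b, _exogenous_names(config, [antibody]))
    return b.build()


# --------------------------------------------------------------------- #
# model 2: three latent chemicals, mutually adjusted
# --------------------------------------------------------------------- #
def model2_mutually_adjusted(antibodies=ANTIBODIES,
                             config: AnalysisConfig | None = None) -> SEMSpec:
    """The three single-chemical measurement models merged into one SEM.

    The latent exposures are freely intercorrelated, and each antibody
    depends on all three, so each coefficient is adjusted for the other
    two chemicals.
    """
    config = config or AnalysisConfig()
    b = _Builder()
    latents = []
    for chem in CHEMICALS:
        x5, x7 = f"{chem}_5", f"{chem}_7"
        lat = f"latent_{chem}"
        latents.append(lat)
        b.var(x5, "observed", "indicator")
        b.var(x7, "observed", "indicator")
        b.var(lat, "latent", "latent-exposure")
        b.path(lat, x5, fixed(f"lambda_{x5}", 1.0))
        b.path(lat, x7, fixed(f"lambda_{x7}", 1.0))
        b.mean(x5, fixed(f"mu_{x5}", 0.0))
        b.mean(x7, free(f"alpha_{chem}", 0.0))
        b.mean(lat, free(f"mu_{lat}", 0.0))
        b.cov(x5, x5, free(f"var_eps_{x5}", 0.1))
        b.cov(x7, x7, free(f"var_eps_{x7}", 0.1))
        b.cov(lat, lat, free(f"var_{lat}", 0.2))
        _measurement_error_cov(b, [x5, x7], config)
    for i, la in enumerate(latents):
        for lb in latents[i + 1:]:
            b.cov(la, lb, free(f"cov_{la}_{lb}", 0.02))
    ys = [_add_outcome(b, a, latents, config) for a in antibodies]
    if len(ys) == 2:
        b.cov(ys[0], ys[1], free("cov_eps_antibodies", 0.1))
    for c in config.covariates:
        for lat in latents:
            b.path(c, lat, free(f"gamma_{lat}_{c}", 0.0))
    _add_exogenous_block(b, _exogenous_names(config, antibodies))
    return b.build()


# --------------------------------------------------------------------- #
# models 3-5: joint latent PFAS
# --------------------------------------------------------------------- #
def _joint_measurement(b: _Builder, age: int, lat: str, config,
                       anchor: str = "pfos"):
    """Three same-age indicators of one latent; the anchor loading is 1."""
    for chem in CHEMICALS:
        x = f"{chem}_{age}"
        b.var(x, "observed", "indicator")
        if chem == anchor:
            b.path(lat, x, fixed(f"lambda_{x}", 1.0))
        else:
            b.path(lat, x, free(f"lambda_{x}", 1.0))
        b.mean(x, free(f"alpha_{x}", 0.0))
        b.cov(x, x, free(f"var_eps_{x}", 0.1))
    _measurement_error_cov(b, [f"{c}_{age}" for c in CHEMICALS], config)


def model3_joint_latent(age: int, config: AnalysisConfig | None = None,
                        equal_effects: bool = False) -> SEMSpec:
    """One latent overall PFAS exposure at a single age (5 or 7).

    The three same-age log2 concentrations are its indicators; the PFOS
    loading is fixed to 1 (PFOS is by far the most prevalent of the three,
    so a doubling of the latent means a doubling on the PFOS scale), the
    latent mean is fixed to 0 and all indicator intercepts are free.  Both
    antibodies are modeled jointly with correlated residuals; with
    ``equal_effects`` the two exposure coefficients share one value.
    """
    config = config or AnalysisConfig()
    if age not in (5, 7):
        raise ValueError("age must be 5 or 7")
    b = _Builder()
    lat = f"latent_pfas_{age}"
    b.var(lat, "latent", "latent-exposure")
    b.mean(lat, fixed(f"mu_{lat}", 0.0))
    b.cov(lat, lat, free(f"var_{lat}", 0.1))
    _joint_measurement(b, age, lat, config)
    group = "beta_joint" if equal_effects else None
    ys = [_add_outcome(b, a, [lat], config, equal_group=group)
          for a in ANTIBODIES]
    b.cov(ys[0], ys[1], free("cov_eps_antibodies", 0.1))
    for c in config.covariates:
        b.path(c, lat, free(f"gamma_{lat}_{c}", 0.0))
    _add_exogenous_block(b, _exogenous_names(config, ANTIBODIES))
    return b.build()


def model4_both_ages(config: AnalysisConfig | None = None) -> SEMSpec:
    """Correlated latent PFAS at ages 5 and 7, mutually adjusted outcomes."""
    config = config or AnalysisConfig()
    b = _Builder()
    latents = []
    for age in (5, 7):
        lat = f"latent_pfas_{age}"
        latents.append(lat)
        b.var(lat, "latent", "latent-exposure")
        b.mean(lat, fixed(f"mu_{lat}", 0.0))
        b.cov(lat, lat, free(f"var_{lat}", 0.1))
        _joint_measurement(b, age, lat, config)
    b.cov(latents[0], latents[1], free("cov_latent_5_7", 0.05))
    ys = [_add_outcome(b, a, latents, config) for a in ANTIBODIES]
    b.cov(ys[0], ys[1], free("cov_eps_antibodies", 0.1))
    for c in config.covariates:
        for lat in latents:
            b.path(c, lat, free(f"gamma_{lat}_{c}", 0.0))
    _add_exogenous_block(b, _exogenous_names(config, ANTIBODIES))
    return b.build()


def model5_childhood(config: AnalysisConfig | None = None,
                     equal_effects: bool = False) -> SEMSpec:
    """One latent childhood PFAS exposure measured by all six concentrations.

    Local dependence beyond the childhood factor is modeled two ways, as in
    the final model variant: Year-5 and Year-7 factors carry the residual
    same-age association (their loadings are equality-grouped across the
    two ages, i.e. equally strong at both assessments; factor variances are
    fixed to 1), and a free residual covariance links the age-5 and age-7
    measurement of each chemical.  Both PFOS loadings are fixed to 1, so a
    doubling of latent childhood PFAS is a doubling on the PFOS scale.
    """
    config = config or AnalysisConfig()
    b = _Builder()
    lat = "latent_pfas_childhood"
    b.var(lat, "latent", "latent-exposure")
    b.mean(lat, fixed(f"mu_{lat}", 0.0))
    b.cov(lat, lat, free(f"var_{lat}", 0.1))
    for age in (5, 7):
        for chem in CHEMICALS:
            x = f"{chem}_{age}"
            b.var(x, "observed", "indicator")
            if chem == "pfos":
                b.path(lat, x, fixed(f"lambda_{x}", 1.0))
            else:
                b.path(lat, x, free(f"lambda_{x}", 1.0))
            b.mean(x, free(f"alpha_{x}", 0.0))
            b.cov(x, x, free(f"var_eps_{x}", 0.1))
    # Year factors: same-age local dependence, equal strength at both ages
    for age in (5, 7):
        yr = f"year_{age}"
        b.var(yr, "latent", "local-dependence-factor")
        b.mean(yr, fixed(f"mu_{yr}", 0.0))
        b.cov(yr, yr, fixed(f"var_{yr}", 1.0))
        for chem in CHEMICALS:
            b.path(yr, f"{chem}_{age}",
                   Parameter(f"kappa_{chem}_{age}", free=True, value=0.2,
                             group=f"kappa_{chem}"))
    # within-chemical local dependence across the two ages
    for chem in CHEMICALS:
        b.cov(f"{chem}_5", f"{chem}_7", free(f"cov_eps_{chem}_5_7", 0.02))
    _measurement_error_cov(
        b, [f"{c}_{a}" for a in (5, 7) for c in CHEMICALS], config)
    group = "beta_joint" if equal_effects else None
    ys = [_add_outcome(b, a, [lat], config, equal_group=group)
          for a in ANTIBODIES]
    b.cov(ys[0], ys[1], free("cov_eps_antibodies", 0.1))
    for c in config.covariates:
        b.path(c, lat, free(f"gamma_{lat}_{c}", 0.0))
    _add_exogenous_block(b, _exogenous_names(config, ANTIBODIES))
    return b.build()


# --------------------------------------------------------------------- #
# full analysis driver
# --------------------------------------------------------------------- #
def canonicalize_local_factor_sign(fit):
    """Resolve the joint sign indeterminacy of the year-factor loadings.

    The local-dependence factors enter the implied moments only through
    pairwise products of their loadings, so flipping all loadings at once
    leaves the likelihood unchanged.  The positive-sum representative is
    reported; any cached parameter covariance is invalidated.
    """
    idx = [i for i, lab in enumerate(fit.labels) if lab.startswith("kappa_")]
    if idx and fit.theta[idx].sum() < 0:
        fit.theta[idx] = -fit.theta[idx]
        fit._vcov = None
    return fit


@dataclass
class AnalysisReport:
    """Bundle of effect tables, fit assessments and bookkeeping."""

    regression_table: pd.DataFrame | None
    joint_table: pd.DataFrame | None
    fit_indices: dict
    spline_checks: dict
    n_rows: int
    n_excluded_extra_booster: int
    n_used: dict
    errors: dict
    config: AnalysisConfig

    def summary(self) -> str:
        lines = ["PFAS immunotoxicity analysis report",
                 "===================================",
                 f"rows analysed: {self.n_rows} "
                 f"(excluded for extra booster: {self.n_excluded_extra_booster})",
                 ""]
        if self.regression_table is not None:
            lines += ["Per-chemical percent change per doubling "
                      "(linear regression and SEM variants):",
                      self.regression_table.to_string(index=False), ""]
        if self.joint_table is not None:
            lines += ["Joint latent PFAS models:",
                      self.joint_table.to_string(index=False), ""]
        for name, fi in self.fit_indices.items():
            verdict = assess(fi)
            lines.append(f"{name}: {fi.summary()} "
                         f"[{'good fit' if verdict['pass'] else 'poor fit'}]")
        if self.errors:
            lines.append("")
            for name, err in self.errors.items():
                lines.append(f"FAILED {name}: {err}")
        return "\n".join(lines)


def exclude_extra_booster(data):
    """Drop children flagged as having received an additional booster."""
    df = as_frame(data)
    if "extra_booster" not in df.columns:
        return df, 0
    flag = df["extra_booster"].fillna(0).astype(bool)
    return df.loc[~flag].drop(columns=["extra_booster"]), int(flag.sum())


def _effect_row(model, antibody, chemical, eff, n):
    return {"model": model, "antibody": antibody, "chemical": chemical,
            "pct_change": eff.percent, "ci_low": eff.ci_low,
            "ci_high": eff.ci_high, "n": n}


def run_full_analysis(data, config: AnalysisConfig | None = None) -> AnalysisReport:
    """Run the baseline regressions and the requested SEM variants.

    Individual model failures are recorded in ``errors`` and the run
    continues.  Deterministic for a given dataset and configuration.
    """
    config = config or AnalysisConfig()
    df_raw, n_excl = exclude_extra_booster(data)
    conc = [f"{c}_{a}" for a in (5, 7) for c in CHEMICALS]
    conc += [_outcome(a) for a in ANTIBODIES]
    if config.pre_booster:
        conc += [_pre_col(a) for a in ANTIBODIES]
    # absent columns are left for the individual model fits to report
    present = [c for c in conc if c in df_raw.columns]
    frame, _ = prepare_model_frame(df_raw, present, config.covariates)

    reg_rows, joint_rows = [], []
    fit_indices, errors, n_used, splines = {}, {}, {}, {}

    # baseline regressions + spline linearity checks
    for antibody in ANTIBODIES:
        for chem in CHEMICALS:
            try:
                rr = fit_naive_regression(
                    df_raw, f"{chem}_7", _outcome(antibody),
                    list(config.covariates), config.level)
                reg_rows.append(_effect_row("linear regression", antibody,
                                            chem, rr.effect, rr.n_used))
                splines[f"{chem}:{antibody}"] = spline_linearity_check(
                    df_raw, f"{chem}_7", _outcome(antibody),
                    list(config.covariates))
            except Exception as exc:   # recorded, run continues
                errors[f"regression {chem}/{antibody}"] = str(exc)

    def run_fit(name, spec):
        fit = canonicalize_local_factor_sign(
            fit_sem(spec, frame, config.fit_options))
        n_used[name] = fit.n_used
        if not fit.converged:
            raise RuntimeError(f"{name} did not converge ({fit.message})")
        fit_indices[name] = compute_fit_indices(fit, frame)
        return fit

    if 1 in config.models:
        for antibody in ANTIBODIES:
            for chem in CHEMICALS:
                name = f"model1 {chem}/{antibody}"
                try:
                    fit = run_fit(name, model1_single_pfas(chem, antibody, config))
                    se = fit.se()
                    eff = percent_change_per_doubling(
                        fit[f"beta_{antibody}"], se[f"beta_{antibody}"],
                        config.level)
                    reg_rows.append(_effect_row("SEM latent chemical",
                                                antibody, chem, eff,
                                                fit.n_used))
                except Exception as exc:
                    errors[name] = str(exc)

    if 2 in config.models:
        try:
            fit = run_fit("model2", model2_mutually_adjusted(ANTIBODIES, config))
            se = fit.se()
            for antibody in ANTIBODIES:
                for chem in CHEMICALS:
                    lab = f"beta_{antibody}_latent_{chem}"
                    eff = percent_change_per_doubling(fit[lab], se[lab],
                                                      config.level)
                    reg_rows.append(_effect_row("SEM mutually adjusted",
                                                antibody, chem, eff,
                                                fit.n_used))
        except Exception as exc:
            errors["model2"] = str(exc)

    def joint_model(name, spec_free, spec_equal, label):
        try:
            fit_free = run_fit(f"{name} (free)", spec_free)
            fit_eq = run_fit(f"{name} (same effect)", spec_equal)
            se_free = fit_free.se()
            row = {"model": label, "n": fit_free.n_used}
            for antibody in ANTIBODIES:
                eff = percent_change_per_doubling(
                    fit_free[f"beta_{antibody}"],
                    se_free[f"beta_{antibody}"], config.level)
                row[f"{antibody}_pct"] = eff.percent
                row[f"{antibody}_ci_low"] = eff.ci_low
                row[f"{antibody}_ci_high"] = eff.ci_high
            lrt = test_equal_effects(fit_free, fit_eq)
            row["equal_effect_p"] = lrt["p"]
            jeff = joint_effect(fit_eq, ["beta_joint"], config.level)
            row["joint_pct"] = jeff.percent
            row["joint_ci_low"] = jeff.ci_low
            row["joint_ci_high"] = jeff.ci_high
            joint_rows.append(row)
        except Exception as exc:
            errors[name] = str(exc)

    if 3 in config.models:
        for age in (5, 7):
            joint_model(f"model3 age {age}",
                        model3_joint_latent(age, config, equal_effects=False),
                        model3_joint_latent(age, config, equal_effects=True),
                        f"PFAS at age {age}")
    if 4 in config.models:
        try:
            fit = run_fit("model4", model4_both_ages(config))
            se = fit.se()
            for antibody in ANTIBODIES:
                for age in (5, 7):
                    lab = f"beta_{antibody}_latent_pfas_{age}"
                    eff = percent_change_per_doubling(fit[lab], se[lab],
                                                      config.level)
                    reg_rows.append(_effect_row(
                        "SEM both ages", antibody, f"pfas_{age}", eff,
                        fit.n_used))
        except Exception as exc:
            errors["model4"] = str(exc)
    if 5 in config.models:
        joint_model("model5",
                    model5_childhood(config, equal_effects=False),
                    model5_childhood(config, equal_effects=True),
                    "PFAS childhood")

    return AnalysisReport(
        regression_table=pd.DataFrame(reg_rows) if reg_rows else None,
        joint_table=pd.DataFrame(joint_rows) if joint_rows else None,
        fit_indices=fit_indices,
        spline_checks=splines,
        n_rows=len(df_raw),
        n_excluded_extra_booster=n_excl,
        n_used=n_used,
        errors=errors,
        config=config,
    )
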