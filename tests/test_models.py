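"""Model-variant builders: structure, identification, recovery, driver."""

import numpy as np
import pytest

import pfasem as pf
from pfasem.models import canonicalize_local_factor_sign

from conftest import MODEL3_TRUTH, MODEL5_TRUTH, spec_sim


class TestModel1Structure:
    def test_default_shape(self, model1_spec):
        assert len([v for v in model1_spec.variables
                    if v.role == "indicator"]) == 2
        assert model1_spec.latent_names == ["latent_pfoa"]
        assert len([v for v in model1_spec.variables
                    if v.role == "outcome"]) == 1

    def test_albumin_flag_adds_two_directed_edges(self):
        base = pf.model1_single_pfas("pfoa", "tetanus",
                                     pf.AnalysisConfig(covariates=("sex",)))
        with_alb = pf.model1_single_pfas(
            "pfoa", "tetanus",
            pf.AnalysisConfig(covariates=("sex",), albumin=True))
        extra = [(s, t) for s, t, _ in with_alb.directed
                 if s == "albumin_7" and t in ("pfoa_5", "pfoa_7")]
        assert len(extra) == 2
        # only the covariate-block edges for albumin itself come on top
        non_alb = [e for e in with_alb.directed
                   if e[0] != "albumin_7" or e[1] not in ("pfoa_5", "pfoa_7")]
        assert len(non_alb) == len(base.directed)

    def test_unknown_chemical_or_antibody_rejected(self):
        with pytest.raises(ValueError):
            pf.model1_single_pfas("pfna", "tetanus")
        with pytest.raises(ValueError):
            pf.model1_single_pfas("pfos", "rubella")


class TestStructuralCounts:
    def test_model2_has_six_exposure_paths(self):
        spec = pf.model2_mutually_adjusted()
        paths = [(s, t) for s, t, _ in spec.directed
                 if s.startswith("latent_") and t.startswith("anti_")]
        assert len(paths) == 6

    def test_model4_has_four_exposure_paths(self):
        spec = pf.model4_both_ages()
        paths = [(s, t) for s, t, _ in spec.directed
                 if s.startswith("latent_") and t.startswith("anti_")]
        assert len(paths) == 4

    def test_model5_year_loadings_grouped_six_to_three(self, model5_spec):
        kappa_edges = [p for _, _, p in model5_spec.directed
                       if p.label.startswith("kappa_")]
        assert len(kappa_edges) == 6
        kappa_free = [l for l in model5_spec.free_labels
                      if l.startswith("kappa_")]
        assert len(kappa_free) == 3

    def test_model3_free_parameter_hand_count(self, model3_spec):
        # 5 observed -> 20 moments; free: 2 loadings, 3 intercepts, 3 error
        # variances, latent variance, 2 effects, 2 outcome intercepts,
        # 2 outcome variances, 1 outcome covariance = 16 -> df = 4
        assert model3_spec.free_parameter_count() == 16
        assert model3_spec.model_df() == 4

    def test_pre_booster_adds_one_outcome_covariate_each(self):
        base = pf.model3_joint_latent(7, pf.AnalysisConfig())
        pre = pf.model3_joint_latent(7, pf.AnalysisConfig(pre_booster=True))
        for ab in ("diphtheria", "tetanus"):
            into = lambda spec: {s for s, t, _ in spec.directed
                                 if t == f"anti_{ab}_7"}
            assert into(pre) - into(base) == {f"anti_{ab}_5_pre"}


class TestRecovery:
    def test_model3_recovers_latent_effect(self, model3_spec):
        rng = np.random.default_rng(300)
        df = spec_sim(model3_spec, MODEL3_TRUTH, 2000, rng)
        fit = pf.fit_sem(model3_spec, df)
        assert fit.converged
        se = fit.se()
        for lab in ("beta_diphtheria", "beta_tetanus", "lambda_pfoa_7"):
            assert abs(fit[lab] - MODEL3_TRUTH[lab]) < 3 * se[lab]

    def test_model5_recovers_childhood_effect(self, model5_spec):
        rng = np.random.default_rng(500)
        df = spec_sim(model5_spec, MODEL5_TRUTH, 2000, rng)
        fit = canonicalize_local_factor_sign(pf.fit_sem(model5_spec, df))
        assert fit.converged
        se = fit.se()
        for lab in ("beta_diphtheria", "beta_tetanus", "kappa_pfos"):
            assert abs(fit[lab] - MODEL5_TRUTH[lab]) < 3 * se[lab]

    def test_model2_mutual_adjustment_separates_active_chemical(self,
                                                                no_covariates):
        spec = pf.model2_mutually_adjusted(config=no_covariates)
        truth = {}
        for chem, (mu, var) in {"pfos": (3.95, 0.16), "pfoa": (2.1, 0.14),
                                "pfhxs": (-1.0, 0.18)}.items():
            truth[f"mu_latent_{chem}"] = mu
            truth[f"var_latent_{chem}"] = var
            truth[f"var_eps_{chem}_5"] = 0.10
            truth[f"var_eps_{chem}_7"] = 0.10
            truth[f"alpha_{chem}"] = 0.1
        truth.update({"cov_latent_pfos_latent_pfoa": 0.04,
                      "cov_latent_pfos_latent_pfhxs": 0.07,
                      "cov_latent_pfoa_latent_pfhxs": 0.05,
                      "beta_diphtheria_latent_pfoa": -0.9,
                      "beta_tetanus_latent_pfoa": -0.9,
                      "var_eps_diphtheria": 2.0, "var_eps_tetanus": 4.0,
                      "cov_eps_antibodies": 0.9,
                      "mu_anti_diphtheria_7": -0.3,
                      "mu_anti_tetanus_7": 0.85})
        rng = np.random.default_rng(222)
        df = spec_sim(spec, truth, 20_000, rng)
        fit = pf.fit_sem(spec, df)
        assert fit.converged
        se = fit.se()
        # only PFOA is truly active; its estimate centres on truth, the
        # other mutually adjusted coefficients centre on zero
        for ab in ("diphtheria", "tetanus"):
            assert abs(fit[f"beta_{ab}_latent_pfoa"] + 0.9) < \
                3 * se[f"beta_{ab}_latent_pfoa"]
            for chem in ("pfos", "pfhxs"):
                lab = f"beta_{ab}_latent_{chem}"
                assert abs(fit[lab]) < 3 * se[lab]

    def test_mutual_adjustment_costs_precision(self, no_covariates):
        # correlated exposures: model-2 SEs exceed the single-chemical SEs
        spec2 = pf.model2_mutually_adjusted(config=no_covariates)
        truth = {}
        for chem in ("pfos", "pfoa", "pfhxs"):
            truth[f"mu_latent_{chem}"] = 2.0
            truth[f"var_latent_{chem}"] = 0.15
            truth[f"var_eps_{chem}_5"] = 0.10
            truth[f"var_eps_{chem}_7"] = 0.10
        truth.update({"cov_latent_pfos_latent_pfoa": 0.10,
                      "cov_latent_pfos_latent_pfhxs": 0.10,
                      "cov_latent_pfoa_latent_pfhxs": 0.10,
                      "beta_diphtheria_latent_pfoa": -0.6,
                      "var_eps_diphtheria": 2.0, "var_eps_tetanus": 4.0})
        rng = np.random.default_rng(223)
        df = spec_sim(spec2, truth, 1000, rng)
        fit2 = pf.fit_sem(spec2, df)
        se2 = fit2.se()
        spec1 = pf.model1_single_pfas("pfoa", "diphtheria", no_covariates)
        fit1 = pf.fit_sem(spec1, df)
        se1 = fit1.se()
        assert se2["beta_diphtheria_latent_pfoa"] > se1["beta_diphtheria"]

    def test_model4_recovery_and_collinearity_se_inflation(self,
                                                           no_covariates):
        spec4 = pf.model4_both_ages(no_covariates)

        def truth_with(cov_lat):
            t = {}
            for age in (5, 7):
                t[f"var_latent_pfas_{age}"] = 0.12
                t[f"lambda_pfoa_{age}"] = 0.6
                t[f"lambda_pfhxs_{age}"] = 0.9
                t[f"alpha_pfos_{age}"] = 4.0
                t[f"alpha_pfoa_{age}"] = 2.1
                t[f"alpha_pfhxs_{age}"] = -1.0
                for chem in ("pfos", "pfoa", "pfhxs"):
                    t[f"var_eps_{chem}_{age}"] = 0.10
            t.update({"cov_latent_5_7": cov_lat,
                      "beta_diphtheria_latent_pfas_5": -0.6,
                      "beta_diphtheria_latent_pfas_7": -0.6,
                      "beta_tetanus_latent_pfas_5": -0.5,
                      "beta_tetanus_latent_pfas_7": -0.5,
                      "var_eps_diphtheria": 2.0, "var_eps_tetanus": 4.0,
                      "cov_eps_antibodies": 0.9,
                      "mu_anti_diphtheria_7": -0.3,
                      "mu_anti_tetanus_7": 0.85})
            return t

        rng = np.random.default_rng(444)
        # independent latents: every coefficient recovered
        t_ind = truth_with(0.0)
        fit_ind = pf.fit_sem(spec4, spec_sim(spec4, t_ind, 2000, rng))
        assert fit_ind.converged
        se_ind = fit_ind.se()
        for lab in ("beta_diphtheria_latent_pfas_5",
                    "beta_diphtheria_latent_pfas_7"):
            assert abs(fit_ind[lab] - t_ind[lab]) < 3 * se_ind[lab]

        # strongly correlated latents (r = 0.9): mutual adjustment inflates
        # the exposure SEs relative to the single-age model 3
        t_cor = truth_with(0.9 * 0.12)
        df_cor = spec_sim(spec4, t_cor, 2000, rng)
        se4 = pf.fit_sem(spec4, df_cor).se()
        spec3 = pf.model3_joint_latent(7, no_covariates)
        se3 = pf.fit_sem(spec3, df_cor).se()
        assert se4["beta_diphtheria_latent_pfas_7"] > \
            2 * se3["beta_diphtheria"]

    def test_model5_misfit_detected_without_local_dependence(self,
                                                             model5_spec):
        rng = np.random.default_rng(555)
        df = spec_sim(model5_spec, MODEL5_TRUTH, 5000, rng)
        sat = pf.saturated_loglik(df, model5_spec.observed_names)
        full = pf.fit_sem(model5_spec, df)
        stripped = model5_spec.with_fixed({
            "kappa_pfos_5": 0.0, "kappa_pfoa_5": 0.0, "kappa_pfhxs_5": 0.0,
            "kappa_pfos_7": 0.0, "kappa_pfoa_7": 0.0, "kappa_pfhxs_7": 0.0,
            "cov_eps_pfos_5_7": 0.0, "cov_eps_pfoa_5_7": 0.0,
            "cov_eps_pfhxs_5_7": 0.0})
        reduced = pf.fit_sem(stripped, df)
        t_full = pf.chi_square(full, sat)
        t_red = pf.chi_square(reduced, sat)
        assert t_red["T"] > t_full["T"] + 30
        assert t_red["p"] < 0.01


class TestDriver:
    def test_full_analysis_on_default_cohort(self):
        data = pf.generate(pf.default_config(), seed=2718)
        report = pf.run_full_analysis(
            data, pf.AnalysisConfig(models=(1, 2, 3, 5)))
        # six children are flagged for the extra booster and excluded
        assert report.n_excluded_extra_booster == 6
        assert report.n_rows == 458
        # per-chemical table: 6 regressions + 6 model-1 + 6 model-2 rows
        assert len(report.regression_table) == 18
        # joint table: model 3 at both ages plus the childhood model
        assert len(report.joint_table) == 3
        assert {"equal_effect_p", "joint_pct"} <= \
            set(report.joint_table.columns)
        assert report.errors == {}
        for name, fi in report.fit_indices.items():
            verdict = pf.assess(fi)
            assert set(verdict["criteria"]) == {
                "chi2_p_above_0.05", "rmsea_below_0.05", "cfi_above_0.95",
                "srmr_below_0.08"}
        text = report.summary()
        assert "chi2-test P" in text

    def test_driver_is_deterministic(self):
        data = pf.generate(pf.default_config(), seed=5)
        cfg = pf.AnalysisConfig(models=(3,))
        a = pf.run_full_analysis(data, cfg)
        b = pf.run_full_analysis(data, cfg)
        assert a.joint_table.equals(b.joint_table)

    def test_failures_recorded_not_raised(self):
        data = pf.generate(pf.default_config(), seed=5)
        broken = data.df.drop(columns=["pfhxs_5"])
        report = pf.run_full_analysis(broken, pf.AnalysisConfig(models=(5,)))
        assert report.errors      # model 5 needs all six PFAS columns
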