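"""FIML likelihood, optimization, standard errors and nested tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import pfasem as pf
from pfasem.estimation import EstimationError, pattern_statistics
from pfasem.spec import Variable, build_spec, free

from conftest import MODEL1_TRUTH, MODEL3_TRUTH, spec_sim, theta_from


def saturated_spec(names):
    b = []
    for i, x in enumerate(names):
        b.append((x, x, free(f"v_{x}", 1.0)))
        for y in names[i + 1:]:
            b.append((x, y, free(f"c_{x}_{y}", 0.0)))
    return build_spec([Variable(x) for x in names], bidirected=b,
                      intercepts={x: free(f"m_{x}", 0.0) for x in names})


class TestLoglik:
    def test_complete_data_equals_closed_form_mvn(self, model1_spec):
        rng = np.random.default_rng(0)
        theta = theta_from(model1_spec, MODEL1_TRUTH)
        df = model1_spec.simulate(theta, 500, rng)
        ll = pf.fiml_loglik(model1_spec, theta, df)
        mom = model1_spec.implied_moments(theta)
        closed = stats.multivariate_normal(mom.mu, mom.sigma).logpdf(
            df[mom.names].to_numpy()).sum()
        assert abs(ll - closed) < 1e-10 * abs(closed)

    def test_missing_cell_contributes_marginal_density(self, model1_spec):
        # one row missing variable j contributes the sub-vector density
        theta = theta_from(model1_spec, MODEL1_TRUTH)
        mom = model1_spec.implied_moments(theta)
        row = pd.DataFrame([{ "pfoa_5": 2.2, "pfoa_7": np.nan,
                              "anti_tetanus_7": 0.3}])
        ll = pf.fiml_loglik(model1_spec, theta, row)
        keep = [0, 2]   # pfoa_5, anti_tetanus_7 in the spec's observed order
        marginal = stats.multivariate_normal(
            mom.mu[keep], mom.sigma[np.ix_(keep, keep)]).logpdf([2.2, 0.3])
        assert abs(ll - float(marginal)) < 1e-12

    def test_row_order_invariance(self, model1_spec, model1_data):
        theta = theta_from(model1_spec, MODEL1_TRUTH)
        df = model1_data.copy()
        df.iloc[::3, 0] = np.nan
        df.iloc[::5, 2] = np.nan
        shuffled = df.sample(frac=1.0, random_state=99)
        a = pf.fiml_loglik(model1_spec, theta, df)
        b = pf.fiml_loglik(model1_spec, theta, shuffled)
        assert abs(a - b) < 1e-10 * abs(a)

    def test_all_missing_rows_dropped_and_counted(self, model1_spec,
                                                  model1_data):
        df = model1_data.copy()
        df.iloc[:7, :] = np.nan
        patterns, n_used, n_dropped = pattern_statistics(
            df, model1_spec.observed_names)
        assert n_dropped == 7
        assert n_used == len(df) - 7

    def test_inadmissible_theta_is_barrier_not_crash(self):
        spec = saturated_spec(["a", "b"])
        theta = spec.start_theta()
        theta[spec.free_labels.index("c_a_b")] = 5.0   # corr > 1: not PD
        df = pd.DataFrame({"a": [0.0, 1.0], "b": [0.0, 1.0]})
        assert pf.fiml_loglik(spec, theta, df) == -np.inf


class TestFit:
    def test_recovers_generator_parameters_large_n(self, model1_spec):
        rng = np.random.default_rng(7)
        df = spec_sim(model1_spec, MODEL1_TRUTH, 100_000, rng)
        fit = pf.fit_sem(model1_spec, df)
        assert fit.converged
        se = fit.se()
        for lab in model1_spec.free_labels:
            z = (fit[lab] - MODEL1_TRUTH[lab]) / se[lab]
            assert abs(z) < 3, f"{lab}: z={z:.2f}"

    def test_error_free_indicator_with_covariate_equals_ols(self):
        """An SEM with the exposure entering directly (no measurement
        error) must reproduce ordinary least squares exactly."""
        rng = np.random.default_rng(21)
        n = 400
        x = rng.normal(2.0, 0.5, n)
        c = rng.normal(0.0, 1.0, n)
        y = 1.0 - 0.8 * x + 0.3 * c + rng.normal(0, 1.2, n)
        df = pd.DataFrame({"x": x, "c": c, "y": y})

        spec = build_spec(
            [Variable("x", role="covariate"), Variable("c", role="covariate"),
             Variable("y", role="outcome")],
            directed=[("x", "y", free("beta_x", 0.0)),
                      ("c", "y", free("beta_c", 0.0))],
            bidirected=[("x", "x", free("v_x", 1.0)),
                        ("c", "c", free("v_c", 1.0)),
                        ("x", "c", free("c_xc", 0.0)),
                        ("y", "y", free("v_y", 1.0))],
            intercepts={"x": free("m_x", 0.0), "c": free("m_c", 0.0),
                        "y": free("m_y", 0.0)},
        )
        fit = pf.fit_sem(spec, df, pf.FitOptions(tol=1e-12, gtol=1e-9))
        assert fit.converged
        X = np.column_stack([np.ones(n), x, c])
        ols = np.linalg.solve(X.T @ X, X.T @ y)
        assert abs(fit["m_y"] - ols[0]) < 1e-6
        assert abs(fit["beta_x"] - ols[1]) < 1e-6
        assert abs(fit["beta_c"] - ols[2]) < 1e-6

    def test_zero_iterations_returns_flagged_start_values(self, model1_spec,
                                                          model1_data):
        opts = pf.FitOptions(max_iter=0)
        fit = pf.fit_sem(model1_spec, model1_data, opts)
        assert not fit.converged
        assert fit.n_iter == 0

    def test_fit_deterministic_under_row_permutation(self, model1_spec,
                                                     model1_data):
        df = model1_data.copy()
        df.iloc[::4, 1] = np.nan
        fit_a = pf.fit_sem(model1_spec, df)
        fit_b = pf.fit_sem(model1_spec, df.sample(frac=1.0, random_state=3))
        np.testing.assert_allclose(fit_a.theta, fit_b.theta, atol=1e-10)
        assert abs(fit_a.loglik - fit_b.loglik) < 1e-10 * abs(fit_a.loglik)

    def test_restarts_are_seeded_and_deterministic(self, model1_spec,
                                                   model1_data):
        opts = pf.FitOptions(restarts=2, restart_seed=11)
        a = pf.fit_sem(model1_spec, model1_data, opts)
        b = pf.fit_sem(model1_spec, model1_data, opts)
        np.testing.assert_array_equal(a.theta, b.theta)

    def test_mcar_deletion_leaves_estimates_unbiased(self, model1_spec):
        """FIML on 20% MCAR-deleted cells shows no systematic bias."""
        rng = np.random.default_rng(404)
        reps = 100
        est = []
        theta_true = theta_from(model1_spec, MODEL1_TRUTH)
        for _ in range(reps):
            df = model1_spec.simulate(theta_true, 400, rng)
            mask = rng.random(df.shape) < 0.2
            df = df.mask(mask)
            fit = pf.fit_sem(model1_spec, df)
            if fit.converged:
                est.append(fit["beta_tetanus"])
        est = np.array(est)
        assert len(est) > 0.95 * reps
        z = (est.mean() - MODEL1_TRUTH["beta_tetanus"]) / \
            (est.std(ddof=1) / np.sqrt(len(est)))
        assert abs(z) < 3


class TestVcov:
    def test_se_of_mean_matches_closed_form(self):
        rng = np.random.default_rng(5)
        x = rng.normal(10.0, 2.0, 600)
        df = pd.DataFrame({"a": x})
        spec = saturated_spec(["a"])
        fit = pf.fit_sem(spec, df)
        se = fit.se()
        sigma_hat = np.sqrt(x.var())        # ML variance estimate
        assert abs(se["m_a"] - sigma_hat / np.sqrt(len(x))) < 1e-6

    def test_invariant_under_parameter_reordering(self, model1_data):
        spec_a = saturated_spec(["pfoa_5", "pfoa_7", "anti_tetanus_7"])
        spec_b = saturated_spec(["anti_tetanus_7", "pfoa_5", "pfoa_7"])
        se_a = pf.fit_sem(spec_a, model1_data).se()
        se_b = pf.fit_sem(spec_b, model1_data).se()

        def canonical(se):
            # covariance labels depend on variable order; key by name pair
            out = {}
            for lab, v in se.items():
                if lab.startswith("c_"):
                    parts = lab[2:]
                    names = sorted(n for n in
                                   ("pfoa_5", "pfoa_7", "anti_tetanus_7")
                                   if n in parts)
                    out["cov:" + "|".join(names)] = v
                else:
                    out[lab] = v
            return out

        ca, cb = canonical(se_a), canonical(se_b)
        assert set(ca) == set(cb)
        for k in ca:
            assert abs(ca[k] - cb[k]) < 1e-7, k

    def test_matches_nonparametric_bootstrap(self, model1_spec):
        rng = np.random.default_rng(77)
        df = spec_sim(model1_spec, MODEL1_TRUTH, 2000, rng)
        fit = pf.fit_sem(model1_spec, df)
        se = fit.se()["beta_tetanus"]
        boot = []
        for _ in range(200):
            idx = rng.integers(0, len(df), len(df))
            bfit = pf.fit_sem(model1_spec, df.iloc[idx])
            boot.append(bfit["beta_tetanus"])
        boot_se = np.std(boot, ddof=1)
        assert abs(se - boot_se) / boot_se < 0.15

    def test_singular_information_is_flagged(self):
        # single indicator with free latent AND free error variance: only
        # their sum is identified, so the observed information is singular
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"x": rng.normal(size=300)})
        spec = build_spec(
            [Variable("x", role="indicator"),
             Variable("L", "latent", "latent-exposure")],
            directed=[("L", "x", pf.fixed("l", 1.0))],
            bidirected=[("x", "x", free("v_x", 0.6)),
                        ("L", "L", free("v_L", 0.6))],
            intercepts={"x": free("m_x", 0.0), "L": pf.fixed("m_L", 0.0)},
        )
        fit = pf.fit_sem(spec, df)
        with pytest.raises(EstimationError, match="information"):
            pf.vcov_observed_information(fit)


class TestLikelihoodRatio:
    def test_constraint_at_mle_gives_zero_stat(self, model3_spec):
        rng = np.random.default_rng(12)
        df = spec_sim(model3_spec, MODEL3_TRUTH, 450, rng)
        fit_full = pf.fit_sem(model3_spec, df)
        pinned = model3_spec.with_fixed(
            {"lambda_pfoa_7": fit_full["lambda_pfoa_7"]})
        fit_c = pf.fit_sem(pinned, df)
        out = pf.likelihood_ratio_test(fit_c, fit_full)
        assert out["df"] == 1
        assert out["stat"] < 1e-4
        assert out["p"] > 0.99

    def test_equality_constraint_has_one_df(self, no_covariates):
        rng = np.random.default_rng(13)
        spec_free = pf.model3_joint_latent(7, no_covariates)
        spec_eq = pf.model3_joint_latent(7, no_covariates, equal_effects=True)
        df = spec_sim(spec_free, MODEL3_TRUTH, 450, rng)
        out = pf.test_equal_effects(pf.fit_sem(spec_free, df),
                                    pf.fit_sem(spec_eq, df))
        assert out["df"] == 1
        assert 0 <= out["p"] <= 1

    def test_non_nested_rejected(self, model3_spec, model1_spec, model1_data):
        fit = pf.fit_sem(model1_spec, model1_data)
        with pytest.raises(ValueError):
            pf.likelihood_ratio_test(fit, fit)
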