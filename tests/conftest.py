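import numpy as np
import pytest

import pfasem as pf


def theta_from(spec, values):
    """Free-parameter vector with the named entries set; rest keep starts."""
    theta = spec.start_theta()
    labels = spec.free_labels
    for k, v in values.items():
        theta[labels.index(k)] = v
    return theta


# generator-truth parameter sets used by the recovery studies: chosen to be
# of the magnitude the cohort summaries imply (log2 scale throughout)
MODEL1_TRUTH = {
    "beta_tetanus": -0.9,
    "var_eps_pfoa_5": 0.15, "var_eps_pfoa_7": 0.15, "var_latent_pfoa": 0.15,
    "var_eps_tetanus": 4.0,
    "alpha_pfoa": 0.1, "mu_latent_pfoa": 2.05, "mu_anti_tetanus_7": 0.85,
}

MODEL3_TRUTH = {
    "var_latent_pfas_7": 0.12,
    "lambda_pfoa_7": 0.6, "lambda_pfhxs_7": 0.9,
    "alpha_pfos_7": 3.95, "alpha_pfoa_7": 2.1, "alpha_pfhxs_7": -1.0,
    "var_eps_pfos_7": 0.07, "var_eps_pfoa_7": 0.12, "var_eps_pfhxs_7": 0.08,
    "beta_diphtheria": -1.1, "beta_tetanus": -0.9,
    "mu_anti_diphtheria_7": -0.3, "mu_anti_tetanus_7": 0.85,
    "var_eps_diphtheria": 2.0, "var_eps_tetanus": 4.0,
    "cov_eps_antibodies": 0.9,
}

MODEL5_TRUTH = {
    "var_latent_pfas_childhood": 0.10,
    "lambda_pfoa_5": 0.5, "lambda_pfhxs_5": 0.8,
    "lambda_pfoa_7": 0.6, "lambda_pfhxs_7": 0.9,
    "alpha_pfos_5": 4.1, "alpha_pfoa_5": 2.0, "alpha_pfhxs_5": -0.7,
    "alpha_pfos_7": 3.95, "alpha_pfoa_7": 2.1, "alpha_pfhxs_7": -1.0,
    "var_eps_pfos_5": 0.06, "var_eps_pfoa_5": 0.12, "var_eps_pfhxs_5": 0.10,
    "var_eps_pfos_7": 0.07, "var_eps_pfoa_7": 0.12, "var_eps_pfhxs_7": 0.08,
    "kappa_pfos": 0.12, "kappa_pfoa": 0.10, "kappa_pfhxs": 0.15,
    "cov_eps_pfos_5_7": 0.03, "cov_eps_pfoa_5_7": 0.04,
    "cov_eps_pfhxs_5_7": 0.05,
    "beta_diphtheria": -1.1, "beta_tetanus": -0.9,
    "mu_anti_diphtheria_7": -0.3, "mu_anti_tetanus_7": 0.85,
    "var_eps_diphtheria": 2.0, "var_eps_tetanus": 4.0,
    "cov_eps_antibodies": 0.9,
}


@pytest.fixture(scope="session")
def no_covariates():
    return pf.AnalysisConfig(covariates=())


@pytest.fixture(scope="session")
def model1_spec(no_covariates):
    return pf.model1_single_pfas("pfoa", "tetanus", no_covariates)


@pytest.fixture(scope="session")
def model3_spec(no_covariates):
    return pf.model3_joint_latent(7, no_covariates)


@pytest.fixture(scope="session")
def model5_spec(no_covariates):
    return pf.model5_childhood(no_covariates)


@pytest.fixture(scope="session")
def model1_data(model1_spec):
    rng = np.random.default_rng(101)
    return spec_sim(model1_spec, MODEL1_TRUTH, 2000, rng)


def spec_sim(spec, truth, n, rng):
    return spec.simulate(theta_from(spec, truth), n, rng)
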