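import warnings

import numpy as np
import pytest

import circamix as cm

warnings.filterwarnings("ignore", category=RuntimeWarning, module="circamix")


@pytest.fixture(scope="session")
def ref_params():
    return cm.reference_params()


@pytest.fixture(scope="session")
def small_dataset():
    """60 subjects on the dense schedule, simulated at the reference truth."""
    return cm.dense_cohort(60, seed=1301)


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """A quick full-model fit shared across diagnostic tests."""
    return cm.CircadianMixedModel(small_dataset).fit(
        settings=cm.SaemSettings.fast(n_burn=120, n_iter=60, ofv_samples=200),
        seed=1302,
    )


def true_result(dataset, config=None, params=None, cv=None, sigma=None):
    """A results object carrying the generating (true) parameter values.

    Lets calibration tests evaluate simulation-based diagnostics exactly
    at the truth without an estimation step.
    """
    config = config or cm.ModelConfig(covariate_refs=(("age", 49.9),))
    params = params or cm.reference_params()
    cv = cv or dict(cm.REFERENCE_CV)
    sigma = cm.REFERENCE_SIGMA if sigma is None else sigma
    model = cm.CircadianMixedModel(dataset, config)
    estimates = {
        "t_max": params.t_max, "t_min": params.t_min,
        "amplitude": params.amplitude, "base": params.base,
        "theta_age": params.theta_age, "theta_semester1": params.theta_sem,
    }
    if config.boxcox_on_base:
        estimates["theta_boxcox"] = params.theta_boxcox
    omega = np.diag([cv[p] ** 2 for p in config.iiv_on])
    result = cm.CircadianFitResult(
        model=model, config=config, settings=None, seed=None,
        estimates=estimates, omega=omega, iiv_names=config.iiv_on,
        sigma_prop=sigma, ofv=None, ofv_se=None, rse=None, ebes=None,
        shrinkage=None, convergence={"converged": True},
    )
    result.state = result.rebuild_state()
    return result
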