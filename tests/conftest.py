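import numpy as np
import pytest

from flimlca.synthetic import CohortSpec, CovariateSpec, coin_os_spec, simulate_cohort

COVARIATES = ["trt", "ras_mut", "fret", "fret_x_her3"]


@pytest.fixture(scope="session")
def coin_cohort():
    """Default-preset cohort at the trial's size."""
    return simulate_cohort(coin_os_spec(n_patients=398, seed=123))


@pytest.fixture(scope="session")
def recovery_cohort():
    """Inflated-separation recovery cohort (n=2000)."""
    return simulate_cohort(coin_os_spec(n_patients=2000, separation=2.0, seed=7))


def single_class_spec(n_patients: int, seed: int, p_covariates: int = 4,
                      signal: float = 0.0, rate: float = 0.0014,
                      horizon: float = 1500.0) -> CohortSpec:
    """One-population cohort with standard-normal covariates; the first
    covariate carries ``signal`` as its log hazard ratio."""
    names = ([f"x{j}" for j in range(p_covariates)])
    covs = [CovariateSpec(nm, "continuous",
                          [{"dist": "normal", "mean": 0.0, "sd": 1.0}])
            for nm in names]
    beta = np.zeros((1, p_covariates))
    if p_covariates:
        beta[0, 0] = signal
    return CohortSpec(n_patients=n_patients, class_proportions=(1.0,),
                      covariate_specs=covs, class_log_hazard_coefs=beta,
                      cut_points=np.array([0.0]),
                      baseline_rates=np.array([[rate]]),
                      horizon=horizon, dropout_window=None, seed=seed)
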