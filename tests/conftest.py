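import numpy as np
import pytest

from coxianreg import CoxianParameters, RegressionCoefficients


@pytest.fixture(scope="session")
def ckd_rates() -> CoxianParameters:
    """Three-phase haemodialysis-cohort reference rates (per month) used as
    the canonical worked example throughout the package."""
    return CoxianParameters(
        np.array([0.060, 0.467, 0.0]), np.array([9.02e-11, 0.435, 0.060])
    )


@pytest.fixture(scope="session")
def ckd_coeffs() -> RegressionCoefficients:
    """Reference covariate effects for the intercept and slope deviations."""
    return RegressionCoefficients(0.246, 0.156)


def _random_separated_params(rng: np.random.Generator, n: int) -> CoxianParameters:
    """A valid parameter set whose total rates are pairwise well separated
    (>= 20% relative), so the partial-fraction expansion is well conditioned."""
    while True:
        lams = np.exp(rng.uniform(np.log(0.02), np.log(3.0), size=n))
        lams[-1] = 0.0
        mus = np.exp(rng.uniform(np.log(0.02), np.log(3.0), size=n))
        sigma = np.sort(lams + mus)
        if n == 1 or np.all(sigma[1:] / sigma[:-1] >= 1.2):
            return CoxianParameters(lams, mus)


@pytest.fixture(scope="session")
def parameter_battery() -> list:
    """24 well-separated parameter sets spanning 1-4 phases."""
    rng = np.random.default_rng(20240901)
    battery = []
    for n in (1, 2, 3, 4):
        for _ in range(6):
            battery.append(_random_separated_params(rng, n))
    return battery
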