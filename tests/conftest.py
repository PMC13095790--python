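import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import lymphodose as ld

settings.register_profile(
    "ci", deadline=None, max_examples=50, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def photon_records():
    """Small photon-like cohort reused across tests (deterministic)."""
    return ld.generate_cohort(120, ld.PHOTON_PROFILE, ld.PHOTON_TRUTH, seed=7)


@pytest.fixture(scope="session")
def photon_cohort(photon_records):
    return ld.cohort_outcomes(photon_records)


@pytest.fixture(scope="session")
def photon_fit(photon_cohort):
    return ld.fit_lkb(photon_cohort)


def random_differential_dvh(rng, n_bins=None, allow_zero=True):
    """Random valid differential DVH for property tests."""
    n = n_bins or rng.integers(2, 25)
    start = 0.0 if (allow_zero and rng.random() < 0.3) else rng.uniform(0.01, 1.0)
    doses = start + np.cumsum(rng.uniform(0.05, 2.0, n))
    if allow_zero and rng.random() < 0.3:
        doses[0] = 0.0
    fractions = rng.dirichlet(np.ones(n))
    return ld.DifferentialDVH(doses, fractions)
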