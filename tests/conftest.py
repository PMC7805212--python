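import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from ftdindex import default_nacc_params, simulate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def nacc_cohort():
    """One seeded synthetic training cohort (47 matched NC/AD/FTD triplets)."""
    config = default_nacc_params(seed=1234)
    records, matrix = simulate_cohort(config)
    return records, matrix


@pytest.fixture(scope="session")
def replicate_seeds():
    """Deterministic master-seed stream for replicate experiments."""
    def make(n, entropy=20210112):
        return [int(s) for s in np.random.SeedSequence(entropy).generate_state(n) >> 1]

    return make
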