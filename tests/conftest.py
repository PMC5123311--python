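from dataclasses import replace

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_config():
    from dipyrone_pd import default_study_config

    return default_study_config(seed=0)


@pytest.fixture(scope="session")
def noise_free_config(study_config):
    return replace(study_config, noise_rsd_pct={}, seed=0)


@pytest.fixture(scope="session")
def noise_free_dataset(noise_free_config):
    from dipyrone_pd import simulate_cohort

    return simulate_cohort(noise_free_config)


@pytest.fixture(scope="session")
def noisy_dataset(study_config):
    from dipyrone_pd import simulate_cohort

    return simulate_cohort(replace(study_config, seed=11))
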