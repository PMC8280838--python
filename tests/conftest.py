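import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from phosphotriage.synth import GeneratorConfig, generate_screen

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


SMALL = GeneratorConfig(n_proteins=300, mean_sites_per_protein=4.0, seed=5)


@pytest.fixture(scope="session")
def small_screen():
    """~1,200-site screen with default noise, for fast stage tests."""
    return generate_screen(SMALL)


@pytest.fixture(scope="session")
def noiseless_small_screen():
    return generate_screen(SMALL.noiseless())


@pytest.fixture(scope="session")
def default_screen():
    """Full-size screen at the default study conditions."""
    return generate_screen(dataclasses.replace(GeneratorConfig(), seed=101))
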