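import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced synthetic cohort (fast) with the default structure."""
    from symdyn.simulate import GeneratorConfig, generate_cohort

    return generate_cohort(GeneratorConfig(seed=11, n_patients=80))


@pytest.fixture(scope="session")
def default_cohort():
    """The full default-configuration cohort at the documented seed."""
    from symdyn.simulate import GeneratorConfig, generate_cohort

    return generate_cohort(GeneratorConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture(autouse=True)
def _quiet_statsmodels():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*convergence.*")
        yield
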