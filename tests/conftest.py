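import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_data():
    """One shared tiny two-site cohort with planted effects."""
    from gmpredict import preprocess
    from gmpredict.simulate import generate_cohort, preset_config

    config = preset_config("tiny", seed=1234)
    maps, cohort = generate_cohort(config)
    features = preprocess(maps, cohort)
    return config, maps, cohort, features


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
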