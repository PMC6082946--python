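import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_population():
    from astrosync import init_population

    return init_population(800, 200, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
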