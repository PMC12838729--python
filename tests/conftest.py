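import numpy as np
import pytest
from hypothesis import settings

from evmetrics import CoatedSphereModel, RunConfig

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def optics():
    return CoatedSphereModel()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
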