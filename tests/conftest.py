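import numpy as np
import pytest

from banmon.config import PipelineConfig
from banmon.synth import calibration_suite, make_profile


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def profile(cfg):
    """User profile derived from the standard synthetic calibration runs."""
    return make_profile(calibration_suite(seed=1000, cfg=cfg), cfg=cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
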