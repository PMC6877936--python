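import numpy as np
import pytest

from dgsim.io import preset_config


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def cfg200():
    """Default 200-GC configuration (published tables + calibrated wiring)."""
    return preset_config("200gc")
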