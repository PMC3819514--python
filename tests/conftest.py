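import numpy as np
import pytest

from countsim import ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def table1_config():
    """The reference 20,000-feature model configuration."""
    return ModelConfig()


@pytest.fixture(scope="session")
def small_config():
    """A reduced model (same marker structure, few non-markers) for
    moment-matching tests where the non-marker bulk is irrelevant."""
    return ModelConfig(D=220, D_gm=10, c=2, D_hm=50, D_hv=40, D_lv=70)
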