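import numpy as np
import pytest

from fmha_ae.model import ModelConfig, build_model


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def tiny_model():
    """A small float64 network shared by structural tests."""
    return build_model(
        ModelConfig(width=16, depth=3, heads=4, segment_length=64, seed=7)
    )


@pytest.fixture(scope="session")
def default_model():
    """The default-geometry network (width 128, depth 7); built once."""
    return build_model(ModelConfig(seed=0))
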