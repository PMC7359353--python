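import numpy as np
import pytest

from melanosim import SimConfig, build_preset


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(12345))


@pytest.fixture
def tiny_config():
    """Small, fast configuration for engine-level unit tests."""
    return build_preset("attached", {
        "n_organelles": 10,
        "duration": 2.0,
        "seed": 7,
    })
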