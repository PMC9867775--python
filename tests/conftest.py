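import numpy as np
import pytest

from pggcoop import SimParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_params():
    return SimParams()


@pytest.fixture
def small_params():
    """A fast condition for dynamics tests: 30% altruists, beta=0.5."""
    return SimParams(
        altruist_fraction=0.3,
        noise=0.5,
        stubbornness=1.0,
        generations=50,
        replicates=2,
        base_seed=7,
    )
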