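import numpy as np
import pytest

from exactroc.models import BinormalModel


@pytest.fixture(scope="session")
def equal_model():
    """Null model with identical TP and TN distributions (F = G)."""
    return BinormalModel(delta=0.0)


@pytest.fixture(scope="session")
def unit_model():
    """Binormal model with unit mean difference."""
    return BinormalModel(delta=1.0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230315)
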