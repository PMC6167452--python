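import numpy as np
import pytest

from emgsynergy.synthetic import make_prototypes


@pytest.fixture(scope="session")
def prototypes() -> np.ndarray:
    """Ten sparse unit prototype synergies over 12 channels."""
    return make_prototypes(n_channels=12, n_prototypes=10, seed=1)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
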