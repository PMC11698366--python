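import numpy as np
import pytest

from tlechen import TlecParams, load_dataset

# Reference parameter vectors used across the suite: a left-skewed set with
# all shapes below 1, the three simulation presets, and an all-above-one set.
BASE = TlecParams(0.6, 0.9, 0.5, 0.3)
CASES = {
    1: TlecParams(0.6, 0.9, 0.5, 0.3),
    2: TlecParams(0.7, 0.4, 0.1, 0.3),
    3: TlecParams(1.2, 1.5, 1.3, 1.4),
}


@pytest.fixture(scope="session")
def base_params():
    return BASE


@pytest.fixture(scope="session")
def infected():
    return load_dataset("infected")


@pytest.fixture(scope="session")
def recovered():
    return load_dataset("recovered")


@pytest.fixture(scope="session")
def random_param_draws():
    """Seeded batch of valid parameter vectors spanning the moderate regime."""
    rng = np.random.default_rng(20240901)
    draws = np.exp(rng.uniform(np.log(0.2), np.log(3.0), size=(20, 4)))
    return [TlecParams(*row) for row in draws]
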