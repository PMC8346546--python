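import numpy as np
import pytest

from fuzzymsc import ParameterSet, default_controller


@pytest.fixture(scope="session")
def params():
    return ParameterSet()


@pytest.fixture(scope="session")
def controller(params):
    return default_controller(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_input_batch(rng, n):
    """Wide-ranging random controller inputs covering all membership bands."""
    return {
        "maturity": rng.uniform(0.0, 1.0, n),
        "dna_damage": rng.integers(0, 2, n).astype(float),
        "mg": rng.uniform(0.0, 80.0, n),
        "alkalinity": rng.uniform(0.0, 2.5, n),
        "bmp2": rng.uniform(0.0, 2500.0, n),
        "tgfb1": rng.uniform(0.0, 80.0, n),
        "density": rng.uniform(0.0, 1.0, n),
    }
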