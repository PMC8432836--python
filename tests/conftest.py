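import numpy as np
import pytest

from equigof import get_model, sample_lehmann

#: seed for the regenerated worked-example sample (n=100 standard-normal draws)
EXAMPLE_SEED = 1729


@pytest.fixture(scope="session")
def std_normal():
    return get_model("standard_normal")


@pytest.fixture(scope="session")
def std_expon():
    return get_model("exponential")


@pytest.fixture(scope="session")
def example_sample(std_normal):
    """Synthetic stand-in for the worked-example dataset: n=100 draws from
    the perfectly fitting model (theta = 1, standard normal), fixed seed."""
    return sample_lehmann(std_normal, theta=1.0, n=100, seed=EXAMPLE_SEED)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(8675309)
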