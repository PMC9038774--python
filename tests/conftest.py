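import numpy as np
import pytest

from viromine import Parameters, SynthDesign, simulate


@pytest.fixture(scope="session")
def params():
    return Parameters()


@pytest.fixture(scope="session")
def default_dataset():
    """One baseline synthetic community shared by read-only tests."""
    return simulate(SynthDesign(rng_seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def random_dna(rng, length):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
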