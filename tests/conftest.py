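import numpy as np
import pytest
from hypothesis import settings

from hatscan.synthetic_data import but2_fixtures

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20240217)


@pytest.fixture(scope="session")
def fixtures():
    """Bundled BuT2 primers and structural constants."""
    return but2_fixtures()


def random_dna(rng, n, gc=0.5):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
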