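import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lphash.io_spss import synthetic_spss
from lphash.kmer_minimizer import DensityRegimeWarning, decode_dna

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# Small minimizer lengths are exercised on purpose to stress the
# ambiguous-minimizer machinery; silence the density-regime advisory.
pytestmark = pytest.mark.filterwarnings("ignore::UserWarning")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0xC0FFEE)


@pytest.fixture
def random_dna(rng):
    def make(length: int) -> str:
        return decode_dna(rng.integers(0, 4, length).astype(np.uint8))

    return make


@pytest.fixture(scope="session")
def small_spss():
    """A mid-sized SPSS shared by read-only tests."""
    return synthetic_spss(20_000, 31, n_strings=4, seed=17)
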