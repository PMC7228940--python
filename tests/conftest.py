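import numpy as np
import pytest

from splicepipe.substrates import AMINO_ACIDS, Substrate


@pytest.fixture
def unique_substrate():
    """Substrate with 20 unique letters: every peptide has a unique explanation."""
    return Substrate("UNI", AMINO_ACIDS)


@pytest.fixture
def small_substrate():
    return Substrate("S6", "ACDEFG")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


def random_substrate(rng, length, sid="R"):
    letters = np.array(list(AMINO_ACIDS))
    return Substrate(sid, "".join(rng.choice(letters, size=length)))
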