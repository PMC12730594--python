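import numpy as np
import pytest

from tetpipe.seqsim import archetype_specs


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture
def archetypes():
    return archetype_specs()


def random_dna(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
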