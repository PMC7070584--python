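import numpy as np
import pytest

from phrynopep.synthetic import generate_transcriptome


@pytest.fixture(scope="session")
def small_transcriptome():
    """5 precursors + 15 decoys, fixed seed, reused across read-only tests."""
    return generate_transcriptome(5, 15, rng_seed=2)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
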