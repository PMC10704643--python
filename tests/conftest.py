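import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def dna2():
    from porecall import build_kmer_alphabet

    return build_kmer_alphabet(2)


@pytest.fixture(scope="session")
def dna3():
    from porecall import build_kmer_alphabet

    return build_kmer_alphabet(3)
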