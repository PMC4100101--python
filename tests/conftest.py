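import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def random_cds(rng):
    """Factory for random in-frame coding sequences without stops."""
    from carptrx.ng86 import SENSE_CODONS

    def make(n_codons: int) -> str:
        return "".join(SENSE_CODONS[i]
                       for i in rng.integers(len(SENSE_CODONS), size=n_codons))

    return make
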