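import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from orthodiverge.codons import SENSE_CODONS  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_codon_pairs(rng):
    """Factory: n random sense-codon pairs, some identical, some divergent."""

    def make(n_codons: int):
        codons = list(SENSE_CODONS)
        out = []
        for _ in range(n_codons):
            a = codons[rng.integers(len(codons))]
            if rng.random() < 0.5:
                b = a
            else:
                b = codons[rng.integers(len(codons))]
            out.append((a, b))
        return out

    return make
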