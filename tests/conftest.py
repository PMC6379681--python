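import numpy as np
import pytest

from topocleave.ends_profiles import GenomeSequence


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_genome(rng):
    seq = "".join("ACGT"[c] for c in rng.integers(0, 4, 1000))
    return GenomeSequence(contig_id="chr", sequence=seq, circular=True)


@pytest.fixture
def linear_genome(rng):
    seq = "".join("ACGT"[c] for c in rng.integers(0, 4, 500))
    return GenomeSequence(contig_id="lin", sequence=seq, circular=False)
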