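import numpy as np
import pytest

from lacunaseq import NucleotideSequence, mtdna_like_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def small_reference():
    """A short CpG-depleted mtDNA-like reference (fast pipeline fixture)."""
    return mtdna_like_sequence(seed=11, length=4000)


@pytest.fixture
def acgt():
    return NucleotideSequence("acgt", name="toy")
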