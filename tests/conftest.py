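import numpy as np
import pytest

from prophagekit import synth

# The published attachment-site sequences of the impaired 26-bp core:
# hybrid sites before induction (attL/attR) and the phage site observed
# on the excised circle (attP).
VNP2_ATTL = "CAGCCCACTTTTTTCTTCTTTGATTA"
VNP2_ATTR = "CAGCCGACATTCTTCTTCTTTGACTA"
VNP2_ATTP = "CAGCCGACATTCTTCTTCTTTGATTA"
VNP1_CORE = "TAGATTTGTGTGGT"


@pytest.fixture(scope="session")
def truth():
    """Default synthetic host chromosome with two implanted prophages."""
    return synth.generate_host_genome(seed=11)


@pytest.fixture(scope="session")
def coverage(truth):
    """One supernatant-sequencing coverage realisation of the default truth."""
    return synth.simulate_supernatant_coverage(truth, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
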