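import numpy as np
import pytest

from qtronset import ALLELES, CallerConfig, ReadSimConfig, RepeatLocus, build_allele_sequence
from qtronset.simulate import simulate_reads


@pytest.fixture(scope="session")
def locus():
    return RepeatLocus()


@pytest.fixture(scope="session")
def caller_config():
    return CallerConfig()


@pytest.fixture(scope="session")
def haplotypes(locus):
    return {name: build_allele_sequence(spec, locus) for name, spec in ALLELES.items()}


@pytest.fixture(scope="session")
def make_reads(haplotypes):
    """Factory: error-free 30x paired reads for an allele pair."""

    def _make(a, b, seed=1, **kwargs):
        cfg = ReadSimConfig(seed=seed, **kwargs)
        rng = np.random.default_rng(seed)
        return simulate_reads(haplotypes[a], haplotypes[b], cfg, rng=rng)[0]

    return _make
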