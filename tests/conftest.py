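import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from spaceraq import GenomeRecord, LocusModel, OrfFeature
from spaceraq.config import default_loci


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def loci():
    return default_loci()


@pytest.fixture
def iic(loci):
    """Array-to-leader (II-C style) locus: downstream SAM."""
    return loci[0]


@pytest.fixture
def vib(loci):
    """Leader-to-array (VI-B style) locus: upstream SAM."""
    return loci[1]


def random_seq(rng, n, gc=0.5):
    at = (1 - gc) / 2
    return "".join(rng.choice(list("ACGT"), size=n, p=[at, gc / 2, gc / 2, at]))


@pytest.fixture
def toy_genome(rng):
    seq = random_seq(rng, 2000, gc=0.4)
    feats = [
        OrfFeature(id="orfA", start=100, end=700, strand="+"),
        OrfFeature(id="orfB", start=800, end=1400, strand="-"),
    ]
    return GenomeRecord(id="toy", sequence=seq, topology="linear", features=feats)
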