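import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from telotide import build_motif_set
from telotide.read_io import ReadRecord
from telotide.simulate import scrub_subtelomere, _random_seq

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def motifs():
    return build_motif_set("GGTTAG")


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_917)


def make_read(seq, read_id="r1", qual=20, oriented=False, strand="unset"):
    rec = ReadRecord(read_id, seq, np.full(len(seq), qual, dtype=np.uint8))
    rec.oriented = oriented
    rec.strand_tag = strand
    return rec


def scrubbed(n, motifs, seed):
    """Random motif-free background sequence."""
    return scrub_subtelomere(_random_seq(n, np.random.default_rng(seed)), motifs)


@pytest.fixture()
def make_read_fn():
    return make_read


@pytest.fixture()
def scrubbed_fn(motifs):
    return lambda n, seed=0: scrubbed(n, motifs, seed)
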