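import numpy as np
import pytest

from nucleoidgcc import InteractionNetwork, SynthConfig, digest_genome, make_genome


@pytest.fixture
def toy_map():
    """L=20 circular genome with two HhaI sites: cuts at 7 and 15,
    fragments [7,15) and [15,7)."""
    return digest_genome("AAAAGCGCAAAAGCGCAAAA")


@pytest.fixture
def small_genome():
    """Deterministic ~200-fragment synthetic genome (50 kb)."""
    cfg = SynthConfig(genome_length=50_000, seed=42)
    seq, gmap = make_genome(cfg)
    return cfg, seq, gmap


def make_net(gmap, counts, condition="EXP", cutoff_applied=True):
    net = InteractionNetwork(gmap, condition, dict(counts), cutoff=0,
                             cutoff_applied=cutoff_applied)
    return net


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
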