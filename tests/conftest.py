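import numpy as np
import pytest

from txome_consensus.seqio import Contig
from txome_consensus.simulate import SimConfig, simulate_transcriptome

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode("ascii")


@pytest.fixture(scope="session")
def small_transcriptome():
    """50 deterministic transcripts with expression weights."""
    cfg = SimConfig(n_transcripts=50, seed=1234)
    transcripts, weights = simulate_transcriptome(cfg)
    return cfg, transcripts, weights


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
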