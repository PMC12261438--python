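import numpy as np
import pytest

from near.model import EmbeddingModel, ModelConfig
from near.sequences import ProteinSequence
from near.simulate import ROBINSON_FREQS, _random_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_model():
    """Small untrained model; embeddings are deterministic given the seed."""
    return EmbeddingModel(ModelConfig(embed_dim=8, n_blocks=2, kernel_size=5), seed=7)


def random_protein(rng, length, sid="seq"):
    return ProteinSequence(sid, _random_sequence(length, ROBINSON_FREQS, rng))


@pytest.fixture
def random_proteins(rng):
    def make(n, lo=20, hi=60, prefix="s"):
        return [
            random_protein(rng, int(rng.integers(lo, hi + 1)), f"{prefix}{i}")
            for i in range(n)
        ]
    return make
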