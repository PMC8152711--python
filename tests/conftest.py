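import numpy as np
import pytest

from screensift.representations import WordVectors
from screensift.synthdata import SynthConfig, generate_corpus, train_toy_embeddings


@pytest.fixture(scope="session")
def tiny_synth():
    """A small labelled corpus with clustered eligibles (session-cached)."""
    return generate_corpus(SynthConfig(n_docs=300, seed=7, n_seeds=3))


@pytest.fixture(scope="session")
def tiny_word_vectors(tiny_synth):
    return train_toy_embeddings(tiny_synth.corpus, D=16, seed=11)


@pytest.fixture()
def toy_wv():
    """Hand-sized word vectors for arithmetic checks."""
    rng = np.random.default_rng(5)
    words = [f"t{i}" for i in range(12)]
    return WordVectors({w: rng.standard_normal(4) for w in words})
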