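import numpy as np
import pytest

from infocurve.corpus import corpus_from_sentences


def random_toy_corpus(rng, vocab_size=None, n_sentences=None, max_len=8):
    """A small random corpus for smoothing/entropy tests."""
    v = vocab_size or int(rng.integers(5, 20))
    n = n_sentences or int(rng.integers(10, 50))
    sents = [
        [f"w{rng.integers(0, v)}" for _ in range(int(rng.integers(1, max_len + 1)))]
        for _ in range(n)
    ]
    return corpus_from_sentences(sents)


@pytest.fixture
def tiny_corpus():
    return corpus_from_sentences([["a", "b"], ["a", "c"], ["b", "a", "c"]])


@pytest.fixture
def rng():
    return np.random.default_rng(20250929)
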