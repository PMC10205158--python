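import numpy as np
import pytest

from lexrsa import (
    SyntheticConfig,
    affective_similarity,
    embedding_similarity,
    generate_word_set,
)


@pytest.fixture(scope="session")
def word_bundle():
    """One deterministic synthetic word set shared across the suite."""
    return generate_word_set(SyntheticConfig(), seed=7)


@pytest.fixture(scope="session")
def models(word_bundle):
    return {
        "embedding": embedding_similarity(word_bundle.embeddings),
        "affective": affective_similarity(word_bundle.ratings),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
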