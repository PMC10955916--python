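import numpy as np
import pytest

from stressclust import (
    EnsembleConfig,
    GeneratorConfig,
    build_term_document_matrix,
    compute_tfidf,
    generate_corpus,
)


@pytest.fixture(scope="session")
def default_corpus():
    """Synthetic two-group corpus at generator defaults (seed 0)."""
    corpus, roles = generate_corpus(GeneratorConfig(seed=0))
    return corpus, roles


@pytest.fixture(scope="session")
def default_tfidf(default_corpus):
    corpus, _ = default_corpus
    return compute_tfidf(build_term_document_matrix(corpus))


@pytest.fixture
def small_config():
    """A light ensemble configuration for tests that rerun the pipeline."""
    return EnsembleConfig(n_topics=5, n_seeds=8, max_iter=150)


def random_tfidf_weights(rng, n_docs, n_terms):
    """Row-L2-normalized nonnegative matrix mimicking TF-IDF output."""
    X = rng.random((n_docs, n_terms)) * (rng.random((n_docs, n_terms)) < 0.5)
    X[X.sum(axis=1) == 0, 0] = 1.0
    return X / np.linalg.norm(X, axis=1, keepdims=True)
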