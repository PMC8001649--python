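import numpy as np
import pytest

import littrend as lt


@pytest.fixture(scope="session")
def toy_corpus():
    """Three-document corpus small enough to evaluate TF-IDF by hand."""
    return lt.Corpus(
        [
            lt.Document("d1", "gene tumor gene"),
            lt.Document("d2", "tumor cell"),
            lt.Document("d3", "cell cell drug"),
        ]
    )


@pytest.fixture(scope="session")
def small_topic_corpus():
    """3 topics x 20 docs: big enough to embed, small enough for unit tests."""
    spec = lt.GeneratorSpec(
        n_topics=3, docs_per_topic=20, background_vocab_size=100,
        topic_vocab_size=20, doc_length_mean=50.0, seed=11,
    )
    return lt.generate_topic_corpus(spec)


@pytest.fixture(scope="session")
def small_table(small_topic_corpus):
    corpus, _ = small_topic_corpus
    return lt.train_word_vectors(
        corpus, lt.Word2VecConfig(dimension=30, epochs=3, seed=3)
    )


@pytest.fixture
def tiny_table():
    """Hand-built 2-D vector table for exact arithmetic checks."""
    return lt.WordVectorTable(
        dimension=2,
        vectors={
            "aa": np.array([1.0, 0.0]),
            "bb": np.array([0.0, 1.0]),
            "cc": np.array([1.0, 1.0]),
        },
    )
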