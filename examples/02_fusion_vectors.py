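"""Build fused document vectors and see topic structure emerge.

Trains skip-gram embeddings on a synthetic two-topic corpus, builds the
mean-of-vectors baseline and the TextRank-weighted fusion (Tr-W2v), and
shows that same-topic documents are closer in cosine than cross-topic ones.
"""

import numpy as np

import littrend as lt

spec = lt.GeneratorSpec(
    n_topics=2, docs_per_topic=40, background_vocab_size=150,
    topic_vocab_size=25, doc_length_mean=50.0, seed=8,
)
corpus, truth = lt.generate_topic_corpus(spec)
table = lt.train_word_vectors(
    corpus, lt.Word2VecConfig(dimension=40, epochs=5, seed=0)
)


def mean_cosines(dvs):
    X = np.stack([d.vector for d in dvs])
    X = X / np.linalg.norm(X, axis=1, keepdims=True)
    labels = np.array([truth.topic_of[d.doc_id] for d in dvs])
    C = X @ X.T
    same = C[np.equal.outer(labels, labels) & ~np.eye(len(X), dtype=bool)]
    cross = C[~np.equal.outer(labels, labels)]
    return same.mean(), cross.mean()


for method in ("mean", "tr-w2v"):
    dvs = lt.corpus_document_vectors(corpus, table, method)
    same, cross = mean_cosines(dvs)
    print(f"{method:7s}  same-topic cosine {same:.3f}   cross-topic {cross:.3f}")

print(
    "\nSame-topic documents are consistently closer; weighting by TextRank "
    "emphasizes each document's salient vocabulary over shared background."
)
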