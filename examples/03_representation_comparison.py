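"""Compare five text representations by k-means clustering quality.

Vectorizes a synthetic 3-topic corpus under the sparse TF-IDF and TextRank
representations, the mean-embedding baseline, and the Ti-W2v / Tr-W2v
fusions, clusters each with k-means and reports silhouette coefficients
plus agreement with the planted topics.
"""

import littrend as lt

spec = lt.GeneratorSpec(
    n_topics=3, docs_per_topic=40, background_vocab_size=200,
    topic_vocab_size=30, doc_length_mean=60.0, seed=4,
)
corpus, truth = lt.generate_topic_corpus(spec)
table = lt.train_word_vectors(
    corpus, lt.Word2VecConfig(dimension=50, epochs=5, seed=0)
)

reports = lt.compare_representations(
    corpus,
    ["tfidf-vector", "textrank-vector", "mean-w2v", "ti-w2v", "tr-w2v"],
    k=3, seeds=[0, 1, 2], table=table, truth=truth.topic_of,
)

print(f"{'representation':18s} {'mean silhouette':>16s} {'ARI vs truth':>13s}")
for r in reports:
    print(f"{r.representation:18s} {r.mean_silhouette:16.3f} {r.agreement:13.3f}")

print(
    "\nHigher silhouette = tighter, better-separated clusters; ARI = 1 means "
    "the clustering exactly recovers the planted topics. Dense embedding "
    "representations typically separate this corpus far better than the "
    "sparse term-weight vectors."
)
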