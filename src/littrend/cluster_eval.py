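"""Clustering-based comparison of text representations.

Protocol: vectorize the corpus under each representation, partition the
vectors with k-means (k-means++ initialization, up to 300 Lloyd
iterations), and score the partition with the mean silhouette coefficient
(b - a) / max(a, b).  Representations compared:

* ``tfidf-vector`` / ``textrank-vector`` — the document as its sparse
  term-weight vector over the full corpus vocabulary;
* ``mean-w2v`` — average of word embeddings;
* ``ti-w2v`` / ``tr-w2v`` — weighted embedding fusion.

Silhouette and Lloyd's algorithm run through scikit-learn.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .corpus_io import Corpus, TokenizerConfig, tokenize
from .fusion_embedding import DocumentVector, WordVectorTable, corpus_document_vectors
from .term_weighting import (
    TextRankConfig,
    build_cooccurrence_graph,
    term_counts,
    textrank_scores,
    tfidf_weights,
)

__all__ = [
    "Partition",
    "EvalReport",
    "KNOWN_REPRESENTATIONS",
    "kmeans_partition",
    "silhouette",
    "sparse_weight_matrix",
    "representation_matrix",
    "compare_representations",
]

KNOWN_REPRESENTATIONS = ("tfidf-vector", "textrank-vector", "mean-w2v", "ti-w2v", "tr-w2v")


@dataclass(frozen=True)
class Partition:
    labels: dict[str, int]  # doc_id -> cluster label in 0..k-1
    k: int
    inertia: float
    seed: int

    def label_array(self, doc_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.labels[d] for d in doc_ids])


@dataclass
class EvalReport:
    """Silhouette (mean and per-seed) for one representation."""

    representation: str
    silhouettes: list[float]
    seeds: list[int]
    agreement: float | None = None  # adjusted Rand vs. ground truth, if known
    config: dict = field(default_factory=dict)

    @property
    def mean_silhouette(self) -> float:
        return float(np.mean(self.silhouettes))


def _as_matrix(vectors: Sequence[DocumentVector]) -> tuple[np.ndarray, list[str]]:
    ids = [dv.doc_id for dv in vectors]
    return np.stack([dv.vector for dv in vectors]), ids


def kmeans_partition(
    vectors: Sequence[DocumentVector] | np.ndarray,
    k: int,
    seed: int = 0,
    max_iterations: int = 300,
    doc_ids: Sequence[str] | None = None,
) -> Partition:
    """k-means with k-means++ initialization; deterministic given the seed."""
    if isinstance(vectors, np.ndarray):
        X = vectors
        ids = list(doc_ids) if doc_ids is not None else [str(i) for i in range(len(X))]
    else:
        X, ids = _as_matrix(vectors)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must satisfy 1 <= k <= {n}, got {k}")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=10,
        max_iter=max_iterations,
        random_state=seed,
    ).fit(X)
    return Partition(
        labels={d: int(l) for d, l in zip(ids, km.labels_)},
        k=k,
        inertia=float(km.inertia_),
        seed=seed,
    )


def silhouette(
    vectors: Sequence[DocumentVector] | np.ndarray,
    partition: Partition | Sequence[int],
    metric: str = "euclidean",
) -> float:
    """Mean silhouette coefficient of a partition; requires >= 2 clusters."""
    if isinstance(vectors, np.ndarray):
        X = vectors
        ids = [str(i) for i in range(len(X))]
    else:
        X, ids = _as_matrix(vectors)
    if isinstance(partition, Partition):
        labels = partition.label_array(ids)
    else:
        labels = np.asarray(partition)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    if X.shape[0] < 3:
        raise ValueError("silhouette requires at least 3 points")
    return float(silhouette_score(X, labels, metric=metric))


def sparse_weight_matrix(
    weight_maps: Sequence[dict[str, float]],
) -> tuple[np.ndarray, list[str]]:
    """Documents as term-weight vectors over the union vocabulary.

    Terms absent from a document get weight 0.  Columns are ordered by
    sorted vocabulary for reproducibility.
    """
    vocab = sorted({t for wm in weight_maps for t in wm})
    col = {t: i for i, t in enumerate(vocab)}
    X = np.zeros((len(weight_maps), len(vocab)))
    for i, wm in enumerate(weight_maps):
        for t, w in wm.items():
            X[i, col[t]] = w
    return X, vocab


def representation_matrix(
    corpus: Corpus,
    representation: str,
    table: WordVectorTable | None = None,
    *,
    tokenizer: TokenizerConfig | None = None,
    textrank_config: TextRankConfig | None = None,
) -> np.ndarray:
    """Document-by-feature matrix for one named representation."""
    if representation not in KNOWN_REPRESENTATIONS:
        raise ValueError(
            f"unknown representation {representation!r}; expected one of {KNOWN_REPRESENTATIONS}"
        )
    token_lists = [tokenize(doc.text, tokenizer) for doc in corpus]
    if representation == "tfidf-vector":
        maps = tfidf_weights([term_counts(toks) for toks in token_lists])
        return sparse_weight_matrix(maps)[0]
    if representation == "textrank-vector":
        trc = textrank_config or TextRankConfig()
        maps = []
        for toks in token_lists:
            if not toks:
                maps.append({})
                continue
            graph = build_cooccurrence_graph(toks, trc.window_size)
            maps.append(textrank_scores(graph, trc).scores)
        return sparse_weight_matrix(maps)[0]
    if table is None:
        raise ValueError(f"representation {representation!r} needs a word-vector table")
    method = {"mean-w2v": "mean", "ti-w2v": "ti-w2v", "tr-w2v": "tr-w2v"}[representation]
    dvs = corpus_document_vectors(
        corpus, table, method, tokenizer=tokenizer, textrank_config=textrank_config
    )
    return np.stack([dv.vector for dv in dvs])


def compare_representations(
    corpus: Corpus,
    representations: Sequence[str],
    k: int = 10,
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    table: WordVectorTable | None = None,
    *,
    truth: dict[str, int] | None = None,
    tokenizer: TokenizerConfig | None = None,
    textrank_config: TextRankConfig | None = None,
) -> list[EvalReport]:
    """Run the k-means + silhouette protocol for each representation.

    With a ground-truth labeling (synthetic corpora), the report also
    carries the adjusted Rand agreement of the first seed's partition.
    """
    doc_ids = [doc.doc_id for doc in corpus]
    reports = []
    for rep in representations:
        X = representation_matrix(
            corpus, rep, table, tokenizer=tokenizer, textrank_config=textrank_config
        )
        sils, agreement = [], None
        for i, seed in enumerate(seeds):
            part = kmeans_partition(X, k, seed=seed, doc_ids=doc_ids)
            sils.append(silhouette(X, part.label_array(doc_ids)))
            if i == 0 and truth is not None:
                true_labels = [truth[d] for d in doc_ids]
                agreement = float(
                    adjusted_rand_score(true_labels, part.label_array(doc_ids))
                )
        reports.append(
            EvalReport(
                representation=rep,
                silhouettes=sils,
                seeds=list(seeds),
                agreement=agreement,
                config={"k": k},
            )
        )
    return reports
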