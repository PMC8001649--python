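"""Document vectors from word embeddings: mean baseline, Ti-W2v, Tr-W2v.

The classic baseline represents a document as the average of its word
vectors, treating every word as equally important.  The two fusion
representations instead weight each word vector before summing:

* **Ti-W2v** — weights are the document's TF-IDF values.
* **Tr-W2v** — weights are the document's TextRank vertex scores, computed
  on its own co-occurrence graph.

In both cases the document vector is ``V = Σ_j ŵ_j · v_j`` over tokens
present in both the weight map and the vector table.  By default the
weights are normalized to sum to one, which keeps fused vectors on the
same scale as the mean baseline; raw mode applies the weights as given.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .corpus_io import Corpus, TokenizerConfig, tokenize
from .term_weighting import (
    TextRankConfig,
    build_cooccurrence_graph,
    term_counts,
    textrank_scores,
    tfidf_weights,
)
from .word2vec import Word2VecConfig, train_embeddings

__all__ = [
    "WordVectorTable",
    "DocumentVector",
    "train_word_vectors",
    "load_word_vectors",
    "save_word_vectors",
    "fused_document_vector",
    "mean_document_vector",
    "corpus_document_vectors",
]


@dataclass
class WordVectorTable:
    """Term -> D-dimensional vector lookup with training metadata."""

    dimension: int
    vectors: dict[str, np.ndarray]
    mode: str = "pretrained"  # cbow | skipgram | pretrained
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t, v in self.vectors.items():
            if v.shape != (self.dimension,):
                raise ValueError(
                    f"vector for {t!r} has length {v.shape}, expected {self.dimension}"
                )

    def __len__(self) -> int:
        return len(self.vectors)

    def __contains__(self, term: str) -> bool:
        return term in self.vectors

    def get(self, term: str) -> np.ndarray | None:
        """Vector for a term, or None if absent (distinct from a zero vector)."""
        return self.vectors.get(term)


@dataclass(frozen=True)
class DocumentVector:
    doc_id: str
    vector: np.ndarray
    coverage: float  # fraction of the document's tokens found in the table

    def __post_init__(self) -> None:
        if not 0.0 <= self.coverage <= 1.0:
            raise ValueError("coverage must lie in [0, 1]")
        if not np.all(np.isfinite(self.vector)):
            raise ValueError("document vector must be finite")


def train_word_vectors(
    corpus: Corpus,
    config: Word2VecConfig | None = None,
    tokenizer: TokenizerConfig | None = None,
) -> WordVectorTable:
    """Train embeddings on a corpus (one sentence per document)."""
    config = config or Word2VecConfig()
    sentences = [tokenize(doc.text, tokenizer) for doc in corpus]
    vocab, matrix = train_embeddings(sentences, config)
    return WordVectorTable(
        dimension=config.dimension,
        vectors={t: matrix[i] for i, t in enumerate(vocab)},
        mode=config.mode,
        seed=config.seed,
        metadata={"epochs": config.epochs, "window": config.window},
    )


def load_word_vectors(path: str | Path) -> WordVectorTable:
    """Read the plain-text word-vector dialect (optional ``count dim`` header).

    Each data line is a term followed by D whitespace-separated floats.
    Duplicate terms keep the last occurrence with a warning; a row whose
    float count disagrees with D raises, naming the line.
    """
    path = Path(path)
    vectors: dict[str, np.ndarray] = {}
    dim: int | None = None
    with path.open("r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    start = 0
    if lines:
        first = lines[0].split()
        if len(first) == 2 and all(p.isdigit() for p in first):
            dim = int(first[1])
            start = 1
    for lineno, line in enumerate(lines[start:], start=start + 1):
        parts = line.split()
        term, floats = parts[0], parts[1:]
        try:
            vec = np.array([float(x) for x in floats])
        except ValueError:
            raise ValueError(f"line {lineno}: non-numeric vector entry")
        if dim is None:
            dim = len(vec)
        if len(vec) != dim:
            raise ValueError(
                f"line {lineno}: expected {dim} floats, found {len(vec)}"
            )
        if term in vectors:
            warnings.warn(f"duplicate term {term!r}; keeping the last occurrence")
        vectors[term] = vec
    if dim is None:
        raise ValueError(f"{path}: no vectors found")
    return WordVectorTable(dimension=dim, vectors=vectors, mode="pretrained")


def save_word_vectors(table: WordVectorTable, path: str | Path) -> None:
    """Write the table in the plain-text dialect with a ``count dim`` header."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(f"{len(table.vectors)} {table.dimension}\n")
        for term, vec in table.vectors.items():
            fh.write(term + " " + " ".join(repr(float(x)) for x in vec) + "\n")


def fused_document_vector(
    tokens: Sequence[str],
    weights: Mapping[str, float],
    table: WordVectorTable,
    *,
    doc_id: str = "",
    normalize: bool = True,
) -> DocumentVector:
    """Weighted sum of word vectors over tokens covered by weights and table.

    With ``normalize`` (default) the participating weights are rescaled to
    sum to one first.  A document with no covered token yields the zero
    vector, coverage 0, and a warning.
    """
    vocab = set(tokens)
    active = [
        (t, w) for t, w in weights.items() if t in vocab and table.get(t) is not None
    ]
    n_tokens = len(tokens)
    covered = sum(1 for t in tokens if table.get(t) is not None and t in weights)
    coverage = covered / n_tokens if n_tokens else 0.0
    if not active:
        warnings.warn(f"document {doc_id!r}: no token covered by weights and table")
        return DocumentVector(doc_id, np.zeros(table.dimension), 0.0)
    w = np.array([x for _, x in active])
    if normalize:
        total = w.sum()
        if total != 0:
            w = w / total
    mat = np.stack([table.vectors[t] for t, _ in active])
    return DocumentVector(doc_id, w @ mat, coverage)


def mean_document_vector(
    tokens: Sequence[str], table: WordVectorTable, *, doc_id: str = ""
) -> DocumentVector:
    """Occurrence-weighted average of the in-table word vectors."""
    in_table = [t for t in tokens if table.get(t) is not None]
    coverage = len(in_table) / len(tokens) if tokens else 0.0
    if not in_table:
        warnings.warn(f"document {doc_id!r}: no token found in the vector table")
        return DocumentVector(doc_id, np.zeros(table.dimension), 0.0)
    mat = np.stack([table.vectors[t] for t in in_table])
    return DocumentVector(doc_id, mat.mean(axis=0), coverage)


def corpus_document_vectors(
    corpus: Corpus,
    table: WordVectorTable,
    method: str = "tr-w2v",
    *,
    tokenizer: TokenizerConfig | None = None,
    textrank_config: TextRankConfig | None = None,
    normalize: bool = True,
) -> list[DocumentVector]:
    """Build one document vector per corpus document.

    ``method`` is one of ``mean`` (plain average), ``ti-w2v`` (TF-IDF
    weighted fusion) or ``tr-w2v`` (TextRank weighted fusion).
    """
    token_lists = [tokenize(doc.text, tokenizer) for doc in corpus]
    if method == "mean":
        return [
            mean_document_vector(toks, table, doc_id=doc.doc_id)
            for doc, toks in zip(corpus, token_lists)
        ]
    if method == "ti-w2v":
        weight_maps = tfidf_weights([term_counts(toks) for toks in token_lists])
    elif method == "tr-w2v":
        trc = textrank_config or TextRankConfig()
        weight_maps = []
        for toks in token_lists:
            if not toks:
                weight_maps.append({})
                continue
            graph = build_cooccurrence_graph(toks, trc.window_size)
            weight_maps.append(textrank_scores(graph, trc).scores)
    else:
        raise ValueError(f"unknown method {method!r}; expected mean|ti-w2v|tr-w2v")
    return [
        fused_document_vector(
            toks, wmap, table, doc_id=doc.doc_id, normalize=normalize
        )
        for doc, toks, wmap in zip(corpus, token_lists, weight_maps)
    ]
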