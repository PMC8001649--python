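"""Per-document term weighting: raw counts, TF-IDF, and TextRank.

Three weighting views of the same token stream:

* ``term_counts`` — plain occurrence counts n_ij.
* ``tfidf_weights`` — (n_ij / Σ_k n_kj) · ln(|D| / (1 + df_i)), where df_i is
  the number of documents containing term i.  The ``+1`` in the denominator
  guards against a zero denominator and makes the idf of an everywhere-term
  slightly negative; that behaviour is kept as-is (a ``clip_negative_idf``
  switch zeroes it instead).
* ``textrank_scores`` — the PageRank-style recursion
  ``WS(V_i) = (1 - d) + d · Σ_{j∈In(i)} w_ji / Σ_{k∈Out(j)} w_jk · WS(V_j)``
  run on a word co-occurrence graph: words are vertices and two words are
  linked (with an integer co-occurrence count as weight) whenever they fall
  within a fixed-length sliding window of the token stream.  The graph is
  undirected; each edge acts as a pair of reciprocal directed edges.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "TermCounts",
    "TextRankConfig",
    "TextRankResult",
    "term_counts",
    "tfidf_weights",
    "build_cooccurrence_graph",
    "textrank_scores",
    "top_fraction_keywords",
]


@dataclass(frozen=True)
class TermCounts:
    """Exact multiset counts for one document."""

    counts: Mapping[str, int]
    total: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.total:
            raise ValueError("counts must sum to total")


@dataclass(frozen=True)
class TextRankConfig:
    """Damping, convergence and windowing settings for the word ranking.

    Defaults: d = 0.85, tolerance 1e-6, 100 iterations max, window 5.
    """

    damping: float = 0.85
    tolerance: float = 1e-6
    max_iterations: int = 100
    window_size: int = 5

    def __post_init__(self) -> None:
        if not 0.0 < self.damping < 1.0:
            raise ValueError("damping must be in (0, 1)")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")


@dataclass(frozen=True)
class TextRankResult:
    scores: dict[str, float]
    iterations: int
    converged: bool


def term_counts(tokens: Sequence[str]) -> TermCounts:
    """Occurrence count of each term in one document (word-count weighting)."""
    c = Counter(tokens)
    return TermCounts(dict(c), total=len(tokens))


def tfidf_weights(
    corpus_counts: Sequence[TermCounts], *, clip_negative_idf: bool = False
) -> list[dict[str, float]]:
    """TF-IDF weight maps for every document of a corpus.

    tf is the within-document relative frequency; idf is
    ``ln(n_docs / (1 + df))`` with df the number of documents containing the
    term.  With ``clip_negative_idf`` the (rare) negative idf values are
    clamped to zero instead of propagating.
    """
    n_docs = len(corpus_counts)
    if n_docs == 0:
        raise ValueError("corpus must contain at least one document")
    df: Counter[str] = Counter()
    for tc in corpus_counts:
        df.update(tc.counts.keys())
    idf = {t: math.log(n_docs / (1 + d)) for t, d in df.items()}
    if clip_negative_idf:
        idf = {t: max(v, 0.0) for t, v in idf.items()}
    out: list[dict[str, float]] = []
    for tc in corpus_counts:
        if tc.total == 0:
            out.append({})
            continue
        out.append({t: (n / tc.total) * idf[t] for t, n in tc.counts.items()})
    return out


def build_cooccurrence_graph(tokens: Sequence[str], window_size: int = 5) -> nx.Graph:
    """Undirected word co-occurrence graph over a sliding positional window.

    An edge (a, b) accumulates weight 1 for every position pair (i, j) with
    ``0 < j - i < window_size`` and distinct terms; same-term pairs never
    create self-loops.
    """
    if window_size < 2:
        raise ValueError("window_size must be >= 2")
    graph = nx.Graph()
    graph.add_nodes_from(tokens)
    n = len(tokens)
    for i in range(n):
        a = tokens[i]
        for j in range(i + 1, min(i + window_size, n)):
            b = tokens[j]
            if a == b:
                continue
            if graph.has_edge(a, b):
                graph[a][b]["weight"] += 1
            else:
                graph.add_edge(a, b, weight=1)
    return graph


def textrank_scores(
    graph: nx.Graph, config: TextRankConfig | None = None
) -> TextRankResult:
    """Iterate the damped vertex-score recursion to a fixed point.

    Starts from all-ones scores and applies synchronous updates until the
    maximum absolute per-vertex change drops below the tolerance.  Isolated
    vertices settle at ``1 - d``.  On a graph where every vertex has an
    edge, the converged scores sum to the vertex count (the normalized
    out-weights telescope to one when summed over vertices).
    """
    config = config or TextRankConfig()
    nodes = list(graph.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("graph must have at least one vertex")
    index = {t: i for i, t in enumerate(nodes)}

    # Column-normalized weighted adjacency: M[i, j] = w_ji / sum_k w_jk, so
    # that the update is ws <- (1 - d) + d * M @ ws.
    M = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        ia, ib = index[a], index[b]
        M[ia, ib] = M[ib, ia] = w
    out_sums = M.sum(axis=0)
    nonzero = out_sums > 0
    M[:, nonzero] /= out_sums[nonzero]

    d = config.damping
    ws = np.ones(n)
    converged = False
    iterations = 0
    for iterations in range(1, config.max_iterations + 1):
        new = (1.0 - d) + d * (M @ ws)
        if np.max(np.abs(new - ws)) < config.tolerance:
            ws = new
            converged = True
            break
        ws = new
    return TextRankResult(
        scores={t: float(ws[index[t]]) for t in nodes},
        iterations=iterations,
        converged=converged,
    )


def top_fraction_keywords(
    weights: Mapping[str, float], fraction: float = 0.1
) -> list[tuple[str, float]]:
    """Highest-weight terms covering a fraction of the distinct vocabulary.

    Returns ``ceil(fraction * |vocab|)`` terms, at least one for a non-empty
    map.  Ties break by descending weight, then ascending term.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if not weights:
        return []
    k = max(1, math.ceil(fraction * len(weights)))
    ranked = sorted(weights.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]
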