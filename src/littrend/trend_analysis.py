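"""Literature trend analysis: similarity correlation, hotspots, refined hotspots.

Three year-resolved views of a document collection:

1. **Similarity correlation** — per (group, year), average the document
   vectors into a yearly profile; compare groups within each year by cosine
   similarity.
2. **Keyword trend analysis** — per document, rank terms with TextRank and
   keep the top fraction; per year, merge the kept (term, weight) lists by
   summing weights; report the top-N merged terms as the year's hotspots.
3. **Improved (cluster-refined) hotspots** — per year, cluster the year's
   fused document vectors with k-means, run the keyword merge within each
   cluster, take the top terms of each cluster, and union them into the
   year's hotspot set.  Terms present in every year's set form a common
   core reported separately; removing it leaves the differential hotspots
   that distinguish one year's research from the others.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cluster_eval import kmeans_partition
from .corpus_io import Corpus, TokenizerConfig, tokenize
from .fusion_embedding import DocumentVector
from .term_weighting import (
    TextRankConfig,
    build_cooccurrence_graph,
    textrank_scores,
    top_fraction_keywords,
)

__all__ = [
    "YearlyProfile",
    "SimilarityMatrix",
    "HotspotTable",
    "ImprovedHotspotResult",
    "yearly_profiles",
    "pairwise_group_similarity",
    "merge_keyword_weights",
    "document_keywords",
    "yearly_hotspots",
    "improved_yearly_hotspots",
]


@dataclass(frozen=True)
class YearlyProfile:
    """Mean document vector of one group in one year."""

    group: str
    year: int
    vector: np.ndarray
    n_docs: int


@dataclass
class SimilarityMatrix:
    """Cosine similarities between all group profiles of one year."""

    year: int
    groups: list[str]
    matrix: np.ndarray

    def lookup(self, group_a: str, group_b: str) -> float:
        i, j = self.groups.index(group_a), self.groups.index(group_b)
        return float(self.matrix[i, j])


@dataclass
class HotspotTable:
    """Ranked (term, merged weight) hotspot list for one year."""

    year: int
    hotspots: list[tuple[str, float]]  # descending weight
    method: str = "basic"  # basic | improved

    def terms(self) -> list[str]:
        return [t for t, _ in self.hotspots]


@dataclass
class ImprovedHotspotResult:
    """Cluster-refined hotspots with the cross-year common core split out."""

    tables: dict[int, HotspotTable]  # unfiltered union per year
    differential: dict[int, HotspotTable]  # after removing the common core
    common_core: list[str]
    cluster_detail: dict[int, dict[int, list[tuple[str, float]]]] = field(
        default_factory=dict
    )  # year -> cluster label -> top (term, weight)


def yearly_profiles(
    doc_vectors: Sequence[DocumentVector], corpus: Corpus
) -> tuple[list[YearlyProfile], int]:
    """Mean vector per (group, year); returns (profiles, n_skipped_no_year).

    Documents lacking a year are excluded and counted.  Documents lacking a
    group are pooled under the group label ``"all"``.
    """
    meta = {doc.doc_id: doc for doc in corpus}
    buckets: dict[tuple[str, int], list[np.ndarray]] = defaultdict(list)
    skipped = 0
    for dv in doc_vectors:
        doc = meta[dv.doc_id]
        if doc.year is None:
            skipped += 1
            continue
        buckets[(doc.group or "all", doc.year)].append(dv.vector)
    if not buckets:
        raise ValueError("no documents with a year: yearly profiles undefined")
    profiles = [
        YearlyProfile(group, year, np.mean(vecs, axis=0), len(vecs))
        for (group, year), vecs in sorted(buckets.items())
    ]
    return profiles, skipped


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def pairwise_group_similarity(
    profiles: Sequence[YearlyProfile],
) -> dict[int, SimilarityMatrix]:
    """Cosine similarity between every pair of group profiles, per year.

    Zero-vector profiles get similarity 0 against everything (with their
    own diagonal also 0, since direction is undefined).
    """
    by_year: dict[int, list[YearlyProfile]] = defaultdict(list)
    for p in profiles:
        by_year[p.year].append(p)
    shared = {y: ps for y, ps in by_year.items() if len(ps) >= 2}
    if not shared:
        raise ValueError("no year is shared by at least two groups")
    out: dict[int, SimilarityMatrix] = {}
    for year, ps in sorted(shared.items()):
        ps = sorted(ps, key=lambda p: p.group)
        groups = [p.group for p in ps]
        n = len(ps)
        M = np.zeros((n, n))
        for i in range(n):
            for j in range(i, n):
                s = 1.0 if i == j and np.linalg.norm(ps[i].vector) > 0 else None
                if s is None:
                    s = _cosine(ps[i].vector, ps[j].vector)
                M[i, j] = M[j, i] = s
        out[year] = SimilarityMatrix(year, groups, M)
    return out


def merge_keyword_weights(
    per_doc_keywords: Sequence[Sequence[tuple[str, float]]],
) -> dict[str, float]:
    """Union keyword lists, summing weights of repeated terms.

    Total weight is conserved exactly: the merged sum equals the input sum.
    """
    merged: dict[str, float] = {}
    for kws in per_doc_keywords:
        for term, w in kws:
            merged[term] = merged.get(term, 0.0) + w
    return merged


def document_keywords(
    text: str,
    fraction: float = 0.1,
    textrank_config: TextRankConfig | None = None,
    tokenizer: TokenizerConfig | None = None,
) -> list[tuple[str, float]]:
    """Top-fraction TextRank keywords of one document."""
    trc = textrank_config or TextRankConfig()
    tokens = tokenize(text, tokenizer)
    if not tokens:
        return []
    graph = build_cooccurrence_graph(tokens, trc.window_size)
    scores = textrank_scores(graph, trc).scores
    return top_fraction_keywords(scores, fraction)


def _rank(merged: Mapping[str, float]) -> list[tuple[str, float]]:
    return sorted(merged.items(), key=lambda kv: (-kv[1], kv[0]))


def yearly_hotspots(
    corpus: Corpus,
    fraction: float = 0.1,
    top_n: int = 50,
    textrank_config: TextRankConfig | None = None,
    tokenizer: TokenizerConfig | None = None,
) -> dict[int, HotspotTable]:
    """Per-year hotspot keywords by TextRank extraction and weight merging.

    Defaults: keep the top 10% of each document's distinct terms, report
    the 50 highest merged weights per year.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    by_year: dict[int, list[list[tuple[str, float]]]] = defaultdict(list)
    for doc in corpus:
        if doc.year is None:
            continue
        kws = document_keywords(doc.text, fraction, textrank_config, tokenizer)
        if kws:
            by_year[doc.year].append(kws)
    return {
        year: HotspotTable(year, _rank(merge_keyword_weights(lists))[:top_n], "basic")
        for year, lists in sorted(by_year.items())
    }


def improved_yearly_hotspots(
    corpus: Corpus,
    doc_vectors: Sequence[DocumentVector],
    k: int = 10,
    per_cluster_top: int = 1,
    fraction: float = 0.1,
    seed: int = 0,
    textrank_config: TextRankConfig | None = None,
    tokenizer: TokenizerConfig | None = None,
    differential_filter: bool = True,
) -> ImprovedHotspotResult:
    """Cluster-refined yearly hotspots with cross-year differential filtering.

    Per year: k-means over that year's document vectors, keyword merge per
    cluster, top ``per_cluster_top`` terms per cluster (weight summed when
    a term tops several clusters), union as the year's table.  Terms that
    appear in every year's table form the common core; the differential
    tables have it removed.  With ``differential_filter`` off, the
    differential tables equal the unfiltered ones.
    """
    vec_by_id = {dv.doc_id: dv for dv in doc_vectors}
    by_year: dict[int, list] = defaultdict(list)
    for doc in corpus:
        if doc.year is not None and doc.doc_id in vec_by_id:
            by_year[doc.year].append(doc)
    if not by_year:
        raise ValueError("no documents with both a year and a vector")

    tables: dict[int, HotspotTable] = {}
    cluster_detail: dict[int, dict[int, list[tuple[str, float]]]] = {}
    for year, docs in sorted(by_year.items()):
        if k > len(docs):
            raise ValueError(
                f"year {year}: k={k} exceeds the {len(docs)} available documents"
            )
        X = np.stack([vec_by_id[d.doc_id].vector for d in docs])
        part = kmeans_partition(
            X, k, seed=seed, doc_ids=[d.doc_id for d in docs]
        )
        year_merged: dict[str, float] = {}
        detail: dict[int, list[tuple[str, float]]] = {}
        for label in range(k):
            members = [d for d in docs if part.labels[d.doc_id] == label]
            kw_lists = [
                document_keywords(d.text, fraction, textrank_config, tokenizer)
                for d in members
            ]
            merged = merge_keyword_weights([kws for kws in kw_lists if kws])
            top = _rank(merged)[:per_cluster_top]
            detail[label] = top
            for term, w in top:
                year_merged[term] = year_merged.get(term, 0.0) + w
        tables[year] = HotspotTable(year, _rank(year_merged), "improved")
        cluster_detail[year] = detail

    if differential_filter and len(tables) > 1:
        term_sets = [set(t.terms()) for t in tables.values()]
        core = sorted(set.intersection(*term_sets))
    else:
        core = []
    differential = {
        year: HotspotTable(
            year,
            [(t, w) for t, w in table.hotspots if t not in core],
            "improved",
        )
        for year, table in tables.items()
    }
    return ImprovedHotspotResult(tables, differential, core, cluster_detail)
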