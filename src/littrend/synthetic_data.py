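"""Synthetic corpora with planted structure for end-to-end testing.

Documents are token-level mixtures: each token comes from the document's
topic vocabulary with probability ``topic_word_rate`` and from a shared
background vocabulary otherwise, both sampled under Zipf-ranked
frequencies.  Topic vocabularies are pairwise disjoint and disjoint from
the background, so topics are separable by any reasonable embedding.  Year
and group labels are assigned round-robin; trend corpora additionally
inject year-specific "emergent" terms at a configurable per-term rate so
they rank high under TextRank within that year's documents.

This emulates the structure the analysis pipeline assumes — multi-topic
corpora with salient vocabulary and year-specific hotspots — not realistic
biomedical language.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .corpus_io import Corpus, Document

__all__ = ["GeneratorSpec", "GroundTruth", "generate_topic_corpus", "generate_trend_corpus"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic corpus generator.

    ``doc_length_mean``/``doc_length_dispersion`` parametrize a
    gamma-Poisson (negative binomial) length distribution; dispersion is
    the gamma shape, larger = more concentrated around the mean.
    """

    n_topics: int = 5
    docs_per_topic: int = 100
    background_vocab_size: int = 500
    topic_vocab_size: int = 50
    doc_length_mean: float = 80.0
    doc_length_dispersion: float = 20.0
    topic_word_rate: float = 0.5
    zipf_exponent: float = 1.1
    years: tuple[int, ...] = ()
    groups: tuple[str, ...] = ()
    planted_year_terms: Mapping[int, tuple[str, ...]] = field(default_factory=dict)
    injection_rate: float = 0.05
    group_topics: Mapping[str, tuple[int, ...]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_topics < 1 or self.docs_per_topic < 1:
            raise ValueError("n_topics and docs_per_topic must be >= 1")
        if self.background_vocab_size < 1 or self.topic_vocab_size < 1:
            raise ValueError("vocabulary sizes must be positive")
        if not 0.0 < self.topic_word_rate < 1.0:
            raise ValueError("topic_word_rate must be in (0, 1)")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be > 0")
        if not 0.0 <= self.injection_rate < 1.0:
            raise ValueError("injection_rate must be in [0, 1)")
        for year in self.planted_year_terms:
            if year not in self.years:
                raise ValueError(f"planted year {year} not in spec.years")
        for g in self.group_topics:
            if g not in self.groups:
                raise ValueError(f"group_topics key {g!r} not in spec.groups")


@dataclass
class GroundTruth:
    """What the generator planted: topic labels and year-specific terms."""

    topic_of: dict[str, int]  # doc_id -> topic index
    planted: list[tuple[str, int, str | None]]  # (term, year, group)


def _zipf_probs(size: int, exponent: float) -> np.ndarray:
    p = (np.arange(1, size + 1, dtype=np.float64)) ** (-exponent)
    return p / p.sum()


def _vocabularies(spec: GeneratorSpec) -> tuple[list[str], list[list[str]]]:
    background = [f"bg{i:04d}" for i in range(spec.background_vocab_size)]
    topics = [
        [f"tp{k}x{i:03d}" for i in range(spec.topic_vocab_size)]
        for k in range(spec.n_topics)
    ]
    return background, topics


def generate_topic_corpus(spec: GeneratorSpec) -> tuple[Corpus, GroundTruth]:
    """Corpus of n_topics * docs_per_topic documents with known topic labels.

    Same spec + seed always produces a byte-identical corpus.
    """
    rng = np.random.default_rng(spec.seed)
    background, topics = _vocabularies(spec)
    bg_probs = _zipf_probs(len(background), spec.zipf_exponent)
    tp_probs = _zipf_probs(spec.topic_vocab_size, spec.zipf_exponent)

    n_docs = spec.n_topics * spec.docs_per_topic
    documents: list[Document] = []
    topic_of: dict[str, int] = {}
    for d in range(n_docs):
        # Blocked topic assignment unless group_topics dictates otherwise.
        group = spec.groups[d % len(spec.groups)] if spec.groups else None
        if group is not None and group in spec.group_topics:
            choices = spec.group_topics[group]
            topic = int(choices[rng.integers(len(choices))])
        else:
            topic = d // spec.docs_per_topic
        # Years cycle on a stride of the group count so the two round-robin
        # assignments stay decorrelated (every group occurs in every year).
        year_idx = d // len(spec.groups) if spec.groups else d
        year = spec.years[year_idx % len(spec.years)] if spec.years else None

        length = max(
            5,
            int(
                rng.poisson(
                    rng.gamma(
                        spec.doc_length_dispersion,
                        spec.doc_length_mean / spec.doc_length_dispersion,
                    )
                )
            ),
        )
        from_topic = rng.random(length) < spec.topic_word_rate
        n_topic_tokens = int(from_topic.sum())
        topic_draw = rng.choice(
            spec.topic_vocab_size, size=n_topic_tokens, p=tp_probs
        )
        bg_draw = rng.choice(len(background), size=length - n_topic_tokens, p=bg_probs)
        tokens = np.empty(length, dtype=object)
        tokens[from_topic] = [topics[topic][i] for i in topic_draw]
        tokens[~from_topic] = [background[i] for i in bg_draw]

        doc_id = f"doc{d:05d}"
        documents.append(
            Document(doc_id, " ".join(tokens.tolist()), year=year, group=group)
        )
        topic_of[doc_id] = topic

    corpus = Corpus(documents, provenance=f"synthetic#seed={spec.seed}")
    return corpus, GroundTruth(topic_of, planted=[])


def generate_trend_corpus(spec: GeneratorSpec) -> tuple[Corpus, GroundTruth]:
    """Topic corpus plus year-specific planted terms.

    Each planted term of a document's year is inserted at random positions,
    with an occurrence count ~ Binomial(base length, injection_rate), so the
    expected total count across a year is n_docs(year) x mean length x rate.
    With injection_rate 0 the output is identical to generate_topic_corpus
    under the same seed.
    """
    corpus, truth = generate_topic_corpus(spec)
    if spec.injection_rate == 0.0 or not spec.planted_year_terms:
        truth.planted = [
            (term, year, None)
            for year, terms in sorted(spec.planted_year_terms.items())
            for term in terms
        ]
        return corpus, truth

    rng = np.random.default_rng(spec.seed + 1)
    documents: list[Document] = []
    for doc in corpus:
        planted = spec.planted_year_terms.get(doc.year, ()) if doc.year else ()
        if not planted:
            documents.append(doc)
            continue
        tokens = doc.text.split(" ")
        base_len = len(tokens)
        for term in planted:
            n_insert = int(rng.binomial(base_len, spec.injection_rate))
            for _ in range(n_insert):
                pos = int(rng.integers(len(tokens) + 1))
                tokens.insert(pos, term)
        documents.append(Document(doc.doc_id, " ".join(tokens), doc.year, doc.group))

    truth.planted = [
        (term, year, None)
        for year, terms in sorted(spec.planted_year_terms.items())
        for term in terms
    ]
    return Corpus(documents, provenance=corpus.provenance + "#trend"), truth
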