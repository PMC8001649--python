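# Methods

## Problem and approach

`littrend` analyzes how research literature evolves over time. Its input is
a corpus of documents (title + abstract style text) annotated with a
publication year and a group label such as a disease or subject category.
The package has two layers:

1. **Text representation.** Documents are embedded as dense vectors by
   fusing word embeddings with per-document term importance weights.
2. **Trend analysis.** The document vectors and keyword weights drive three
   year-resolved analyses: cross-group similarity, yearly keyword hotspots,
   and cluster-refined differential hotspots.

## Term weighting

Three weighting schemes operate on the tokenized document:

* **Word counts** — n_ij, the occurrences of term i in document j.
* **TF-IDF** — tf·idf with tf = n_ij / Σ_k n_kj and
  idf = ln(|D| / (1 + df_i)), df_i the number of documents containing term
  i. The `+1` in the denominator guards against division by zero; its side
  effect is that a term present in every document receives a slightly
  negative idf, ln(|D|/(1+|D|)). We keep the formula as-is rather than
  clamping, because the negative weight is informative (the term carries no
  discriminative signal); a `clip_negative_idf` switch restores the
  clamped convention. The log base is natural; any other base would only
  rescale all weights uniformly.
* **TextRank** — words are vertices of a co-occurrence graph: an edge
  (a, b) accumulates weight 1 for every token-position pair (i, j) with
  0 < j − i < window, giving deterministic integer weights. The vertex
  score is the damped recursion

      WS(V_i) = (1 − d) + d · Σ_{j ∈ In(i)} [ w_ji / Σ_{k ∈ Out(j)} w_jk ] · WS(V_j)

  iterated synchronously from all-ones until the maximum absolute change
  falls below the tolerance. The co-occurrence graph is undirected; each
  edge acts as two reciprocal directed edges, the standard practice for
  word graphs. Defaults: damping d = 0.85, tolerance 1e−6, ≤100
  iterations, window 5 (chosen because a window sweep of the clustering
  protocol peaks there). On any graph without isolated vertices the
  converged scores sum to the vertex count — summing the recursion over
  vertices telescopes the normalized out-weights to one — which the tests
  use as a conservation check. Scores are invariant to uniform scaling of
  edge weights.

**Keyword selection** keeps the top ceil(fraction · |distinct terms|)
terms per document (minimum one), fraction 0.1 by default. Ties break by
descending weight then ascending term, so results are fully deterministic.
"Fraction of distinct terms" rather than of token count was an open
choice; distinct terms make the kept-set size independent of document
verbosity.

## Word embeddings

Word vectors come from a compact skip-gram / CBOW implementation with
negative sampling (5 negatives against a unigram^0.75 noise distribution),
minibatch SGD and a linearly decaying learning rate. Defaults: skip-gram,
dimension 100, context window 5, min-count 1, 10 epochs, learning rate
0.025, fixed seed. Training is single-threaded numpy and bit-reproducible
given the seed. A pretrained table in the plain-text vector dialect
(optional `count dim` header, then one term + D floats per line) can be
loaded instead.

## Fusion document vectors

The mean baseline averages word vectors per occurrence. The fusion
representations compute V = Σ_j ŵ_j · v_j over tokens present in both the
weight map and the table, with ŵ the TF-IDF weights (**Ti-W2v**) or the
TextRank scores of the document's own co-occurrence graph (**Tr-W2v**).
Weights are normalized to sum to one by default so fused vectors stay on
the same scale as the mean baseline and silhouette comparisons between
representations are fair; raw (unnormalized) mode is available. With
uniform weights over distinct tokens the fusion reduces exactly to the
mean baseline, which the tests verify to machine precision. Out-of-table
tokens are skipped, never imputed; a document with no covered token yields
the zero vector with coverage 0 and a warning.

## Clustering evaluation

Representations are compared by k-means (k-means++ initialization, up to
300 Lloyd iterations, 10 restarts per seed) followed by the mean
silhouette coefficient (b − a)/max(a, b) under Euclidean distance (cosine
available by flag). Default k = 10, matching the common ten-category
evaluation setup. The sparse TF-IDF/TextRank document representations use
the full corpus vocabulary as dimensions with zeros for absent terms — the
only construction consistent with per-document term weights. For synthetic
corpora with known topic labels the report also carries the adjusted Rand
agreement of the clustering with the ground truth.

## Trend analyses

* **Similarity correlation.** Document vectors of each (group, year) cell
  are averaged into a yearly profile; groups are compared within each year
  by cosine similarity. Zero profiles get similarity 0 (direction
  undefined). Cosine makes the analysis invariant to per-cell scaling.
* **Keyword hotspots.** Per document, TextRank keywords (top 10% of
  distinct terms) with their scores; per year, lists are merged by summing
  the weights of repeated terms — total weight is conserved exactly — and
  the top 50 merged terms are the year's hotspots.
* **Improved hotspots.** Per year, the year's Tr-W2v vectors are clustered
  into k groups (default k = 10, configurable); the keyword merge runs
  within each cluster and the top `per_cluster_top` terms per cluster
  (default 1, the top keyword of each category) are unioned into the
  year's set. Terms present in *every* year's set — the common core of
  perennial vocabulary — are removed to leave the **differential
  hotspots**; the rule for "differential" was an open design choice, and
  both the filtered and unfiltered tables are reported, with the common
  core listed separately. In the shipped analyses we use
  `per_cluster_top = 10`: with the default of 1 a year's set holds at most
  k terms, which is too small a budget to surface several co-occurring
  emergent terms at once.

## Synthetic data generator

The generator emulates the corpus structure the analyses assume, not
realistic biomedical language. Each document's tokens are drawn i.i.d.:
with probability `topic_word_rate` (default 0.5) from the document's topic
vocabulary, otherwise from a shared background vocabulary, both under
Zipf-ranked frequencies (exponent 1.1). Topic vocabularies (50 terms per
topic) are pairwise disjoint and disjoint from the background (500 terms),
so topics are in principle separable. Document lengths are gamma-Poisson
with mean 80 (an abstract-sized text). Year and group labels are assigned
round-robin, with the year cycle strided by the group count so the two
labelings stay decorrelated. Trend corpora additionally inject each of the
year's planted terms at rate 0.05 per token position (≈4 occurrences in an
80-token document) — enough for a planted term to rank inside a document's
top keywords, which is the generator's contract: planted terms must behave
like genuinely emergent vocabulary, not trace contamination.

Because topic vocabularies are disjoint and tokens i.i.d., passing the
planted-signal tests shows the pipeline recovers structure that is
linearly separable in distribution; it does not show robustness to
polysemy, topic overlap, multiword terms or label noise, all of which real
literature has.

## Numerical and degenerate-input choices

* TextRank on an isolated vertex returns 1 − d; non-convergence within the
  iteration cap is flagged on the result, scores still returned.
* Empty documents produce empty weight maps and (for fusion) zero vectors
  with a warning rather than errors; records without a year are kept in
  the corpus but excluded, with a count, from yearly analyses.
* k-means requires 1 ≤ k ≤ n and silhouette requires ≥ 2 populated
  clusters; violations raise with the offending quantity named.
* All ranked outputs use (descending weight, ascending term) ordering, so
  every table is reproducible bit-for-bit.

## Problem sizes in the shipped analyses

The planted-topic study uses 5 topics × 100 documents and the trend study
5 years × 100 documents with 5 planted terms per year; the similarity
study uses 2 topics, 3 groups and 3 years over 180 documents. These sizes
give stable signal recovery (adjusted Rand and hotspot recovery at or near
their ceilings) while keeping a full run of the analysis scripts in the
low minutes on one CPU.

## Known limitations

* The embedding trainer is a minimal reference implementation; it does not
  subsample frequent words, use dynamic windows, or parallelize.
* TF-IDF's negative idf values can make normalized fusion weights
  ill-conditioned when a document consists mostly of everywhere-terms;
  `clip_negative_idf` avoids this if it arises.
* The silhouette of embedding representations depends on embedding
  hyperparameters; per-seed distributions are reported instead of a single
  number.
* Hotspot quality degrades when a year has fewer documents than k; the
  per-year k is configurable for unbalanced corpora.
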