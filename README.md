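# littrend

Weighted word-embedding fusion and literature trend analysis.

`littrend` is for researchers who want to track how a body of literature —
e.g. the abstracts published on several cancer types over a span of years —
shifts its vocabulary and focus over time. It provides:

* **Fusion document embeddings.** A document vector is a weighted sum of
  its word embeddings, V = Σ_j ŵ_j · v_j, where the weights come from
  TF-IDF (**Ti-W2v**) or from TextRank scores on the document's own word
  co-occurrence graph (**Tr-W2v**). Both consistently improve on the plain
  mean-of-vectors baseline because they emphasize each document's salient
  vocabulary.
* **Representation evaluation.** k-means (k-means++, ≤300 iterations) plus
  the silhouette coefficient (b − a)/max(a, b) compares sparse TF-IDF /
  TextRank vectors against the embedding representations.
* **Trend analysis.** Three year-resolved models: cosine similarity
  between per-(group, year) mean profiles; yearly keyword hotspots (per
  document TextRank top-10% keywords, merged per year by summing weights,
  top 50 reported); and cluster-refined *differential* hotspots, where
  each year's documents are clustered, top keywords are taken per cluster,
  and vocabulary common to all years is filtered out.
* **A synthetic corpus generator** with planted topics, Zipf-distributed
  vocabularies and year-specific emergent terms, so the whole pipeline is
  testable without downloading any dataset.

The core formulas: TF-IDF is tf_ij · ln(|D| / (1 + df_i)); TextRank is the
damped recursion WS(V_i) = (1 − d) + d · Σ_{j∈In(i)} [w_ji / Σ_k w_jk] ·
WS(V_j) with d = 0.85 on a sliding-window (default 5) co-occurrence graph.
See `docs/methods.md` for the full model description and design choices.

## Worked example

`examples/03_representation_comparison.py` generates a 3-topic synthetic
corpus (120 documents), trains 50-dimensional skip-gram vectors, and runs
the clustering comparison:

```
representation      mean silhouette  ARI vs truth
tfidf-vector                  0.291         1.000
textrank-vector               0.351         1.000
mean-w2v                      0.870         1.000
ti-w2v                        0.881         1.000
tr-w2v                        0.880         1.000
```

Every representation recovers the planted topics (adjusted Rand index 1.0),
but the embedding representations form much tighter, better-separated
clusters (silhouette 0.87–0.88 vs 0.29–0.35), and both fusion variants
improve on the plain embedding mean. The other examples demonstrate
keyword extraction (`01`), fused vectors (`02`), yearly similarity
trends (`04`) and differential hotspot discovery (`05`); each prints a
short interpretation with its numbers.

## Command line

A thin CLI mirrors the library stages:

```bash
littrend synth     --spec spec.json --out corpus.jsonl --truth truth.json
littrend ingest    --in corpus.jsonl --report report.json
littrend keywords  --in corpus.jsonl --fraction 0.1 --out keywords.csv
littrend embed     --in corpus.jsonl --method tr-w2v --out docvecs.csv
littrend evaluate  --in corpus.jsonl --reps tfidf,mean,tr-w2v --k 10 --out eval.csv
littrend correlate --in corpus.jsonl --out sim.csv
littrend hotspots  --in corpus.jsonl --mode improved --k 10 --out hotspots.csv
```

Corpora are JSONL (one `{"id", "text", "year", "group"}` object per line)
or CSV with the same header fields; all outputs are tidy CSV.

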