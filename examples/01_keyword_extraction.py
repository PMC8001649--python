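"""Extract weighted keywords from a single document.

Builds a word co-occurrence graph over a sliding window, ranks words with
the damped TextRank recursion, and compares the result with TF-IDF weights
computed against a small reference corpus.
"""

import littrend as lt

abstract = (
    "EGFR mutations drive tumor growth in lung cancer. Targeted EGFR "
    "inhibitors improve survival, but resistance mutations limit the "
    "inhibitors. Combining EGFR inhibitors with immunotherapy is an "
    "active area of lung cancer research."
)
others = [
    "BRCA1 variants raise breast cancer risk and guide PARP inhibitor use.",
    "Helicobacter pylori infection is a major driver of gastric cancer.",
]

tokens = lt.tokenize(abstract)
graph = lt.build_cooccurrence_graph(tokens, window_size=5)
scores = lt.textrank_scores(graph).scores
top = lt.top_fraction_keywords(scores, fraction=0.25)

print("TextRank keywords (top 25% of distinct terms):")
for term, weight in top:
    print(f"  {term:15s} {weight:.4f}")

counts = [lt.term_counts(lt.tokenize(t)) for t in [abstract, *others]]
tfidf = lt.tfidf_weights(counts)[0]
print("\nTF-IDF keywords for the same document:")
for term, weight in lt.top_fraction_keywords(tfidf, fraction=0.25):
    print(f"  {term:15s} {weight:.4f}")

print(
    "\nTextRank favors words central to the document's own co-occurrence "
    "structure; TF-IDF favors words rare in the rest of the corpus."
)
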