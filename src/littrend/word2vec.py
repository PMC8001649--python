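"""Shallow word-embedding training (skip-gram / CBOW with negative sampling).

A compact, deterministic numpy implementation of the two classic Word2Vec
training modes.  Skip-gram predicts each context word from the center word;
CBOW predicts the center word from the averaged context.  Both are trained
with negative sampling against a unigram^0.75 noise distribution, minibatch
SGD and a linearly decaying learning rate.  With a fixed seed the result is
bit-reproducible.

Sized for the corpora this package targets (tens of thousands of tokens,
vocabularies of a few thousand terms); it is not a large-scale trainer.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["Word2VecConfig", "train_embeddings"]


@dataclass(frozen=True)
class Word2VecConfig:
    mode: str = "skipgram"  # "skipgram" or "cbow"
    dimension: int = 100
    window: int = 5
    min_count: int = 1
    negative: int = 5
    epochs: int = 10
    learning_rate: float = 0.025
    batch_size: int = 1024
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("skipgram", "cbow"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.dimension < 1 or self.window < 1 or self.epochs < 1:
            raise ValueError("dimension, window and epochs must be >= 1")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


def train_embeddings(
    sentences: Sequence[Sequence[str]], config: Word2VecConfig | None = None
) -> tuple[list[str], np.ndarray]:
    """Train word vectors; returns (vocabulary, matrix of shape (V, D)).

    The vocabulary is ordered by descending corpus frequency (ties by term)
    and row i of the matrix is the input vector of vocabulary[i].
    """
    config = config or Word2VecConfig()
    freq = Counter(t for sent in sentences for t in sent)
    vocab = sorted(
        (t for t, c in freq.items() if c >= config.min_count),
        key=lambda t: (-freq[t], t),
    )
    if not vocab:
        raise ValueError("empty vocabulary after min_count filtering")
    index = {t: i for i, t in enumerate(vocab)}
    V, D = len(vocab), config.dimension

    encoded = [
        np.array([index[t] for t in sent if t in index], dtype=np.int64)
        for sent in sentences
    ]

    # (center, context) pairs within the symmetric window, sentence-bounded.
    centers_l, contexts_l = [], []
    for sent in encoded:
        n = len(sent)
        for i in range(n):
            lo, hi = max(0, i - config.window), min(n, i + config.window + 1)
            for j in range(lo, hi):
                if j != i:
                    centers_l.append(sent[i])
                    contexts_l.append(sent[j])
    if not centers_l:
        raise ValueError("no training pairs: sentences too short for the window")
    centers = np.array(centers_l, dtype=np.int64)
    contexts = np.array(contexts_l, dtype=np.int64)
    n_pairs = len(centers)

    rng = np.random.default_rng(config.seed)
    W_in = (rng.random((V, D)) - 0.5) / D  # input vectors (the embeddings)
    W_out = np.zeros((V, D))

    counts = np.array([freq[t] for t in vocab], dtype=np.float64)
    noise = counts**0.75
    noise /= noise.sum()

    if config.mode == "cbow":
        # Padded context matrix per center position, with validity mask.
        width = 2 * config.window
        ctx_pad = np.zeros((0, width), dtype=np.int64)
        rows, mask_rows, targets_l = [], [], []
        for sent in encoded:
            n = len(sent)
            for i in range(n):
                lo, hi = max(0, i - config.window), min(n, i + config.window + 1)
                ctx = [sent[j] for j in range(lo, hi) if j != i]
                if not ctx:
                    continue
                pad = ctx + [0] * (width - len(ctx))
                rows.append(pad)
                mask_rows.append([1.0] * len(ctx) + [0.0] * (width - len(ctx)))
                targets_l.append(sent[i])
        ctx_pad = np.array(rows, dtype=np.int64)
        ctx_mask = np.array(mask_rows)
        targets = np.array(targets_l, dtype=np.int64)
        n_examples = len(targets)
    else:
        n_examples = n_pairs

    batches_total = config.epochs * max(1, -(-n_examples // config.batch_size))
    batch_no = 0
    lr0 = config.learning_rate

    for _epoch in range(config.epochs):
        order = rng.permutation(n_examples)
        for start in range(0, n_examples, config.batch_size):
            idx = order[start : start + config.batch_size]
            B = len(idx)
            lr = lr0 * max(1e-4, 1.0 - batch_no / batches_total)
            batch_no += 1
            neg = rng.choice(V, size=(B, config.negative), p=noise)

            if config.mode == "skipgram":
                h = W_in[centers[idx]]  # (B, D)
                pos_out = W_out[contexts[idx]]  # (B, D)
            else:
                ctx_i = ctx_pad[idx]  # (B, width)
                m = ctx_mask[idx]  # (B, width)
                h = (W_in[ctx_i] * m[:, :, None]).sum(axis=1) / m.sum(
                    axis=1, keepdims=True
                )
                pos_out = W_out[targets[idx]]

            neg_out = W_out[neg]  # (B, k, D)
            pos_score = _sigmoid((h * pos_out).sum(axis=1))  # label 1
            neg_score = _sigmoid((neg_out @ h[:, :, None]).squeeze(-1))  # label 0

            g_pos = pos_score - 1.0  # (B,)
            g_neg = neg_score  # (B, k)
            grad_h = g_pos[:, None] * pos_out + (g_neg[:, :, None] * neg_out).sum(
                axis=1
            )
            grad_pos_out = g_pos[:, None] * h
            grad_neg_out = g_neg[:, :, None] * h[:, None, :]

            if config.mode == "skipgram":
                np.add.at(W_in, centers[idx], -lr * grad_h)
                np.add.at(W_out, contexts[idx], -lr * grad_pos_out)
            else:
                share = (m / m.sum(axis=1, keepdims=True))[:, :, None]
                np.add.at(
                    W_in,
                    ctx_i.ravel(),
                    (-lr * grad_h[:, None, :] * share).reshape(-1, D),
                )
                np.add.at(W_out, targets[idx], -lr * grad_pos_out)
            np.add.at(W_out, neg.ravel(), (-lr * grad_neg_out).reshape(-1, D))

    return vocab, W_in
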