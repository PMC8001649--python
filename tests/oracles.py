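"""Independent brute-force oracles used only by the test suite.

Deliberately naive implementations (explicit loops, dense matrices) kept
separate from the library code paths they validate.
"""

from __future__ import annotations

import math


def textrank_power_oracle(edges, nodes, damping=0.85, tol=1e-12, max_iter=100000):
    """Dense fixed-point iteration of the damped vertex-score recursion.

    edges: iterable of (a, b, weight) for an undirected graph.
    Returns {node: score}.
    """
    nodes = list(nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    W = [[0.0] * n for _ in range(n)]
    for a, b, w in edges:
        W[idx[a]][idx[b]] = float(w)
        W[idx[b]][idx[a]] = float(w)
    out_sum = [sum(row) for row in W]
    ws = [1.0] * n
    for _ in range(max_iter):
        new = []
        for i in range(n):
            s = 0.0
            for j in range(n):
                if W[j][i] > 0 and out_sum[j] > 0:
                    s += W[j][i] / out_sum[j] * ws[j]
            new.append((1.0 - damping) + damping * s)
        if max(abs(x - y) for x, y in zip(new, ws)) < tol:
            return {v: new[idx[v]] for v in nodes}
        ws = new
    return {v: ws[idx[v]] for v in nodes}


def silhouette_bruteforce(X, labels):
    """Direct O(n^2) evaluation of the mean silhouette coefficient.

    Follows the standard convention: a point alone in its cluster scores 0.
    """
    n = len(X)

    def dist(i, j):
        return math.sqrt(sum((X[i][d] - X[j][d]) ** 2 for d in range(len(X[i]))))

    clusters = sorted(set(labels))
    scores = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            scores.append(0.0)
            continue
        a = sum(dist(i, j) for j in same) / len(same)
        b = math.inf
        for c in clusters:
            if c == labels[i]:
                continue
            members = [j for j in range(n) if labels[j] == c]
            b = min(b, sum(dist(i, j) for j in members) / len(members))
        scores.append((b - a) / max(a, b))
    return sum(scores) / n


def best_two_partition(X):
    """Exhaustive search over all 2-partitions minimizing k-means inertia."""
    n = len(X)
    d = len(X[0])
    best, best_cost = None, math.inf
    for mask in range(1, 2 ** (n - 1)):  # point 0 fixed in cluster 0
        labels = [0] + [(mask >> (i - 1)) & 1 for i in range(1, n)]
        groups = [[], []]
        for i in range(n):
            groups[labels[i]].append(X[i])
        if not groups[0] or not groups[1]:
            continue
        cost = 0.0
        for g in groups:
            cen = [sum(p[k] for p in g) / len(g) for k in range(d)]
            cost += sum(sum((p[k] - cen[k]) ** 2 for k in range(d)) for p in g)
        if cost < best_cost:
            best_cost = cost
            best = labels
    return best, best_cost
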