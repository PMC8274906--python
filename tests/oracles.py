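"""Independent brute-force reference implementations used only by tests.

These deliberately avoid every code path of the package: plain Python loops,
literal transcriptions of the update rules, naive sorting.  They exist so the
vectorized implementations can be checked against something that is obviously
correct on small inputs.
"""

from __future__ import annotations

import numpy as np


def naive_diff(xi, xj, kind, lo, hi):
    if kind == "nominal":
        return 0.0 if xi == xj else 1.0
    if hi <= lo:
        return 0.0
    return abs(xi - xj) / (hi - lo)


def naive_relieff(X, y, k, kinds=None, m_mode="paper"):
    """Literal term-by-term evaluation of the ReliefF weight update.

    Visits every instance once in index order; neighbor distances are sums of
    per-feature diffs with ties broken by instance index.
    """
    X = np.asarray(X, dtype=float)
    y = list(y)
    n, m = X.shape
    if kinds is None:
        kinds = [
            "nominal" if len(set(X[:, j])) <= 2 else "continuous" for j in range(m)
        ]
    ranges = [(X[:, j].min(), X[:, j].max()) for j in range(m)]
    classes = sorted(set(y), key=str)
    priors = {c: y.count(c) / n for c in classes}

    def dist(i, j):
        return sum(
            naive_diff(X[i, f], X[j, f], kinds[f], *ranges[f]) for f in range(m)
        )

    m_norm = m if m_mode == "paper" else n
    w = [0.0] * m
    for i in range(n):
        others = sorted((j for j in range(n) if j != i), key=lambda j: (dist(i, j), j))
        hits = [j for j in others if y[j] == y[i]][:k]
        for f in range(m):
            for j in hits:
                w[f] -= naive_diff(X[i, f], X[j, f], kinds[f], *ranges[f]) / (m_norm * k)
        for c in classes:
            if c == y[i]:
                continue
            misses = [j for j in others if y[j] == c][:k]
            factor = priors[c] / (1.0 - priors[y[i]])
            for f in range(m):
                for j in misses:
                    w[f] += (
                        factor
                        * naive_diff(X[i, f], X[j, f], kinds[f], *ranges[f])
                        / (m_norm * k)
                    )
    return np.array(w)


def naive_neighbors(X, y, i, k, kinds=None):
    """Brute-force nearest hit/miss sets for one instance."""
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if kinds is None:
        kinds = [
            "nominal" if len(set(X[:, j])) <= 2 else "continuous" for j in range(m)
        ]
    ranges = [(X[:, j].min(), X[:, j].max()) for j in range(m)]

    def dist(a, b):
        return sum(
            naive_diff(X[a, f], X[b, f], kinds[f], *ranges[f]) for f in range(m)
        )

    others = sorted((j for j in range(n) if j != i), key=lambda j: (dist(i, j), j))
    hits = [j for j in others if y[j] == y[i]][:k]
    misses = {
        c: [j for j in others if y[j] == c][:k]
        for c in sorted(set(y), key=str)
        if c != y[i]
    }
    return hits, misses


def naive_midranks(values):
    """Descending ranks with averaged ties, by explicit enumeration."""
    n = len(values)
    ranks = [0.0] * n
    for i, v in enumerate(values):
        greater = sum(1 for u in values if u > v)
        ties = sum(1 for u in values if u == v)
        # ranks occupied by the tie group: greater+1 .. greater+ties
        ranks[i] = greater + (ties + 1) / 2.0
    return ranks
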