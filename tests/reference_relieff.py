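"""Brute-force ReliefF reference used as an independent oracle in tests.

Pure-Python, loop-based, no vectorization and no shared code with the
implementation: all pairwise distances computed explicitly, neighbors picked
by exhaustive sorting (ties by sample index), diffs divided by per-attribute
training ranges.
"""

from __future__ import annotations


def brute_force_relieff(X, labels, k_neighbors):
    """Return one weight per attribute by exhaustive enumeration.

    ``X`` is a list-like of rows; every instance is evaluated.
    """
    X = [[float(v) for v in row] for row in X]
    labels = [int(l) for l in labels]
    n = len(X)
    m = len(X[0]) if n else 0

    lo = [min(row[a] for row in X) for a in range(m)]
    hi = [max(row[a] for row in X) for a in range(m)]
    rng = [hi[a] - lo[a] for a in range(m)]

    def diff(a, i, j):
        if rng[a] == 0:
            return 0.0
        return abs(X[i][a] - X[j][a]) / rng[a]

    def dist(i, j):
        return sum(diff(a, i, j) for a in range(m))

    W = [0.0] * m
    for i in range(n):
        same = [j for j in range(n) if j != i and labels[j] == labels[i]]
        other = [j for j in range(n) if labels[j] != labels[i]]
        hits = sorted(same, key=lambda j: (dist(i, j), j))[:k_neighbors]
        misses = sorted(other, key=lambda j: (dist(i, j), j))[:k_neighbors]
        for a in range(m):
            hit_mean = sum(diff(a, i, j) for j in hits) / len(hits)
            miss_mean = sum(diff(a, i, j) for j in misses) / len(misses)
            W[a] += (miss_mean - hit_mean) / n
    return W
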