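"""Independent brute-force oracles used only by the tests.

These deliberately avoid the code paths (and, where possible, the
libraries) used by the implementation under test.
"""

from __future__ import annotations

import numpy as np


def naive_ward(X):
    """O(n^3) agglomerative Ward clustering from first principles.

    Maintains explicit clusters; at every step merges the pair whose union
    minimizes the increase in total within-cluster sum of squares
    (ties: lowest index pair).  Returns (merge_heights, partitions) where
    ``partitions[k]`` is the set-of-frozensets partition into k clusters
    and heights follow the scipy convention ``h = sqrt(2 * delta_SSE)``.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    clusters = [[i] for i in range(n)]
    heights = []
    partitions = {n: frozenset(frozenset(c) for c in clusters)}
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i], clusters[j]
                ma, mb = X[a].mean(axis=0), X[b].mean(axis=0)
                d_sse = (len(a) * len(b)) / (len(a) + len(b)) * \
                    float(((ma - mb) ** 2).sum())
                if best is None or d_sse < best[0] - 1e-15:
                    best = (d_sse, i, j)
        d_sse, i, j = best
        heights.append(np.sqrt(2 * d_sse))
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
        partitions[len(clusters)] = frozenset(frozenset(c) for c in clusters)
    return np.array(heights), partitions


def normal_equations_ols(X, y):
    """Least squares via explicit normal equations (X'X)^-1 X'y."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.linalg.solve(X.T @ X, X.T @ y)


def pooled_t(a, b):
    """Two-sample pooled-variance t statistic and two-sided p, by formula."""
    from scipy.stats import t as tdist

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * tdist.sf(abs(t), na + nb - 2)
    return t, p


def l1_by_hand(sigs_a, sigs_b):
    """L1 imbalance from raw signature lists via dictionary counting."""
    ca, cb = {}, {}
    for s in sigs_a:
        ca[s] = ca.get(s, 0) + 1
    for s in sigs_b:
        cb[s] = cb.get(s, 0) + 1
    cells = set(ca) | set(cb)
    return 0.5 * sum(abs(ca.get(c, 0) / len(sigs_a) - cb.get(c, 0) / len(sigs_b))
                     for c in cells)
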