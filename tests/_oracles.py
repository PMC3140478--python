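"""Independent brute-force oracles used to check the package's engines.

Everything here is deliberately written with explicit Python loops and
from-first-principles formulas, independent of the implementation paths it
validates.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np


def mantel_exact_p(a, b, inc, tail="greater", groups=None):
    """Exact Mantel p by enumerating every (group-constrained) label
    permutation of B.  ``inc`` is the boolean cell-inclusion matrix."""
    n = a.shape[0]

    def z_of(bm):
        total = 0.0
        for i in range(n):
            for j in range(n):
                if inc[i, j]:
                    total += a[i, j] * bm[i, j]
        return total

    z_obs = z_of(b)
    if groups is None:
        groups = [list(range(n))]
    all_perms = []

    def build(k, current):
        if k == len(groups):
            all_perms.append(list(current))
            return
        g = groups[k]
        for perm in permutations(g):
            for slot, val in zip(g, perm):
                current[slot] = val
            build(k + 1, current)

    build(0, list(range(n)))
    zs = []
    for pi in all_perms:
        bm = np.empty_like(b)
        for i in range(n):
            for j in range(n):
                bm[i, j] = b[pi[i], pi[j]]
        zs.append(z_of(bm))
    zs = np.array(zs)
    if tail == "greater":
        k = np.sum(zs >= z_obs - 1e-12)
    elif tail == "less":
        k = np.sum(zs <= z_obs + 1e-12)
    else:
        mu = zs.mean()
        k = np.sum(np.abs(zs - mu) >= abs(z_obs - mu) - 1e-12)
    return k / len(zs)


def davids_score_oracle(w):
    """The four David's Score sums, computed dyad by dyad."""
    n = w.shape[0]
    p = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            nij = w[i, j] + w[j, i]
            if nij > 0:
                p[i, j] = w[i, j] / nij
    ds = np.zeros(n)
    for i in range(n):
        w1 = sum(p[i, j] for j in range(n))
        l1 = sum(p[j, i] for j in range(n))
        w2 = sum(p[i, j] * sum(p[j, k] for k in range(n)) for j in range(n))
        l2 = sum(p[j, i] * sum(p[k, j] for k in range(n)) for j in range(n))
        ds[i] = w1 + w2 - l1 - l2
    return ds


def ward_merge_oracle(points):
    """Greedy Ward agglomeration evaluating every candidate merge at each
    step.  Returns (merge pairs as frozensets of frozensets of leaf
    indices, sum-of-squares increments)."""
    points = np.asarray(points, dtype=float)
    clusters = [frozenset([i]) for i in range(len(points))]

    def ss(cluster):
        member_pts = points[sorted(cluster)]
        centroid = member_pts.mean(axis=0)
        return float(((member_pts - centroid) ** 2).sum())

    merges, heights = [], []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                delta = ss(clusters[i] | clusters[j]) - ss(clusters[i]) - ss(clusters[j])
                if best is None or delta < best[0] - 1e-12:
                    best = (delta, i, j)
        delta, i, j = best
        merges.append(frozenset([clusters[i], clusters[j]]))
        heights.append(delta)
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return merges, heights


def cophenetic_oracle(merges, heights, n):
    """Cophenetic distances by double loop: for each pair of leaves, the
    height of the lowest merge whose member set contains both.
    ``merges`` follows the scipy convention (indices into leaves then
    created clusters)."""
    members = {i: {i} for i in range(n)}
    coph = np.zeros((n, n))
    done = np.zeros((n, n), dtype=bool)
    for k, (a, b) in enumerate(merges):
        sa, sb = members[int(a)], members[int(b)]
        for i in sa:
            for j in sb:
                coph[i, j] = coph[j, i] = heights[k]
                done[i, j] = done[j, i] = True
        members[n + k] = sa | sb
    assert done[np.triu_indices(n, 1)].all()
    return coph


def pearson_oracle(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))


def modularity_oracle(a, labels):
    """Weighted modularity by explicit double loop."""
    n = a.shape[0]
    k = [sum(a[i, j] for j in range(n)) for i in range(n)]
    two_m = sum(k)
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += a[i, j] - k[i] * k[j] / two_m
    return q / two_m


def set_partitions(n):
    """All partitions of range(n) as label vectors (restricted growth)."""
    labels = [0] * n

    def rec(i, used):
        if i == n:
            yield list(labels)
            return
        for c in range(used + 1):
            labels[i] = c
            yield from rec(i + 1, max(used, c + 1))

    yield from rec(1, 1)


def best_partition_oracle(a, max_communities=None):
    """Exhaustive modularity optimum over all partitions."""
    n = a.shape[0]
    best_q, best_labels = -np.inf, None
    for labels in set_partitions(n):
        if max_communities and len(set(labels)) > max_communities:
            continue
        q = modularity_oracle(a, labels)
        if q > best_q:
            best_q, best_labels = q, labels
    return best_q, best_labels


def best_bipartition_oracle(a):
    """Best modularity over all 2-way splits (and the trivial 1-community
    partition)."""
    n = a.shape[0]
    best_q = modularity_oracle(a, [0] * n)
    for code in range(1, 2 ** (n - 1)):
        labels = [(code >> i) & 1 for i in range(n)]
        best_q = max(best_q, modularity_oracle(a, labels))
    return best_q
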