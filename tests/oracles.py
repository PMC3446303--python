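"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths of the package: clustering
recomputes maxima over raw point pairs instead of running a distance-matrix
update; components come from a hand-rolled BFS instead of networkx; module
edge counts come from an exhaustive double loop over leaf pairs.
"""

from __future__ import annotations

import math
from collections import deque
from itertools import combinations


def naive_complete_linkage(X, labels):
    """O(n^3) agglomeration: at each step recompute every cluster pair's
    maximum pairwise Euclidean distance from the raw points and merge the
    minimum, breaking ties by the lexicographically smallest pair of
    cluster minimum labels.  Returns merges in the (left, right, height)
    merge-table convention (negative refs = leaves)."""
    n = len(X)

    def dist(i, j):
        return math.sqrt(sum((a - b) ** 2 for a, b in zip(X[i], X[j])))

    clusters = {i: ([i], -(i + 1), labels[i]) for i in range(n)}
    merges = []
    for step in range(1, n):
        best = None
        for i, j in combinations(sorted(clusters), 2):
            mi, ri, li = clusters[i]
            mj, rj, lj = clusters[j]
            d = max(dist(a, b) for a in mi for b in mj)
            lo, hi = sorted((li, lj))
            cand = (d, lo, hi, i, j)
            if best is None or cand[:3] < best[:3]:
                best = cand
        d, lo, hi, i, j = best
        mi, ri, li = clusters[i]
        mj, rj, lj = clusters[j]
        left, right = (ri, rj) if li <= lj else (rj, ri)
        merges.append((left, right, d))
        del clusters[j]
        clusters[i] = (mi + mj, step, min(li, lj))
    return merges


def bfs_components(edges, subset):
    """All connected components of the subgraph induced by ``subset``,
    via an explicit breadth-first search over an adjacency map."""
    subset = set(subset)
    adj = {v: set() for v in subset}
    for u, v in edges:
        if u in subset and v in subset:
            adj[u].add(v)
            adj[v].add(u)
    seen = set()
    comps = []
    for start in sorted(subset):
        if start in seen:
            continue
        comp = {start}
        q = deque([start])
        while q:
            cur = q.popleft()
            for nb in adj[cur]:
                if nb not in comp:
                    comp.add(nb)
                    q.append(nb)
        seen |= comp
        comps.append(comp)
    return comps


def largest_component_oracle(edges, subset):
    comps = bfs_components(edges, subset)
    if not comps:
        return set()
    # largest; ties by smallest lexicographic minimum member
    return sorted(comps, key=lambda c: (-len(c), min(c)))[0]


def cross_pair_count(edges, leaves_a, leaves_b):
    """Exhaustive count of edges with one endpoint in each leaf set."""
    edge_set = {frozenset(e) for e in edges}
    return sum(
        1 for a in leaves_a for b in leaves_b if frozenset((a, b)) in edge_set
    )
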