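"""Agglomerative clustering and its superimposition onto a network.

A :class:`Dendrogram` is the binary merge tree produced by complete-linkage
agglomerative clustering (the maximum pairwise distance between clusters
drives each merge).  Merge references follow the convention of standard
hierarchical-clustering merge tables: negative integers -(i+1) reference
leaf i, positive integers reference prior (1-based) merge steps.

:func:`nest_dendrogram` maps a cut of the tree onto a compound graph as
nested containers — each cluster with at least two members becomes a
container enclosing its leaves, and deeper cut levels become containers
nested inside their parents.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import CONTAINER, GraphError, HierGraph

__all__ = [
    "Dendrogram",
    "NestHCParams",
    "build_dendrogram",
    "rootdist",
    "cut_clusters",
    "nest_dendrogram",
    "threshold_for_k",
]


@dataclass
class Dendrogram:
    """Binary merge tree with heights over labelled leaf objects."""

    leaf_labels: list[str]
    #: (left, right, height) per step; refs: -(i+1) = leaf i, j >= 1 = step j
    merges: list[tuple[int, int, float]]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def __post_init__(self) -> None:
        n = self.n_leaves
        if n < 2:
            raise ValueError("a dendrogram needs at least 2 leaves")
        if len(self.merges) != n - 1:
            raise ValueError(
                f"expected {n - 1} merges for {n} leaves, got {len(self.merges)}"
            )
        seen: set[int] = set()
        for step, (a, b, h) in enumerate(self.merges, start=1):
            for ref in (a, b):
                if ref == 0 or ref < -n or ref >= step:
                    raise ValueError(f"invalid merge reference {ref} at step {step}")
                if ref in seen:
                    raise ValueError(f"reference {ref} used twice")
                seen.add(ref)
            if h < 0:
                raise ValueError(f"negative merge height at step {step}")

    def leaves_under(self, ref: int) -> list[int]:
        """Leaf indices under a reference (a single leaf for negative refs)."""
        if ref < 0:
            return [-ref - 1]
        out: list[int] = []
        stack = [ref]
        while stack:
            r = stack.pop()
            if r < 0:
                out.append(-r - 1)
            else:
                a, b, _ = self.merges[r - 1]
                stack.extend((a, b))
        return sorted(out)

    def children(self, step: int) -> tuple[int, int]:
        a, b, _ = self.merges[step - 1]
        return a, b

    def height(self, step: int) -> float:
        return self.merges[step - 1][2]

    @property
    def root(self) -> int:
        return len(self.merges)


@dataclass
class NestHCParams:
    """How a dendrogram cut is mapped onto the network.

    metric="rootdist" cuts at an integer merge depth measured from the root
    (the root merge has depth 0); metric="height" severs all merges above a
    real height threshold.  ``nlev`` counts how many successive hierarchy
    levels are mapped as nested containers.
    """

    metric: str = "rootdist"
    cutlevel: float = 1
    nlev: int = 1

    def __post_init__(self) -> None:
        if self.metric not in ("rootdist", "height"):
            raise ValueError(f"unknown cut metric: {self.metric!r}")
        if self.nlev < 1:
            raise ValueError("nlev must be >= 1")
        if self.metric == "rootdist" and (
            self.cutlevel < 0 or int(self.cutlevel) != self.cutlevel
        ):
            raise ValueError("rootdist cutlevel must be a nonnegative integer")


def build_dendrogram(
    matrix: np.ndarray,
    labels: Optional[Sequence[str]] = None,
) -> Dendrogram:
    """Complete-linkage agglomerative clustering with Euclidean distances.

    Rows are objects, columns features.  At each step the pair of clusters
    with the minimal complete-linkage distance (maximum pairwise Euclidean
    distance between members) is merged; ties are broken by the
    lexicographically smallest pair of cluster minimum labels, so the result
    is bit-reproducible without a seed.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows to cluster")
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values")
    if labels is None:
        labels = [str(i) for i in range(n)]
    labels = list(labels)
    if len(labels) != n:
        raise ValueError("label count does not match row count")
    if len(set(labels)) != n:
        raise ValueError("labels must be unique")

    D = squareform(pdist(X, metric="euclidean"))
    # active cluster state: ref (-i-1 leaf / step), min label, row index in D
    active: dict[int, tuple[int, str]] = {
        i: (-(i + 1), labels[i]) for i in range(n)
    }
    merges: list[tuple[int, int, float]] = []
    for step in range(1, n):
        best: Optional[tuple[float, str, str, int, int]] = None
        keys = sorted(active)
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                i, j = keys[ai], keys[bi]
                d = D[i, j]
                la, lb = active[i][1], active[j][1]
                lo, hi = (la, lb) if la < lb else (lb, la)
                cand = (d, lo, hi, i, j)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        assert best is not None
        d, lo, _, i, j = best
        ref_i, lab_i = active[i]
        ref_j, lab_j = active[j]
        # order children so the smaller minimum label comes first
        if lab_i <= lab_j:
            merges.append((ref_i, ref_j, float(d)))
        else:
            merges.append((ref_j, ref_i, float(d)))
        # Lance-Williams update for complete linkage: new distance is the max
        D[i, :] = np.maximum(D[i, :], D[j, :])
        D[:, i] = D[i, :]
        D[i, i] = 0.0
        del active[j]
        active[i] = (step, min(lab_i, lab_j))
    return Dendrogram(leaf_labels=labels, merges=merges)


def rootdist(d: Dendrogram) -> dict[int, int]:
    """Depth of every merge step measured from the root (root depth 0)."""
    depth = {d.root: 0}
    for step in range(d.root, 0, -1):
        a, b, _ = d.merges[step - 1]
        for ref in (a, b):
            if ref > 0:
                depth[ref] = depth[step] + 1
    return depth


def _cut_refs(d: Dendrogram, params: NestHCParams) -> list[int]:
    """References (merge steps or leaf refs) of the cluster roots of a cut."""
    if params.metric == "rootdist":
        level = int(params.cutlevel)
        depth = rootdist(d)
        roots: list[int] = []
        stack = [d.root]
        while stack:
            ref = stack.pop()
            if ref < 0:
                roots.append(ref)  # leaf detaching above the cut: singleton
                continue
            if depth[ref] == level:
                roots.append(ref)
            else:
                a, b, _ = d.merges[ref - 1]
                stack.extend((a, b))
        return roots
    # metric == "height": sever merges with height > threshold
    t = float(params.cutlevel)
    roots = []
    stack = [d.root]
    while stack:
        ref = stack.pop()
        if ref < 0 or d.height(ref) <= t:
            roots.append(ref)
        else:
            a, b, _ = d.merges[ref - 1]
            stack.extend((a, b))
    return roots


def cut_clusters(d: Dendrogram, params: NestHCParams) -> list[set[str]]:
    """Cut the tree into a disjoint cover of the leaves.

    With metric="rootdist" the clusters are the maximal subtrees whose root
    merge sits at depth ``cutlevel``; leaves detaching nearer the root become
    singletons, and a cut deeper than the tree yields all singletons.  With
    metric="height" clusters arise from severing all merges above the
    threshold.
    """
    clusters = [
        {d.leaf_labels[i] for i in d.leaves_under(ref)}
        for ref in _cut_refs(d, params)
    ]
    return sorted(clusters, key=lambda c: min(c))


def threshold_for_k(d: Dendrogram, k: int) -> float:
    """A height threshold whose cut severs exactly the ``k - 1`` top merges.

    The classic "cut the tree into k groups" device: with distinct merge
    heights the returned threshold makes ``cut_clusters`` (metric="height")
    produce exactly k clusters; with tied heights the count may differ.
    """
    m = d.root
    if not 1 <= k <= d.n_leaves:
        raise ValueError(f"k must be in [1, {d.n_leaves}]")
    hs = sorted(h for _, _, h in d.merges)
    if k == 1:
        return hs[-1]
    if k > m:
        return 0.0 if hs[0] > 0 else -1.0
    return (hs[m - k] + hs[m - k + 1]) / 2.0


def nest_dendrogram(
    g: HierGraph,
    d: Dendrogram,
    params: NestHCParams,
    prefix: str = "M",
) -> list[str]:
    """Superimpose a dendrogram cut onto a graph as nested containers.

    Every cluster of :func:`cut_clusters` with >= 2 members becomes a
    container holding its leaves; for ``nlev > 1`` each cluster's child
    subtrees (one merge-depth step further down) are nested inside it,
    recursively.  Singleton clusters create no container.  Prior containment
    of the affected leaves is replaced; containers emptied by the
    re-parenting are pruned.  Returns the created container ids, outermost
    level first.
    """
    missing = set(d.leaf_labels) - set(g.leaf_ids())
    if missing:
        raise GraphError(
            f"dendrogram labels not in graph: {sorted(missing)[:5]}"
        )

    created: list[str] = []
    counter = [0]

    def fresh_id() -> str:
        counter[0] += 1
        cid = f"{prefix}{counter[0]}"
        while cid in g:
            counter[0] += 1
            cid = f"{prefix}{counter[0]}"
        return cid

    def materialize(ref: int, level: int, parent: Optional[str]) -> None:
        leaves = [d.leaf_labels[i] for i in d.leaves_under(ref)]
        if ref < 0 or len(leaves) < 2:
            # singleton: no container; an explicit parent adopts the leaf
            for lab in leaves:
                g._set_parent(lab, parent)
            return
        cid = fresh_id()
        g.add_node(cid, kind=CONTAINER, parent=parent)
        created.append(cid)
        if level < params.nlev:
            a, b = d.children(ref)
            for child in (a, b):
                materialize(child, level + 1, cid)
        else:
            for lab in leaves:
                g._set_parent(lab, cid)

    roots = sorted(
        _cut_refs(d, params),
        key=lambda r: min(d.leaf_labels[i] for i in d.leaves_under(r)),
    )
    for ref in roots:
        # singleton clusters create no container and keep their prior parent,
        # so a cut deeper than the tree leaves the graph unchanged
        if ref >= 0 and len(d.leaves_under(ref)) >= 2:
            materialize(ref, 1, None)

    _prune_empty_containers(g, exclude=set(created))
    return created


def _prune_empty_containers(g: HierGraph, exclude: set[str]) -> None:
    changed = True
    while changed:
        changed = False
        for cid in g.container_ids():
            if cid in exclude:
                continue
            if not g.children(cid):
                g.unnest(cid)
                changed = True
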