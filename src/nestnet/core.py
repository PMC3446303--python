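"""Two-layer compound graph: a containment forest over an undirected leaf graph.

The model mirrors the data structure used by hierarchical network viewers:
an acyclic containment layer (every node has at most one parent, so the
parent pointers form a forest of "containers") superimposed on an
undirected, weighted graph over the lowest-level ("leaf") nodes.  Edges
between two leaves live on the leaf layer; edges touching at least one
container are horizontal "association" edges, external to the hierarchy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import networkx as nx

__all__ = [
    "LEAF",
    "CONTAINER",
    "ASSOCIATION",
    "NodeRecord",
    "Edge",
    "HierGraph",
    "GraphError",
]

LEAF = "leaf"
CONTAINER = "container"
ASSOCIATION = "association"


class GraphError(ValueError):
    """Raised when an operation would violate a structural invariant."""


@dataclass
class NodeRecord:
    """A vertex of the compound graph.

    ``kind`` is ``"leaf"`` for lowest-level nodes (genes, proteins, ...) or
    ``"container"`` for special nodes that enclose a set of members.  The
    ``parent`` pointer, when set, names the enclosing container; leaves
    never have children.  ``attrs`` holds scalar annotations (label, color,
    size, logFC, kb distance to a binding site, planted module, ...).
    """

    id: str
    kind: str = LEAF
    parent: Optional[str] = None
    attrs: dict = field(default_factory=dict)


@dataclass
class Edge:
    """An undirected edge stored canonically with ``u < v`` (lexicographic).

    ``layer`` is ``"leaf"`` when both endpoints are leaves, otherwise
    ``"association"`` (a horizontal, non-hierarchical link that may touch
    containers).  Weights are nonnegative.
    """

    u: str
    v: str
    weight: float = 1.0
    layer: str = LEAF

    @property
    def key(self) -> tuple[str, str]:
        return (self.u, self.v)


def _canon(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u < v else (v, u)


class HierGraph:
    """Compound graph with validated containment and leaf-level edges.

    All mutating operations preserve three invariants: node ids are unique;
    the containment relation is a forest (acyclic, at most one parent per
    node, leaves childless); edges are canonical undirected pairs, at most
    one per unordered pair, with no self-loops.
    """

    def __init__(self) -> None:
        self._nodes: dict[str, NodeRecord] = {}
        self._edges: dict[tuple[str, str], Edge] = {}
        self._children: dict[str, set[str]] = {}

    # ------------------------------------------------------------------ nodes

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._nodes

    def __len__(self) -> int:
        return len(self._nodes)

    @property
    def node_count(self) -> int:
        return len(self._nodes)

    @property
    def edge_count(self) -> int:
        return len(self._edges)

    def node(self, node_id: str) -> NodeRecord:
        try:
            return self._nodes[node_id]
        except KeyError:
            raise GraphError(f"unknown node id: {node_id!r}") from None

    def nodes(self) -> Iterator[NodeRecord]:
        return iter(self._nodes.values())

    def node_ids(self) -> list[str]:
        return sorted(self._nodes)

    def leaf_ids(self) -> list[str]:
        return sorted(n.id for n in self._nodes.values() if n.kind == LEAF)

    def container_ids(self) -> list[str]:
        return sorted(n.id for n in self._nodes.values() if n.kind == CONTAINER)

    def add_node(
        self,
        node_id: str,
        kind: str = LEAF,
        parent: Optional[str] = None,
        **attrs,
    ) -> NodeRecord:
        if node_id in self._nodes:
            raise GraphError(f"duplicate node id: {node_id!r}")
        if kind not in (LEAF, CONTAINER):
            raise GraphError(f"invalid node kind: {kind!r}")
        if parent is not None:
            p = self.node(parent)
            if p.kind != CONTAINER:
                raise GraphError(f"parent {parent!r} is not a container")
        rec = NodeRecord(id=node_id, kind=kind, parent=parent, attrs=dict(attrs))
        self._nodes[node_id] = rec
        if kind == CONTAINER:
            self._children[node_id] = set()
        if parent is not None:
            self._children[parent].add(node_id)
        return rec

    # ------------------------------------------------------------------ edges

    def edges(self, layer: Optional[str] = None) -> list[Edge]:
        es = sorted(self._edges.values(), key=lambda e: e.key)
        if layer is None:
            return es
        return [e for e in es if e.layer == layer]

    def get_edge(self, u: str, v: str) -> Optional[Edge]:
        return self._edges.get(_canon(u, v))

    def has_edge(self, u: str, v: str) -> bool:
        return _canon(u, v) in self._edges

    def add_edge(self, u: str, v: str, weight: float = 1.0) -> Edge:
        """Add (or re-weight) the canonical undirected edge between u and v.

        The layer is inferred: leaf--leaf pairs go on the leaf layer, any
        pair touching a container becomes an association edge.  Re-adding an
        existing pair replaces its weight.
        """
        if u == v:
            raise GraphError(f"self-loop rejected: {u!r}")
        nu, nv = self.node(u), self.node(v)
        if weight < 0:
            raise GraphError(f"negative edge weight: {weight}")
        layer = LEAF if (nu.kind == LEAF and nv.kind == LEAF) else ASSOCIATION
        cu, cv = _canon(u, v)
        edge = Edge(cu, cv, float(weight), layer)
        self._edges[(cu, cv)] = edge
        return edge

    def remove_edge(self, u: str, v: str) -> None:
        key = _canon(u, v)
        if key not in self._edges:
            raise GraphError(f"no edge between {u!r} and {v!r}")
        del self._edges[key]

    # ------------------------------------------------------------ containment

    def children(self, container_id: str) -> list[str]:
        n = self.node(container_id)
        if n.kind != CONTAINER:
            raise GraphError(f"{container_id!r} is not a container")
        return sorted(self._children[container_id])

    def ancestors(self, node_id: str) -> list[str]:
        """Chain of enclosing containers, nearest first; length = depth."""
        self.node(node_id)
        out: list[str] = []
        cur = self._nodes[node_id].parent
        while cur is not None:
            out.append(cur)
            cur = self._nodes[cur].parent
        return out

    def depth(self, node_id: str) -> int:
        return len(self.ancestors(node_id))

    def leaf_descendants(self, node_id: str) -> set[str]:
        """All leaves reachable downward from a node (itself if a leaf)."""
        n = self.node(node_id)
        if n.kind == LEAF:
            return {node_id}
        out: set[str] = set()
        stack = [node_id]
        while stack:
            cur = stack.pop()
            for ch in self._children.get(cur, ()):
                if self._nodes[ch].kind == LEAF:
                    out.add(ch)
                else:
                    stack.append(ch)
        return out

    def _set_parent(self, node_id: str, parent: Optional[str]) -> None:
        rec = self._nodes[node_id]
        if rec.parent is not None:
            self._children[rec.parent].discard(node_id)
        rec.parent = parent
        if parent is not None:
            self._children[parent].add(node_id)

    def _deepest_common_ancestor(self, ids: Iterable[str]) -> Optional[str]:
        chains = [self.ancestors(i) for i in ids]
        common = set(chains[0])
        for c in chains[1:]:
            common &= set(c)
        for anc in chains[0]:  # nearest-first order of any chain
            if anc in common:
                return anc
        return None

    def nest(
        self,
        members: Iterable[str],
        container_id: Optional[str] = None,
        parent: Optional[str] = None,
    ) -> str:
        """Enclose ``members`` in a new container; return its id.

        The container's own parent defaults to the former deepest common
        ancestor of the members (none if they share no enclosing container).
        An explicit ``parent`` may place the container elsewhere, validated
        against containment cycles.
        """
        members = sorted(set(members))
        if not members:
            raise GraphError("cannot nest an empty member set")
        for m in members:
            self.node(m)
        if container_id is None:
            container_id = self._fresh_container_id()
        elif container_id in self._nodes:
            raise GraphError(f"duplicate node id: {container_id!r}")

        if parent is not None:
            p = self.node(parent)
            if p.kind != CONTAINER:
                raise GraphError(f"parent {parent!r} is not a container")
            # the new container must not enclose an ancestor of its own parent
            chain = [parent] + self.ancestors(parent)
            if any(m in chain for m in members):
                raise GraphError(
                    f"containment cycle: {parent!r} is a descendant of a member"
                )
        else:
            dca = self._deepest_common_ancestor(members)
            # a member that is itself an ancestor of other members can be the
            # DCA; re-parenting it under the new container is still acyclic as
            # long as the container hangs off the member's former parent
            while dca in members:
                dca = self._nodes[dca].parent
            parent = dca

        self.add_node(container_id, kind=CONTAINER, parent=parent)
        for m in members:
            self._set_parent(m, container_id)
        return container_id

    def unnest(self, container_id: str) -> None:
        """Dissolve a container: children are promoted to its parent.

        Leaf-layer edges are untouched; association edges incident to the
        removed container are dropped (their endpoint disappears).
        """
        rec = self.node(container_id)
        if rec.kind != CONTAINER:
            raise GraphError(f"cannot unnest leaf {container_id!r}")
        grandparent = rec.parent
        for ch in list(self._children[container_id]):
            self._set_parent(ch, grandparent)
        if grandparent is not None:
            self._children[grandparent].discard(container_id)
        for key in [k for k in self._edges if container_id in k]:
            del self._edges[key]
        del self._children[container_id]
        del self._nodes[container_id]

    def _fresh_container_id(self) -> str:
        i = len(self._children) + 1
        while f"N{i}" in self._nodes:
            i += 1
        return f"N{i}"

    # ------------------------------------------------------------- components

    def leaf_graph(self) -> nx.Graph:
        """The leaf layer as a networkx Graph (weights as edge attributes)."""
        G = nx.Graph()
        G.add_nodes_from(self.leaf_ids())
        for e in self.edges(layer=LEAF):
            G.add_edge(e.u, e.v, weight=e.weight)
        return G

    def largest_connected_component(self, subset: Iterable[str]) -> set[str]:
        """Node set of the largest component of the induced leaf subgraph.

        Ties are broken by the smallest lexicographic minimum member id, so
        the result is deterministic.  An empty subset yields an empty set.
        """
        subset = set(subset)
        leaf_set = set(self.leaf_ids())
        bad = subset - leaf_set
        if bad:
            raise GraphError(f"subset contains non-leaf ids: {sorted(bad)[:5]}")
        if not subset:
            return set()
        sub = self.leaf_graph().subgraph(subset)
        comps = list(nx.connected_components(sub))
        return max(comps, key=lambda c: (len(c), _neg_min(c)))

    # ------------------------------------------------------------- validation

    def validate(self) -> None:
        """Check every structural invariant; raise GraphError on violation."""
        for rec in self._nodes.values():
            if rec.parent is not None:
                if rec.parent not in self._nodes:
                    raise GraphError(f"dangling parent {rec.parent!r} of {rec.id!r}")
                if self._nodes[rec.parent].kind != CONTAINER:
                    raise GraphError(f"parent {rec.parent!r} is not a container")
            if rec.kind == LEAF and self._children.get(rec.id):
                raise GraphError(f"leaf {rec.id!r} has children")
        # acyclicity: walking parent pointers must terminate
        for rec in self._nodes.values():
            seen = {rec.id}
            cur = rec.parent
            while cur is not None:
                if cur in seen:
                    raise GraphError(f"containment cycle through {cur!r}")
                seen.add(cur)
                cur = self._nodes[cur].parent
        for (u, v), e in self._edges.items():
            if (u, v) != _canon(u, v) or u == v:
                raise GraphError(f"non-canonical edge ({u!r}, {v!r})")
            if u not in self._nodes or v not in self._nodes:
                raise GraphError(f"edge endpoint missing: ({u!r}, {v!r})")
            both_leaves = (
                self._nodes[u].kind == LEAF and self._nodes[v].kind == LEAF
            )
            if e.layer == LEAF and not both_leaves:
                raise GraphError(f"leaf-layer edge touches a container: {u} -- {v}")
            if e.layer == ASSOCIATION and both_leaves:
                # leaf--leaf association edges arise only by explicit request
                # through re-layering; the constructor never makes them
                pass

    # ------------------------------------------------------------------ misc

    def copy(self) -> "HierGraph":
        g = HierGraph()
        for rec in self._nodes.values():
            g._nodes[rec.id] = NodeRecord(rec.id, rec.kind, rec.parent, dict(rec.attrs))
        g._children = {k: set(v) for k, v in self._children.items()}
        g._edges = {k: Edge(e.u, e.v, e.weight, e.layer) for k, e in self._edges.items()}
        return g

    def __repr__(self) -> str:
        return (
            f"HierGraph({len(self.leaf_ids())} leaves, "
            f"{len(self.container_ids())} containers, {self.edge_count} edges)"
        )


def _neg_min(component: set[str]) -> tuple[int, ...]:
    # sort key helper: prefer the lexicographically smallest minimum id when
    # component sizes tie; max() picks the largest key, so invert bytewise
    m = min(component)
    return tuple(-b for b in m.encode())


def from_directed_edges(pairs: Iterable[tuple[str, str, float]]) -> HierGraph:
    """Build a leaf graph from possibly-directed (u, v, w) triples.

    Direction is collapsed (the leaf layer is undirected); when both
    orientations occur with different weights, the last one wins and a
    warning is emitted.
    """
    g = HierGraph()
    clashes = []
    for u, v, w in pairs:
        for x in (u, v):
            if x not in g:
                g.add_node(x)
        prev = g.get_edge(u, v)
        if prev is not None and prev.weight != w:
            clashes.append((u, v))
        g.add_edge(u, v, w)
    if clashes:
        warnings.warn(
            f"{len(clashes)} edge pair(s) appeared in both orientations with "
            "different weights; the last weight wins",
            stacklevel=2,
        )
    return g
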