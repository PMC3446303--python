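"""Readers and writers for hierarchical networks and related tables.

GraphML uses the compound-graph dialect: a container node element carries a
nested ``<graph>`` element holding its members, so arbitrary nesting depth
survives a round trip and the files open in common graph tools.  All edges
(leaf layer and association layer) are listed in the top-level graph with
``weight`` and ``layer`` data keys.

JSON is a direct, lossless dump of nodes (id, kind, parent, attrs) and
edges.  Edge lists are TSV with columns source, target and optional weight
and layer; import collapses duplicates and direction (the leaf layer is
undirected).  Linkage tables serialize dendrograms in the standard
merge-table convention: negative integers reference leaves, positive
integers reference prior merge steps.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional, Union

import pandas as pd
from lxml import etree

from .core import CONTAINER, LEAF, GraphError, HierGraph
from .dendro import Dendrogram
from .render import RenderSpec, export_svg  # re-exported: part of the io surface

__all__ = [
    "RenderSpec",
    "export_svg",
    "write_graphml",
    "read_graphml",
    "write_json",
    "read_json",
    "read_edgelist",
    "write_edgelist",
    "write_linkage",
    "read_linkage",
    "write_layout",
    "read_layout",
]

_GRAPHML_NS = "http://graphml.graphdrawing.org/xmlns"

_TYPES = {bool: "boolean", int: "long", float: "double", str: "string"}
_CASTS = {"boolean": lambda s: s == "true", "long": int, "double": float,
          "string": str, "int": int, "float": float}

PathLike = Union[str, Path]


def _attr_type(value) -> str:
    for py, name in _TYPES.items():
        if type(value) is py:
            return name
    return "string"


# ---------------------------------------------------------------- GraphML


def write_graphml(g: HierGraph, path: PathLike) -> None:
    """Write the compound graph as nested-graph GraphML."""
    g.validate()
    root = etree.Element("graphml", nsmap={None: _GRAPHML_NS})

    # declare one key per attribute name, typed from its first occurrence
    keys: dict[str, str] = {}
    for rec in sorted(g.nodes(), key=lambda r: r.id):
        for name, value in rec.attrs.items():
            keys.setdefault(name, _attr_type(value))
    for name in sorted(keys):
        el = etree.SubElement(root, "key")
        el.set("id", name)
        el.set("for", "node")
        el.set("attr.name", name)
        el.set("attr.type", keys[name])
    for name, typ in (("weight", "double"), ("layer", "string")):
        el = etree.SubElement(root, "key")
        el.set("id", f"e_{name}")
        el.set("for", "edge")
        el.set("attr.name", name)
        el.set("attr.type", typ)

    top = etree.SubElement(root, "graph")
    top.set("id", "G")
    top.set("edgedefault", "undirected")

    def emit_node(parent_el: etree._Element, node_id: str) -> None:
        rec = g.node(node_id)
        el = etree.SubElement(parent_el, "node")
        el.set("id", rec.id)
        for name in sorted(rec.attrs):
            d = etree.SubElement(el, "data")
            d.set("key", name)
            d.text = _scalar_to_text(rec.attrs[name])
        if rec.kind == CONTAINER:
            sub = etree.SubElement(el, "graph")
            sub.set("id", f"{rec.id}:")
            sub.set("edgedefault", "undirected")
            for child in g.children(rec.id):
                emit_node(sub, child)

    roots = sorted(n.id for n in g.nodes() if n.parent is None)
    for nid in roots:
        emit_node(top, nid)

    for e in g.edges():
        el = etree.SubElement(top, "edge")
        el.set("source", e.u)
        el.set("target", e.v)
        d = etree.SubElement(el, "data")
        d.set("key", "e_weight")
        d.text = repr(e.weight)
        d = etree.SubElement(el, "data")
        d.set("key", "e_layer")
        d.text = e.layer

    tree = etree.ElementTree(root)
    tree.write(str(path), pretty_print=True, xml_declaration=True,
               encoding="UTF-8")


def _scalar_to_text(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def read_graphml(path: PathLike) -> HierGraph:
    """Read nested-graph GraphML back into a compound graph."""
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise GraphError(f"malformed GraphML in {path}: {exc}") from None
    root = tree.getroot()
    ns = {"g": _GRAPHML_NS} if root.tag.startswith("{") else None

    def q(tag: str) -> str:
        return f"{{{_GRAPHML_NS}}}{tag}" if ns else tag

    keys: dict[str, str] = {}
    for el in root.findall(q("key")):
        keys[el.get("id")] = el.get("attr.type", "string")

    top = root.find(q("graph"))
    if top is None:
        raise GraphError(f"{path}: no <graph> element")
    g = HierGraph()

    def read_node(el: etree._Element, parent: Optional[str]) -> None:
        nid = el.get("id")
        if nid is None:
            raise GraphError(f"{path}: <node> without id (line {el.sourceline})")
        sub = el.find(q("graph"))
        attrs = {}
        for d in el.findall(q("data")):
            key = d.get("key")
            cast = _CASTS.get(keys.get(key, "string"), str)
            attrs[key] = cast(d.text if d.text is not None else "")
        kind = CONTAINER if sub is not None else LEAF
        g.add_node(nid, kind=kind, parent=parent, **attrs)
        if sub is not None:
            for child in sub.findall(q("node")):
                read_node(child, nid)

    for el in top.findall(q("node")):
        read_node(el, None)

    for el in top.iter(q("edge")):
        u, v = el.get("source"), el.get("target")
        weight, layer = 1.0, None
        for d in el.findall(q("data")):
            if d.get("key") == "e_weight":
                weight = float(d.text)
            elif d.get("key") == "e_layer":
                layer = d.text
        for x in (u, v):
            if x not in g:
                raise GraphError(
                    f"{path}: edge references missing id {x!r} "
                    f"(line {el.sourceline})"
                )
        edge = g.add_edge(u, v, weight)
        if layer is not None and layer != edge.layer:
            raise GraphError(
                f"{path}: edge {u!r}--{v!r} declares layer {layer!r} but "
                f"endpoint kinds imply {edge.layer!r} (line {el.sourceline})"
            )
    g.validate()
    return g


# ------------------------------------------------------------------- JSON


def write_json(g: HierGraph, path: PathLike) -> None:
    g.validate()
    payload = {
        "nodes": [
            {"id": n.id, "kind": n.kind, "parent": n.parent, "attrs": n.attrs}
            for n in sorted(g.nodes(), key=lambda r: r.id)
        ],
        "edges": [
            {"u": e.u, "v": e.v, "weight": e.weight, "layer": e.layer}
            for e in g.edges()
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_json(path: PathLike) -> HierGraph:
    payload = json.loads(Path(path).read_text())
    g = HierGraph()
    records = payload.get("nodes", [])
    # parents may appear after children in arbitrary order; add containers
    # topologically by repeated passes
    pending = list(records)
    while pending:
        progressed = []
        for rec in pending:
            parent = rec.get("parent")
            if parent is None or parent in g:
                g.add_node(
                    rec["id"],
                    kind=rec.get("kind", LEAF),
                    parent=parent,
                    **rec.get("attrs", {}),
                )
            else:
                progressed.append(rec)
        if len(progressed) == len(pending):
            missing = sorted({r.get("parent") for r in progressed})
            raise GraphError(f"{path}: dangling parent reference(s) {missing}")
        pending = progressed
    for e in payload.get("edges", []):
        g.add_edge(e["u"], e["v"], e.get("weight", 1.0))
    g.validate()
    return g


# -------------------------------------------------------------- edge lists


def read_edgelist(path: PathLike) -> HierGraph:
    """Import a TSV edge list (source, target[, weight[, layer]]).

    The leaf layer is undirected: rows are collapsed regardless of column
    order, the last weight wins, and a warning is emitted when both
    orientations carry different weights.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    cols = {c.lower(): c for c in df.columns}
    if "source" not in cols or "target" not in cols:
        raise GraphError(f"{path}: edge list needs 'source' and 'target' columns")
    g = HierGraph()
    clashes = 0
    for _, row in df.iterrows():
        u, v = str(row[cols["source"]]), str(row[cols["target"]])
        w = float(row[cols["weight"]]) if "weight" in cols and pd.notna(
            row[cols["weight"]]
        ) else 1.0
        for x in (u, v):
            if x not in g:
                g.add_node(x, label=x)
        prev = g.get_edge(u, v)
        if prev is not None and prev.weight != w:
            clashes += 1
        g.add_edge(u, v, w)
    if clashes:
        warnings.warn(
            f"{path}: {clashes} duplicate edge row(s) with conflicting "
            "weights; the last weight wins",
            stacklevel=2,
        )
    return g


def write_edgelist(g: HierGraph, path: PathLike) -> None:
    rows = [
        {"source": e.u, "target": e.v, "weight": e.weight, "layer": e.layer}
        for e in g.edges()
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight", "layer"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------- linkage tables


def write_linkage(d: Dendrogram, path: PathLike) -> None:
    """Merge-table TSV: step, left, right, height (+ leaf label listing)."""
    lines = ["step\tleft\tright\theight"]
    for step, (a, b, h) in enumerate(d.merges, start=1):
        lines.append(f"{step}\t{a}\t{b}\t{h!r}")
    lines.append("# leaves\t" + "\t".join(d.leaf_labels))
    Path(path).write_text("\n".join(lines) + "\n")


def read_linkage(path: PathLike) -> Dendrogram:
    text = Path(path).read_text().strip().splitlines()
    labels: Optional[list[str]] = None
    merges: list[tuple[int, int, float]] = []
    for line in text[1:]:
        if line.startswith("# leaves"):
            labels = line.split("\t")[1:]
            continue
        _, left, right, height = line.split("\t")
        merges.append((int(left), int(right), float(height)))
    if labels is None:
        labels = [str(i) for i in range(len(merges) + 1)]
    return Dendrogram(leaf_labels=labels, merges=merges)


# ------------------------------------------------------------ layout table


def write_layout(state, path: PathLike) -> None:
    """TSV of id, x, y, radius (radius only for containers)."""
    lines = ["id\tx\ty\tradius"]
    for nid in sorted(state.positions):
        x, y = (float(c) for c in state.positions[nid])
        r = state.radii.get(nid)
        r_txt = repr(float(r)) if r is not None else ""
        lines.append(f"{nid}\t{x!r}\t{y!r}\t{r_txt}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_layout(path: PathLike):
    from .layout import LayoutState  # local import avoids a cycle

    import numpy as np

    positions = {}
    radii = {}
    for line in Path(path).read_text().splitlines()[1:]:
        if not line.strip():
            continue
        nid, x, y, r = line.split("\t")
        positions[nid] = np.array([float(x), float(y)])
        if r:
            radii[nid] = float(r)
    return LayoutState(positions=positions, radii=radii, temperature=0.0,
                       converged=True)
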