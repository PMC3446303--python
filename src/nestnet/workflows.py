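"""End-to-end analysis pipelines over hierarchical networks.

Two workflows are provided:

* :func:`coexpression_pipeline` — build a co-expression graph by
  thresholding absolute Pearson correlation between gene expression rows,
  superimpose a complete-linkage Euclidean dendrogram of the same rows as
  nested module containers, aggregate inter-module edge densities, and
  style nodes by log2 fold-change (diverging color) and by kb distance to
  the nearest binding site (inverse size).
* :func:`timecourse_pipeline` — map per-timepoint differentially expressed
  gene sets onto an interactome, keep the largest connected subnetwork of
  each, and chain the resulting containers: the subnetwork of an earlier
  timepoint is nested inside the next one when fully contained in it,
  otherwise placed alongside with an association edge weighted by their
  overlap.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .aggregate import ModuleEdge, aggregate_all, style_diverging, style_size
from .core import GraphError, HierGraph
from .dendro import NestHCParams, build_dendrogram, nest_dendrogram

__all__ = [
    "coexpression_pipeline",
    "timecourse_pipeline",
    "consecutive_overlap",
    "module_recovery",
]


def coexpression_pipeline(
    expr: pd.DataFrame,
    attrs: pd.DataFrame,
    corr_threshold: float = 0.7,
    params: NestHCParams = NestHCParams(metric="rootdist", cutlevel=3, nlev=1),
) -> tuple[HierGraph, list[ModuleEdge]]:
    """Nested co-expression module network from an expression matrix.

    Steps: (1) co-expression graph with an edge wherever |Pearson r| meets
    the threshold (weight = |r|); (2) complete-linkage Euclidean dendrogram
    of the expression rows; (3) dendrogram superimposed as containers; (4)
    inter-module densities aggregated over the outermost containers and
    written back as association edges; (5) node color from ``logfc``
    (symmetric diverging palette) and node size from ``kb_dist`` (inverse:
    small distances draw large).  Genes with zero expression variance are
    excluded with a warning (their correlation is undefined).
    """
    if not expr.index.equals(attrs.index):
        raise ValueError("expression matrix and attribute table rows differ")
    variances = expr.var(axis=1, ddof=0)
    degenerate = list(expr.index[variances == 0.0])
    if degenerate:
        warnings.warn(
            f"excluding {len(degenerate)} zero-variance gene(s): "
            f"{degenerate[:5]}",
            stacklevel=2,
        )
        expr = expr.drop(index=degenerate)
        attrs = attrs.drop(index=degenerate)
    if expr.shape[0] < 2:
        raise ValueError("need at least 2 non-degenerate genes")

    genes = list(expr.index.astype(str))
    g = HierGraph()
    for gene in genes:
        node_attrs = {
            k: (v.item() if isinstance(v, np.generic) else v)
            for k, v in attrs.loc[gene].items()
        }
        g.add_node(gene, label=gene, **node_attrs)

    corr = np.corrcoef(expr.to_numpy())
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            r = corr[i, j]
            if abs(r) >= corr_threshold:
                g.add_edge(genes[i], genes[j], abs(float(r)))

    dendro = build_dendrogram(expr.to_numpy(), labels=genes)
    created = nest_dendrogram(g, dendro, params)
    top = [c for c in created if g.node(c).parent is None]
    module_edges = aggregate_all(g, top) if len(top) >= 2 else []
    for me in module_edges:
        g.add_edge(me.a, me.b, me.weight)

    if "logfc" in attrs.columns:
        colors = style_diverging(attrs["logfc"].tolist())
        for gene, color in zip(genes, colors):
            g.node(gene).attrs["color"] = color
    if "kb_dist" in attrs.columns:
        sizes = style_size(attrs["kb_dist"].tolist())
        for gene, size in zip(genes, sizes):
            g.node(gene).attrs["size"] = size
    return g, module_edges


def consecutive_overlap(sets: Sequence[set]) -> list[int]:
    """|sets[i] & sets[i+1]| for each consecutive pair."""
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    return [len(set(a) & set(b)) for a, b in zip(sets, sets[1:])]


def timecourse_pipeline(
    interactome: HierGraph,
    de_sets: Mapping[str, Mapping[str, float]],
) -> tuple[HierGraph, pd.DataFrame]:
    """Chain the largest per-timepoint DE subnetworks as nested containers.

    For each timepoint t (in the mapping's order) the largest connected
    component L(t) of the interactome induced on the DE set is placed in a
    container; the container of t is nested inside the container of t+1
    when L(t) is a subset of L(t+1), otherwise the two sit side by side
    joined by an association edge weighted by overlap / min(|L(t)|,
    |L(t+1)|).  Nodes are colored by the log2 fold-change of the earliest
    timepoint whose subnetwork they belong to.  The overlap table lists
    |L(t) & L(t+1)| for consecutive timepoints.
    """
    g = interactome.copy()
    leaf_set = set(g.leaf_ids())
    labels: list[str] = []
    components: list[set[str]] = []
    for label, gene_map in de_sets.items():
        members = set(gene_map) & leaf_set
        if not members:
            warnings.warn(f"timepoint {label!r}: empty DE set skipped", stacklevel=2)
            continue
        comp = g.largest_connected_component(members)
        if not comp:
            warnings.warn(
                f"timepoint {label!r}: no connected subnetwork", stacklevel=2
            )
            continue
        labels.append(label)
        components.append(comp)
    if not labels:
        raise GraphError("no timepoint produced a subnetwork")

    # color each gene by the logFC of its earliest timepoint
    claimed: set[str] = set()
    for label, comp in zip(labels, components):
        fresh = sorted(comp - claimed)
        if fresh:
            colors = style_diverging([de_sets[label][gx] for gx in fresh])
            for gx, color in zip(fresh, colors):
                g.node(gx).attrs["color"] = color
                g.node(gx).attrs["timepoint"] = label
        claimed |= comp

    # build containers innermost (earliest timepoint) first
    containers: list[str | None] = []
    assigned: set[str] = set()
    for i, (label, comp) in enumerate(zip(labels, components)):
        members: list[str] = sorted(comp - assigned)
        if i > 0 and containers[i - 1] is not None and components[i - 1] <= comp:
            members.append(containers[i - 1])
        if not members:
            # every gene of this subnetwork already sits in an earlier,
            # non-nested container: nothing left to enclose
            warnings.warn(
                f"timepoint {label!r}: subnetwork fully claimed by earlier "
                "timepoints; no container created",
                stacklevel=2,
            )
            containers.append(None)
            continue
        cid = g.nest(members, container_id=f"T_{label}")
        g.node(cid).attrs["label"] = label
        containers.append(cid)
        assigned |= comp

    # side-by-side association edges where the chain breaks
    overlaps = consecutive_overlap(components) if len(components) >= 2 else []
    for i, count in enumerate(overlaps):
        ca, cb = containers[i], containers[i + 1]
        if ca is None or cb is None:
            continue
        if not components[i] <= components[i + 1]:
            denom = min(len(components[i]), len(components[i + 1]))
            g.add_edge(ca, cb, count / denom)

    table = pd.DataFrame(
        {
            "from": labels[:-1],
            "to": labels[1:],
            "overlap": overlaps,
            "size_from": [len(c) for c in components[:-1]],
            "size_to": [len(c) for c in components[1:]],
        }
    )
    return g, table


def module_recovery(g: HierGraph, attrs: pd.DataFrame, column: str = "module") -> float:
    """Fraction of genes whose container matches their planted module.

    Each container is labelled by the majority planted module among its
    leaf descendants; a gene counts as recovered when its container's
    majority label is its own.  Genes outside any container count as not
    recovered.  Used to score how well the clustering pipeline rediscovers
    the planted partition of the synthetic generator.
    """
    truth = attrs[column].astype(str).to_dict()
    genes = [gx for gx in g.leaf_ids() if gx in truth]
    if not genes:
        raise ValueError("no annotated genes in graph")
    top: dict[str, str] = {}
    for gx in genes:
        chain = g.ancestors(gx)
        if chain:
            top[gx] = chain[-1]  # outermost container
    by_container: dict[str, list[str]] = {}
    for gx, cid in top.items():
        by_container.setdefault(cid, []).append(gx)
    majority: dict[str, str] = {}
    for cid, members in by_container.items():
        counts: dict[str, int] = {}
        for gx in members:
            counts[truth[gx]] = counts.get(truth[gx], 0) + 1
        majority[cid] = max(sorted(counts), key=lambda k: counts[k])
    hits = sum(
        1 for gx in genes if gx in top and truth[gx] == majority[top[gx]]
    )
    return hits / len(genes)
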