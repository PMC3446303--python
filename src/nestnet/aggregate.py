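"""Inter-module connectivity summaries and attribute-to-style mappings.

The association between two containers is summarised by the number of
leaf-layer edges crossing between their leaf descendants, normalised by the
number of possible cross pairs — a bipartite edge density in [0, 1] that
drives the width of the "out-edges" drawn between module containers.

Styling helpers map numeric node annotations to visual attributes: a
symmetric diverging palette for log2 fold-changes and an inverse linear
size map for kilobase distances (genes close to a binding site are drawn
large).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

from .core import CONTAINER, LEAF, GraphError, HierGraph

__all__ = [
    "ModuleEdge",
    "StyleScale",
    "module_edge_weight",
    "aggregate_all",
    "style_diverging",
    "style_size",
    "DIVERGING_PALETTE",
]

#: symmetric blue-white-red diverging endpoints (negative, neutral, positive)
DIVERGING_PALETTE = ("#2166AC", "#FFFFFF", "#B2182B")


@dataclass(frozen=True)
class ModuleEdge:
    """Aggregated association between two containers.

    ``count`` is the raw number of leaf-layer cross edges; ``weight`` is
    count divided by the number of possible cross pairs (|leaves(a)| x
    |leaves(b)|), so it is 1 exactly when the cross-bipartite graph is
    complete.
    """

    a: str
    b: str
    count: int
    weight: float

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError("module edge endpoints must differ")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError(f"weight {self.weight} outside [0, 1]")


@dataclass
class StyleScale:
    """A linear map from a numeric domain to sizes or color endpoints."""

    domain: tuple[float, float]
    range: tuple = (5.0, 20.0)
    midpoint: Optional[float] = None
    inverse: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.domain
        if not lo < hi:
            raise ValueError(f"degenerate style domain: {self.domain}")


def _check_module_pair(g: HierGraph, a: str, b: str) -> tuple[set[str], set[str]]:
    for cid in (a, b):
        if g.node(cid).kind != CONTAINER:
            raise GraphError(f"{cid!r} is not a container")
    if a == b:
        raise GraphError("module edge endpoints must differ")
    if a in g.ancestors(b) or b in g.ancestors(a):
        raise GraphError(f"{a!r} and {b!r} are nested within each other")
    la, lb = g.leaf_descendants(a), g.leaf_descendants(b)
    if not la or not lb:
        empty = a if not la else b
        raise GraphError(f"container {empty!r} has no leaf descendants")
    return la, lb


def module_edge_weight(
    g: HierGraph, a: str, b: str, weighted: bool = False
) -> ModuleEdge:
    """Cross-edge count and bipartite density between two containers.

    Edges are counted, not summed by weight, by default; ``weighted=True``
    sums leaf-edge weights instead (the density then need not stay <= 1 and
    is clipped never — it is only meaningful for weights in [0, 1]).
    """
    la, lb = _check_module_pair(g, a, b)
    count = 0
    total = 0.0
    for e in g.edges(layer=LEAF):
        if (e.u in la and e.v in lb) or (e.u in lb and e.v in la):
            count += 1
            total += e.weight
    possible = len(la) * len(lb)
    numer = total if weighted else count
    x, y = (a, b) if a < b else (b, a)
    return ModuleEdge(a=x, b=y, count=count, weight=numer / possible)


def aggregate_all(
    g: HierGraph, containers: Sequence[str], weighted: bool = False
) -> list[ModuleEdge]:
    """One ModuleEdge per unordered container pair with >= 1 cross edge."""
    containers = sorted(set(containers))
    out: list[ModuleEdge] = []
    for a, b in combinations(containers, 2):
        me = module_edge_weight(g, a, b, weighted=weighted)
        if me.count > 0:
            out.append(me)
    return out


def _hex_to_rgb(color: str) -> tuple[int, int, int]:
    c = color.lstrip("#")
    return tuple(int(c[i : i + 2], 16) for i in (0, 2, 4))  # type: ignore[return-value]


def _rgb_to_hex(rgb: Sequence[float]) -> str:
    return "#{:02X}{:02X}{:02X}".format(*(int(round(v)) for v in rgb))


def _lerp_color(c0: str, c1: str, t: float) -> str:
    r0, r1 = _hex_to_rgb(c0), _hex_to_rgb(c1)
    return _rgb_to_hex([a + (b - a) * t for a, b in zip(r0, r1)])


def style_diverging(
    values: Sequence[float],
    scale: Optional[StyleScale] = None,
    palette: tuple[str, str, str] = DIVERGING_PALETTE,
) -> list[str]:
    """Map signed values (log2 fold-changes) to a diverging hex palette.

    By default the domain is symmetric about 0 at +/- max|value|, so the
    midpoint maps to the neutral center color, the extremes to the endpoint
    colors, and color(-x) mirrors color(+x).
    """
    vals = [float(v) for v in values]
    if not vals:
        return []
    if scale is None:
        amax = max(abs(v) for v in vals) or 1.0
        scale = StyleScale(domain=(-amax, amax), midpoint=0.0)
    lo, hi = scale.domain
    mid = scale.midpoint if scale.midpoint is not None else (lo + hi) / 2.0
    neg, neutral, pos = palette
    out: list[str] = []
    for v in vals:
        v = min(max(v, lo), hi)
        if v < mid:
            t = (mid - v) / (mid - lo) if mid > lo else 0.0
            out.append(_lerp_color(neutral, neg, t))
        else:
            t = (v - mid) / (hi - mid) if hi > mid else 0.0
            out.append(_lerp_color(neutral, pos, t))
    return out


def style_size(
    values: Sequence[float],
    scale: Optional[StyleScale] = None,
) -> list[float]:
    """Map nonnegative distances (kb) to node sizes, inversely by default.

    The minimum distance maps to the maximum size and vice versa (nodes
    close to a binding site are drawn large); constant input maps to the
    midrange size.
    """
    vals = [float(v) for v in values]
    if not vals:
        return []
    if any(v < 0 for v in vals):
        raise ValueError("distances must be nonnegative")
    if scale is None:
        lo, hi = min(vals), max(vals)
        if lo == hi:
            hi = lo + 1.0  # degenerate: everything lands midrange below
        scale = StyleScale(domain=(lo, hi), inverse=True)
    lo, hi = scale.domain
    smin, smax = float(scale.range[0]), float(scale.range[1])
    if len(set(vals)) == 1:
        return [(smin + smax) / 2.0] * len(vals)
    out = []
    for v in vals:
        t = (min(max(v, lo), hi) - lo) / (hi - lo)
        if scale.inverse:
            t = 1.0 - t
        out.append(smin + t * (smax - smin))
    return out
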