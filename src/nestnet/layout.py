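"""Nested force-directed layout.

A spring-embedder in the Fruchterman-Reingold family, adapted to compound
graphs.  Edges act as springs with a target length; nodes sharing a parent
repel each other like charged particles; and a member that drifts outside
its parent container's padded circle is pulled back by a linear restoring
force — the "opposing force applied by the nest".  Forces never cross
hierarchy levels directly: an edge whose endpoints live in different
containers exerts its spring force on the two enclosing containers (the
representatives that are siblings at the deepest common level), so the
interior of every container reaches a local equilibrium independently of
the rest of the network.

Updates are synchronous, the per-node displacement is capped by a
temperature that decays geometrically each iteration (simulated-annealing
style), and all randomness comes from the seed in :class:`ForceParams`, so
a given (graph, params) pair always yields a bit-identical layout.

With attraction ``d^2/k`` and repulsion ``repulsion * k^2/d`` (k =
``rest_length``), an isolated connected pair settles at the closed-form
equilibrium ``d* = k * repulsion**(1/3)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import sqrt
from typing import Optional

import numpy as np

from .core import CONTAINER, HierGraph

__all__ = ["ForceParams", "LayoutState", "init_layout", "relax_step", "relax",
           "containment_check", "equilibrium_distance", "circle_layout",
           "grid_layout"]

#: fraction of the container radius inside which members move freely
_INNER_FRACTION = 0.75
#: minimum radius of any container, in units of rest_length
_MIN_RADIUS_FACTOR = 0.5


@dataclass
class ForceParams:
    """Constants of the force model.

    rest_length
        target edge length in layout units; also the repulsion length scale.
    repulsion
        charge constant scaling the ``k^2/d`` pairwise repulsion.
    container_padding
        multiplicative margin on the container radius, which is
        ``padding * sqrt(leaf count) * rest_length / 2`` (area grows with
        membership).
    containment_stiffness
        linear restoring-force constant applied per unit of overshoot
        beyond the padded circle.
    cooling
        per-iteration geometric temperature decay, in (0, 1).
    tol
        convergence threshold on the maximum per-node displacement.
    """

    rest_length: float = 1.0
    repulsion: float = 1.0
    container_padding: float = 1.8
    containment_stiffness: float = 4.0
    cooling: float = 0.97
    max_iter: int = 500
    tol: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rest_length", "repulsion", "container_padding",
                     "containment_stiffness", "cooling", "max_iter", "tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cooling >= 1:
            raise ValueError("cooling must be < 1")


@dataclass
class LayoutState:
    """Positions, container radii and annealing state of one layout run."""

    positions: dict[str, np.ndarray]
    radii: dict[str, float]
    temperature: float
    iteration: int = 0
    converged: bool = False

    def copy(self) -> "LayoutState":
        return LayoutState(
            positions={k: v.copy() for k, v in self.positions.items()},
            radii=dict(self.radii),
            temperature=self.temperature,
            iteration=self.iteration,
            converged=self.converged,
        )


def equilibrium_distance(params: ForceParams) -> float:
    """Closed-form rest distance of an isolated connected pair."""
    return params.rest_length * params.repulsion ** (1.0 / 3.0)


def _container_radius(g: HierGraph, cid: str, params: ForceParams) -> float:
    n = max(len(g.leaf_descendants(cid)), 1)
    r = params.container_padding * sqrt(n) * params.rest_length / 2.0
    return max(r, _MIN_RADIUS_FACTOR * params.rest_length)


def _recompute_containers(
    g: HierGraph, pos: dict[str, np.ndarray], params: ForceParams
) -> dict[str, float]:
    """Bottom-up: container centers = member centroids; radii from leaf count."""
    radii: dict[str, float] = {}
    containers = sorted(g.container_ids(), key=lambda c: -g.depth(c))
    for cid in containers:
        members = g.children(cid)
        if members:
            pos[cid] = np.mean([pos[m] for m in members], axis=0)
        radii[cid] = _container_radius(g, cid, params)
    return radii


def init_layout(g: HierGraph, params: ForceParams) -> LayoutState:
    """Seeded random placement in a square of side ~ sqrt(node count)."""
    rng = np.random.default_rng(params.seed)
    ids = g.node_ids()
    side = max(sqrt(max(len(ids), 1)), 1.0) * params.rest_length * 2.0
    pos: dict[str, np.ndarray] = {}
    for nid in ids:  # sorted: draw order is reproducible
        pos[nid] = rng.uniform(0.0, side, size=2)
    radii = _recompute_containers(g, pos, params)
    return LayoutState(
        positions=pos, radii=radii, temperature=side / 8.0, iteration=0
    )


def _sibling_groups(g: HierGraph) -> dict[Optional[str], list[str]]:
    groups: dict[Optional[str], list[str]] = {}
    for nid in g.node_ids():
        groups.setdefault(g.node(nid).parent, []).append(nid)
    return groups


def _representatives(g: HierGraph, u: str, v: str) -> tuple[str, str]:
    """Siblings at the deepest level enclosing both endpoints.

    Forces on an edge act on these representatives: the endpoints
    themselves when they share a parent, otherwise the containers (or
    outside node) that are children of the deepest common ancestor.
    """
    chain_u = [u] + g.ancestors(u)
    chain_v = [v] + g.ancestors(v)
    anc_v = set(chain_v)
    dca = next((a for a in chain_u[1:] if a in anc_v), None)
    if dca is None:
        return chain_u[-1], chain_v[-1]
    ru = chain_u[chain_u.index(dca) - 1]
    rv = chain_v[chain_v.index(dca) - 1]
    return ru, rv


def _unit(vec: np.ndarray, fallback_angle: float) -> tuple[np.ndarray, float]:
    d = float(np.hypot(vec[0], vec[1]))
    if d < 1e-12:
        # coincident points: deterministic symmetric split direction
        return np.array([np.cos(fallback_angle), np.sin(fallback_angle)]), 1e-12
    return vec / d, d


def relax_step(
    g: HierGraph, s: LayoutState, params: ForceParams
) -> tuple[LayoutState, float]:
    """One synchronous force iteration; returns (new state, max displacement)."""
    pos = s.positions
    k = params.rest_length
    disp: dict[str, np.ndarray] = {nid: np.zeros(2) for nid in pos}

    groups = _sibling_groups(g)
    # (ii) pairwise repulsion among siblings (containers as super-nodes)
    for parent, members in groups.items():
        for idx, (a, b) in enumerate(combinations(members, 2)):
            unit, d = _unit(pos[a] - pos[b], fallback_angle=0.7 * (idx + 1))
            f = params.repulsion * k * k / d
            disp[a] += f * unit
            disp[b] -= f * unit

    # (i)+(iv) spring attraction, acting on the sibling representatives
    for e in g.edges():
        ru, rv = _representatives(g, e.u, e.v)
        if ru == rv:
            continue
        unit, d = _unit(pos[rv] - pos[ru], fallback_angle=1.3)
        f = d * d / k
        disp[ru] += f * unit
        disp[rv] -= f * unit

    # (iii) containment: linear restoring force beyond the padded circle
    for nid in pos:
        parent = g.node(nid).parent
        if parent is None:
            continue
        vec = pos[nid] - pos[parent]
        unit, d = _unit(vec, fallback_angle=2.1)
        allowed = _INNER_FRACTION * s.radii[parent]
        if d > allowed:
            disp[nid] -= params.containment_stiffness * (d - allowed) * unit

    # accumulate displacements down the hierarchy (a container's motion is a
    # rigid translation of its descendants), cap the total per node by the
    # temperature, and move the leaves; containers are then re-derived
    order = sorted(pos, key=lambda n: g.depth(n))
    effective: dict[str, np.ndarray] = {}
    for nid in order:
        parent = g.node(nid).parent
        inherited = effective[parent] if parent is not None else np.zeros(2)
        effective[nid] = inherited + disp[nid]

    new_pos = {k_: v.copy() for k_, v in pos.items()}
    max_disp = 0.0
    for nid in pos:
        if g.node(nid).kind == CONTAINER:
            continue
        step = effective[nid]
        mag = float(np.hypot(step[0], step[1]))
        if mag > s.temperature:
            step = step * (s.temperature / mag)
            mag = s.temperature
        new_pos[nid] = pos[nid] + step
        max_disp = max(max_disp, mag)

    radii = _recompute_containers(g, new_pos, params)
    new_state = LayoutState(
        positions=new_pos,
        radii=radii,
        temperature=s.temperature * params.cooling,
        iteration=s.iteration + 1,
        converged=s.converged,
    )
    return new_state, max_disp


def relax(
    g: HierGraph,
    params: Optional[ForceParams] = None,
    state: Optional[LayoutState] = None,
) -> LayoutState:
    """Iterate :func:`relax_step` to (local) equilibrium.

    Stops when the maximum displacement falls below ``tol`` or after
    ``max_iter`` iterations; non-convergence is recorded on the state, not
    raised.
    """
    params = params or ForceParams()
    s = state.copy() if state is not None else init_layout(g, params)
    if len(s.positions) <= 1:
        s.converged = True
        return s
    while s.iteration < params.max_iter:
        s, max_disp = relax_step(g, s, params)
        if max_disp < params.tol:
            s.converged = True
            break
    return s


def containment_check(g: HierGraph, s: LayoutState) -> list[tuple[str, float, float]]:
    """Every (node, distance, radius) whose center lies outside its parent."""
    violations = []
    for nid in sorted(s.positions):
        parent = g.node(nid).parent
        if parent is None:
            continue
        d = float(np.linalg.norm(s.positions[nid] - s.positions[parent]))
        r = s.radii[parent]
        if d > r:
            violations.append((nid, d, r))
    return violations


# --- trivial static layouts (convenience helpers, not part of the force model)


def circle_layout(g: HierGraph, radius: float = 10.0) -> LayoutState:
    ids = g.node_ids()
    n = max(len(ids), 1)
    pos = {
        nid: radius * np.array([np.cos(2 * np.pi * i / n), np.sin(2 * np.pi * i / n)])
        for i, nid in enumerate(ids)
    }
    radii = _recompute_containers(g, pos, ForceParams())
    return LayoutState(positions=pos, radii=radii, temperature=0.0, converged=True)


def grid_layout(g: HierGraph, spacing: float = 2.0) -> LayoutState:
    ids = g.node_ids()
    cols = int(np.ceil(sqrt(max(len(ids), 1))))
    pos = {
        nid: spacing * np.array([i % cols, i // cols], dtype=float)
        for i, nid in enumerate(ids)
    }
    radii = _recompute_containers(g, pos, ForceParams())
    return LayoutState(positions=pos, radii=radii, temperature=0.0, converged=True)
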