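"""Seeded synthetic-data generators.

Three families of inputs are produced, emulating the statistical shape of
the datasets the downstream workflows expect, without any external data:

* a modular toy graph — near-even planted modules with dense intra-module
  and sparse inter-module wiring (a planted-partition graph);
* a scale-free interactome grown by a step model — a single vertex first,
  then one vertex per step attached to an existing vertex with probability
  proportional to degree, so a graph with n vertices has exactly n - 1
  edges and is connected;
* case-study-shaped datasets: a gene-expression matrix with module-shared
  latent profiles plus noise (with per-gene log2 fold-changes and
  heavy-tailed kilobase distances to the nearest binding site), and a
  time-course experiment with growing, partially persistent sets of
  differentially expressed genes over a scale-free interactome.

All generators are pure functions of their spec: the same spec (seed
included) always yields the same output.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .core import HierGraph

__all__ = [
    "ModularGraphSpec",
    "ScaleFreeSpec",
    "TimecourseSpec",
    "gen_modular_graph",
    "gen_scalefree",
    "gen_expression",
    "gen_timecourse",
]


@dataclass(frozen=True)
class ModularGraphSpec:
    """Parameters of the modular toy graph.

    Defaults give m = 5 modules over at most 30 nodes, with intra/inter
    edge probabilities chosen so the modules are statistically separable.
    """

    m: int = 5
    nmax: int = 30
    p_in: float = 0.3
    p_out: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.nmax < self.m:
            raise ValueError("nmax must be >= m")
        if not 0 <= self.p_out <= self.p_in <= 1:
            raise ValueError("need 0 <= p_out <= p_in <= 1")


@dataclass(frozen=True)
class ScaleFreeSpec:
    """Vertex count and seed of the step-model scale-free graph."""

    n: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass(frozen=True)
class TimecourseSpec:
    """Synthetic time-course differential-expression experiment.

    Per-timepoint DE-set sizes are non-decreasing (the subnetwork grows
    over time); ``nested_fraction`` is the probability that a gene
    differentially expressed at one timepoint persists into the next set,
    so 1.0 yields a strictly nested chain of sets.
    """

    interactome_size: int = 200
    timepoints: tuple[str, ...] = ("3h", "6h", "12h")
    set_sizes: tuple[int, ...] = (10, 20, 40)
    nested_fraction: float = 0.8
    locality: float = 1.0
    logfc_scale: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.timepoints) != len(self.set_sizes):
            raise ValueError("one set size per timepoint required")
        if len(self.timepoints) < 1:
            raise ValueError("at least one timepoint required")
        if any(s > self.interactome_size for s in self.set_sizes):
            raise ValueError("set sizes cannot exceed the interactome size")
        if any(b < a for a, b in zip(self.set_sizes, self.set_sizes[1:])):
            raise ValueError("set sizes must be non-decreasing")
        if not 0.0 <= self.nested_fraction <= 1.0:
            raise ValueError("nested_fraction must lie in [0, 1]")
        if not 0.0 <= self.locality <= 1.0:
            raise ValueError("locality must lie in [0, 1]")


def _module_assignment(spec: ModularGraphSpec) -> tuple[list[str], dict[str, str]]:
    """Near-even split of nmax gene ids into m planted modules."""
    n = spec.nmax
    width = len(str(n))
    genes = [f"g{i + 1:0{width}d}" for i in range(n)]
    labels = {}
    base, extra = divmod(n, spec.m)
    idx = 0
    for mod in range(spec.m):
        size = base + (1 if mod < extra else 0)
        for _ in range(size):
            labels[genes[idx]] = f"M{mod + 1}"
            idx += 1
    return genes, labels


def gen_modular_graph(spec: ModularGraphSpec = ModularGraphSpec()) -> HierGraph:
    """Planted-partition toy graph with the module stored as a node attribute.

    The planted module is an attribute (``"module"``), not a container:
    superimposing the module structure onto the topology is the job of the
    clustering/nesting pipeline, and the attribute is the ground truth it
    is checked against.
    """
    rng = np.random.default_rng(spec.seed)
    genes, labels = _module_assignment(spec)
    g = HierGraph()
    for gene in genes:
        g.add_node(gene, module=labels[gene], label=gene)
    for i, u in enumerate(genes):
        for v in genes[i + 1 :]:
            p = spec.p_in if labels[u] == labels[v] else spec.p_out
            if rng.random() < p:
                g.add_edge(u, v, 1.0)
    return g


def gen_scalefree(spec: ScaleFreeSpec = ScaleFreeSpec()) -> HierGraph:
    """Step-model scale-free graph: n vertices, exactly n - 1 edges.

    The first step creates a single vertex and no edge; each subsequent
    step creates one vertex linked to an existing vertex drawn with
    probability proportional to degree + 1 (the +1 makes the second vertex
    attachable when all degrees are still zero).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    width = len(str(n))
    ids = [f"v{i + 1:0{width}d}" for i in range(n)]
    g = HierGraph()
    g.add_node(ids[0], label=ids[0])
    degree = np.zeros(n, dtype=float)
    for i in range(1, n):
        weights = degree[:i] + 1.0
        target = rng.choice(i, p=weights / weights.sum())
        g.add_node(ids[i], label=ids[i])
        g.add_edge(ids[i], ids[target], 1.0)
        degree[i] += 1
        degree[target] += 1
    return g


def gen_expression(
    modules: ModularGraphSpec = ModularGraphSpec(),
    n_samples: int = 20,
    effect: float = 3.0,
    noise: float = 1.0,
    logfc_scale: float = 2.0,
    kb_scale: float = 50.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Module-structured expression matrix plus a gene annotation table.

    Genes (rows) inherit a latent per-module sample profile scaled by
    ``effect``, plus i.i.d. Gaussian noise — genes in the same module are
    therefore correlated across samples when effect >> noise, which is what
    the co-expression workflow thresholds on.  The annotation table carries
    the planted module, a simulated log2 fold-change per gene (module mean
    plus gene-level scatter) and a simulated distance to the nearest
    binding site, exponential with mean ``kb_scale`` kb: most sites are
    distal, a minority proximal, as in real binding-site maps.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if noise < 0 or effect < 0:
        raise ValueError("effect and noise must be nonnegative")
    rng = np.random.default_rng(seed)
    genes, labels = _module_assignment(modules)
    module_names = sorted(set(labels.values()))
    latent = {m: rng.normal(size=n_samples) for m in module_names}
    module_logfc = {m: rng.normal(0.0, logfc_scale) for m in module_names}
    rows = np.empty((len(genes), n_samples))
    logfc = np.empty(len(genes))
    for i, gene in enumerate(genes):
        mod = labels[gene]
        rows[i] = effect * latent[mod] + rng.normal(0.0, noise, size=n_samples)
        logfc[i] = module_logfc[mod] + rng.normal(0.0, 0.25 * logfc_scale)
    kb = rng.exponential(scale=kb_scale, size=len(genes))
    expr = pd.DataFrame(
        rows, index=genes, columns=[f"s{j + 1:02d}" for j in range(n_samples)]
    )
    attrs = pd.DataFrame(
        {
            "module": [labels[gx] for gx in genes],
            "logfc": logfc,
            "kb_dist": kb,
        },
        index=genes,
    )
    return expr, attrs


def gen_timecourse(
    spec: TimecourseSpec = TimecourseSpec(),
) -> tuple[HierGraph, dict[str, dict[str, float]]]:
    """Scale-free interactome plus per-timepoint DE gene sets with logFC.

    The set at timepoint t+1 keeps each gene of the set at t independently
    with probability ``nested_fraction`` and is topped up with fresh genes
    to its target size.  Each fresh gene is drawn, with probability
    ``locality``, uniformly from the frontier — non-member interaction
    partners of the current set — and otherwise uniformly from all
    non-members.  At locality 1 a differential-expression response recruits
    its interaction neighborhood, so each set is a connected, growing
    subnetwork (the shape the nested-chain workflow expects); at locality 0
    the top-up is a plain uniform sample.  Log2 fold-changes are drawn per
    gene per timepoint.
    """
    seq = np.random.SeedSequence(spec.seed)
    graph_seed = int(seq.spawn(1)[0].generate_state(1)[0] % (2**31))
    rng = np.random.default_rng(seq)
    interactome = gen_scalefree(
        ScaleFreeSpec(n=spec.interactome_size, seed=graph_seed)
    )
    adjacency = {
        gx: set(nbrs) for gx, nbrs in interactome.leaf_graph().adjacency()
    }
    genes = interactome.leaf_ids()
    de_sets: dict[str, dict[str, float]] = {}
    prev: list[str] = []
    for label, size in zip(spec.timepoints, spec.set_sizes):
        members = {gx for gx in prev if rng.random() < spec.nested_fraction}
        frontier = sorted(
            {nb for gx in members for nb in adjacency[gx]} - members
        )
        while len(members) < size:
            if frontier and rng.random() < spec.locality:
                pick = frontier[rng.integers(len(frontier))]
            else:
                pool = sorted(set(genes) - members)
                pick = pool[rng.integers(len(pool))]
            members.add(pick)
            frontier = sorted(
                (set(frontier) | adjacency[pick]) - members
            )
        de_sets[label] = {
            gx: float(rng.normal(0.0, spec.logfc_scale))
            for gx in sorted(members)
        }
        prev = sorted(members)
    return interactome, de_sets
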