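import numpy as np
import pytest

from nestnet import HierGraph


@pytest.fixture
def abc_graph():
    """Three parentless leaves a, b, c."""
    g = HierGraph()
    for x in "abc":
        g.add_node(x)
    return g


@pytest.fixture
def nested_toy():
    """Two 3-leaf containers A, B with one cross edge a1--b1."""
    g = HierGraph()
    for x in ("a1", "a2", "a3", "b1", "b2", "b3"):
        g.add_node(x, label=x)
    g.add_edge("a1", "a2")
    g.add_edge("a2", "a3")
    g.add_edge("b1", "b2")
    g.add_edge("a1", "b1")
    g.nest({"a1", "a2", "a3"}, "A")
    g.nest({"b1", "b2", "b3"}, "B")
    return g


def random_nested_graph(seed, max_leaves=12):
    """Random leaf graph with a random (possibly multi-level) nesting."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, max_leaves + 1))
    g = HierGraph()
    leaves = [f"n{i:02d}" for i in range(n)]
    for x in leaves:
        g.add_node(x, label=x, score=float(rng.normal()))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.3:
                g.add_edge(leaves[i], leaves[j], float(rng.uniform(0.1, 2.0)))
    pool = list(leaves)
    for c in range(int(rng.integers(0, 4))):
        if len(pool) < 2:
            break
        k = int(rng.integers(2, min(len(pool), 5) + 1))
        members = list(rng.choice(pool, size=k, replace=False))
        cid = g.nest(members, f"C{c}")
        pool = [x for x in pool if x not in members] + [cid]
    return g
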