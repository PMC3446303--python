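"""Nested force-directed layout: determinism, symmetry and containment."""

import numpy as np
import pytest

from nestnet import (
    ForceParams,
    HierGraph,
    containment_check,
    equilibrium_distance,
    init_layout,
    relax,
    relax_step,
)
from nestnet.layout import circle_layout, grid_layout

from conftest import random_nested_graph


def two_node_graph():
    g = HierGraph()
    g.add_node("a")
    g.add_node("b")
    g.add_edge("a", "b")
    return g


def nested_fixture(seed):
    """Three containers of 3-5 leaves with intra wiring and one cross edge."""
    rng = np.random.default_rng(seed)
    g = HierGraph()
    idx = 0
    firsts = []
    for c in range(3):
        members = []
        for _ in range(int(rng.integers(3, 6))):
            nid = f"n{idx:02d}"
            idx += 1
            g.add_node(nid)
            members.append(nid)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if rng.random() < 0.5:
                    g.add_edge(members[i], members[j])
        firsts.append(members[0])
        g.nest(members, f"C{c}")
    g.add_edge(firsts[0], firsts[1])
    return g


class TestInit:
    def test_same_seed_identical_positions(self):
        g = nested_fixture(0)
        p = ForceParams(seed=42)
        s1, s2 = init_layout(g, p), init_layout(g, p)
        assert all(np.array_equal(s1.positions[k], s2.positions[k]) for k in s1.positions)

    def test_single_node_no_radii(self):
        g = HierGraph()
        g.add_node("solo")
        s = init_layout(g, ForceParams())
        assert "solo" in s.positions and s.radii == {}

    def test_container_starts_at_member_centroid(self):
        g = HierGraph()
        for x in "abcd":
            g.add_node(x)
        g.nest(set("abcd"), "C")
        s = init_layout(g, ForceParams(seed=0))
        centroid = np.mean([s.positions[x] for x in "abcd"], axis=0)
        assert np.allclose(s.positions["C"], centroid)


class TestRelaxStep:
    def test_single_node_zero_displacement(self):
        g = HierGraph()
        g.add_node("solo")
        p = ForceParams()
        s = init_layout(g, p)
        s2, max_disp = relax_step(g, s, p)
        assert max_disp == 0.0
        assert np.array_equal(s2.positions["solo"], s.positions["solo"])

    def test_unconnected_pair_repels_symmetrically(self):
        g = HierGraph()
        g.add_node("a")
        g.add_node("b")
        p = ForceParams(seed=0)
        s = init_layout(g, p)
        s.positions["a"] = np.array([0.0, 0.0])
        s.positions["b"] = np.array([0.3, 0.0])  # closer than equilibrium
        s2, _ = relax_step(g, s, p)
        da = s2.positions["a"] - s.positions["a"]
        db = s2.positions["b"] - s.positions["b"]
        assert np.allclose(da, -db)  # opposite and equal
        assert da[0] < 0 < db[0]  # pushed apart along their axis
        assert da[1] == db[1] == 0.0

    def test_translation_equivariance(self):
        g = nested_fixture(1)
        p = ForceParams(seed=3)
        s = init_layout(g, p)
        shift = np.array([17.0, -4.0])
        s_shifted = s.copy()
        for k in s_shifted.positions:
            s_shifted.positions[k] = s_shifted.positions[k] + shift
        a, _ = relax_step(g, s, p)
        b, _ = relax_step(g, s_shifted, p)
        for k in a.positions:
            assert np.allclose(b.positions[k], a.positions[k] + shift, atol=1e-9)

    def test_displacement_capped_by_temperature(self):
        g = nested_fixture(2)
        p = ForceParams(seed=0)
        s = init_layout(g, p)
        for _ in range(10):
            temp_before = s.temperature
            s, max_disp = relax_step(g, s, p)
            assert max_disp <= temp_before + 1e-12

    def test_temperature_strictly_decreasing(self):
        g = nested_fixture(3)
        p = ForceParams(seed=0)
        s = init_layout(g, p)
        temps = [s.temperature]
        for _ in range(5):
            s, _ = relax_step(g, s, p)
            temps.append(s.temperature)
        assert all(b < a for a, b in zip(temps, temps[1:]))


class TestRelax:
    def test_single_node_keeps_initial_position(self):
        g = HierGraph()
        g.add_node("solo")
        p = ForceParams(seed=5)
        assert np.array_equal(
            relax(g, p).positions["solo"], init_layout(g, p).positions["solo"]
        )

    def test_two_node_equilibrium_within_5pct(self):
        g = two_node_graph()
        p = ForceParams(seed=1)
        s = relax(g, p)
        d = np.linalg.norm(s.positions["a"] - s.positions["b"])
        assert d == pytest.approx(equilibrium_distance(p), rel=0.05)

    def test_two_node_equilibrium_scales_with_repulsion(self):
        g = two_node_graph()
        p = ForceParams(seed=1, repulsion=8.0)
        s = relax(g, p)
        d = np.linalg.norm(s.positions["a"] - s.positions["b"])
        assert d == pytest.approx(equilibrium_distance(p), rel=0.05)
        assert equilibrium_distance(p) == pytest.approx(2.0)

    def test_determinism_bit_identical(self):
        g = nested_fixture(4)
        p = ForceParams(seed=9)
        s1, s2 = relax(g, p), relax(g, p)
        assert all(
            np.array_equal(s1.positions[k], s2.positions[k]) for k in s1.positions
        )

    def test_members_end_inside_their_container(self):
        g = nested_fixture(5)
        s = relax(g, ForceParams(seed=5))
        assert containment_check(g, s) == []

    def test_nest_local_equilibrium_is_external_invariant(self):
        """Members' relative configuration after a step does not depend on
        where unrelated parts of the network sit (level decoupling)."""
        g = nested_fixture(6)
        p = ForceParams(seed=2)
        s = relax(g, p)
        s.temperature = 1e9  # generous cap so no clipping interferes

        def relative_step(state):
            nxt, _ = relax_step(g, state, p)
            return {
                m: nxt.positions[m] - nxt.positions["C0"]
                for m in g.children("C0")
                if g.node(m).kind == "leaf"
            }

        base = relative_step(s)
        perturbed = s.copy()
        for nid in perturbed.positions:
            if "C0" not in ([nid] + g.ancestors(nid)):
                perturbed.positions[nid] = perturbed.positions[nid] + np.array(
                    [30.0, -12.0]
                )
        moved = relative_step(perturbed)
        for m in base:
            assert np.allclose(moved[m], base[m], atol=1e-9)


class TestContainmentCheck:
    def test_members_at_center_no_violation(self):
        g = HierGraph()
        for x in "ab":
            g.add_node(x)
        g.nest({"a", "b"}, "C")
        p = ForceParams()
        s = init_layout(g, p)
        for x in "ab":
            s.positions[x] = np.array([0.0, 0.0])
        s.positions["C"] = np.array([0.0, 0.0])
        assert containment_check(g, s) == []

    def test_displaced_member_reported(self):
        g = HierGraph()
        for x in "ab":
            g.add_node(x)
        g.nest({"a", "b"}, "C")
        s = init_layout(g, ForceParams())
        center = np.array([1.0, 1.0])
        s.positions["C"] = center
        s.positions["b"] = center.copy()
        s.positions["a"] = center + np.array([100.0, 0.0])
        bad = containment_check(g, s)
        assert [v[0] for v in bad] == ["a"]


class TestStaticLayouts:
    @pytest.mark.parametrize("fn", [circle_layout, grid_layout])
    def test_cover_all_nodes(self, fn):
        g = random_nested_graph(2)
        s = fn(g)
        assert set(s.positions) == set(g.node_ids())
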