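"""Graph reconstruction: neighbor scales, linking stages, pruning, segments."""

import networkx as nx
import numpy as np
import pytest

import vasctree as vt
from oracles import brute_knn_scales, replay_linking, replay_prune
from vasctree.errors import DataError
from vasctree.graph import NeighborScales, build_node_graph


def random_point_mix(rng, n):
    """Random centerline-like set: jittered chains plus background clutter."""
    pts = []
    n_chains = rng.integers(1, 4)
    for _ in range(n_chains):
        start = rng.uniform(0, 400, 3)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        k = int(rng.integers(10, max(11, n // n_chains)))
        steps = np.arange(k)[:, None] * 8.0 * direction
        pts.append(start + steps + rng.normal(0, 1.5, (k, 3)))
    clutter = rng.uniform(0, 400, (max(0, n - sum(len(p) for p in pts)), 3))
    pts = np.concatenate(pts + [clutter])[:n]
    return pts


def to_cs(points, rng=None):
    d = np.full(len(points), 20.0) if rng is None else rng.uniform(10, 50, len(points))
    return vt.CenterlineSet(points, d)


class TestNeighborScales:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for n in (11, 60, 300):
            pts = rng.uniform(0, 100, (n, 3))
            scales = vt.compute_neighbor_scales(to_cs(pts))
            nn2, nn5, nn10 = brute_knn_scales(pts)
            assert scales.nn2 == pytest.approx(nn2, rel=0, abs=1e-12)
            assert scales.nn5 == pytest.approx(nn5, rel=0, abs=1e-12)
            assert scales.nn10 == pytest.approx(nn10, rel=0, abs=1e-12)

    def test_1d_lattice(self):
        h = 3.0
        pts = np.zeros((20, 3))
        pts[:, 0] = np.arange(20) * h
        scales = vt.compute_neighbor_scales(to_cs(pts))
        # interior points: 2nd nearest at h; the two boundary points at 2h
        expected_nn2 = (18 * h + 2 * 2 * h) / 20
        assert scales.nn2 == pytest.approx(expected_nn2)
        assert scales.nn2 <= scales.nn5 <= scales.nn10

    def test_too_few_points(self):
        pts = np.arange(30).reshape(10, 3).astype(float)
        with pytest.raises(DataError, match="manually"):
            vt.compute_neighbor_scales(to_cs(pts))


class TestLinkStages:
    def test_three_collinear_points_form_chain(self):
        cs = to_cs(np.array([[0, 0, 0], [5, 0, 0], [10, 0, 0.0]]))
        g = vt.link_stage1(cs, NeighborScales(6.0, 12.0, 24.0))
        assert sorted(tuple(sorted(e)) for e in g.edges) == [(0, 1), (1, 2)]

    def test_far_points_not_linked(self):
        cs = to_cs(np.array([[0, 0, 0], [100, 0, 0.0], [250, 0, 0.0]]))
        g = vt.link_stage1(cs, NeighborScales(6.0, 12.0, 24.0))
        assert g.number_of_edges() == 0

    def test_dense_line_mostly_degree_two(self):
        # transverse jitter only, as on a skeletonized vessel: longitudinal
        # point order stays intact so stage 1 can chain nearly every node
        rng = np.random.default_rng(4)
        pts = np.zeros((200, 3))
        pts[:, 0] = np.arange(200) * 5.0
        pts[:, 1:] += rng.normal(0, 0.3, (200, 2))
        cs = to_cs(pts)
        scales = vt.compute_neighbor_scales(cs)
        g = vt.link_stage1(cs, scales)
        degrees = np.array([g.degree[n] for n in g.nodes])
        assert degrees.max() <= 2
        assert (degrees == 2).mean() >= 0.9

    def test_stage2_joins_fragments(self):
        # two chains with an end gap below nn5
        pts = np.array([[0, 0, 0], [5, 0, 0], [10, 0, 0],
                        [18, 0, 0], [23, 0, 0], [28, 0, 0.0]])
        cs = to_cs(pts)
        scales = NeighborScales(6.0, 10.0, 30.0)
        g = vt.link_stage2(vt.link_stage1(cs, scales), scales)
        assert nx.is_connected(g)
        assert nx.is_tree(g)

    def test_stage2_never_closes_a_folded_chain(self):
        # horseshoe: the two ends are near each other but already connected
        theta = np.linspace(0, 1.8 * np.pi, 24)
        pts = np.stack([10 * np.cos(theta), 10 * np.sin(theta),
                        np.zeros_like(theta)], axis=1)
        cs = to_cs(pts)
        scales = vt.compute_neighbor_scales(cs)
        g = vt.link_stage1(cs, scales)
        g = vt.link_stage2(g, scales)
        assert nx.number_of_selfloops(g) == 0
        assert len(nx.cycle_basis(g)) == 0

    def test_stage2_attaches_isolated_node(self):
        pts = np.array([[0, 0, 0], [5, 0, 0], [10, 0, 0], [14, 3, 0.0]])
        cs = to_cs(pts)
        scales = NeighborScales(5.5, 9.0, 30.0)
        g = vt.link_stage2(vt.link_stage1(cs, scales), scales)
        assert g.degree[3] >= 1

    def test_stage3_bridges_at_half_nn10(self):
        pts = np.array([[0, 0, 0], [6, 0, 0], [12, 0, 0],
                        [27, 0, 0], [33, 0, 0], [39, 0, 0.0]])
        cs = to_cs(pts)
        scales = NeighborScales(7.0, 12.0, 30.0)  # gap 15 = 0.5 * nn10
        g = vt.link_stage3(vt.link_stage1(cs, scales), scales)
        assert nx.is_connected(g)

    def test_stage3_respects_nn10(self):
        pts = np.array([[0, 0, 0], [6, 0, 0], [12, 0, 0],
                        [80, 0, 0], [86, 0, 0], [92, 0, 0.0]])
        cs = to_cs(pts)
        scales = NeighborScales(7.0, 12.0, 30.0)  # gap 68 = ~2.3 * nn10
        g = vt.link_stage3(vt.link_stage1(cs, scales), scales)
        assert nx.number_connected_components(g) == 2

    def test_stage3_three_fragments_two_bridges(self):
        pts = np.array([[0, 0, 0], [6, 0, 0],
                        [20, 0, 0], [26, 0, 0],
                        [40, 0, 0], [46, 0, 0.0]])
        cs = to_cs(pts)
        scales = NeighborScales(7.0, 8.0, 20.0)
        g = vt.link_stage3(vt.link_stage1(cs, scales), scales)
        bridges = [e for e in g.edges(data=True) if e[2]["stage"] == 3]
        assert nx.is_connected(g)
        assert len(bridges) == 2


class TestPruning:
    def _y_graph(self, arm=10, spur=1):
        """Y of three arms plus an optional short spur at the junction."""
        pts = [[0.0, 0.0, 0.0]]
        for d in ([1, 0, 0], [-0.5, 1, 0], [-0.5, -1, 0]):
            d = np.asarray(d, dtype=float)
            d /= np.linalg.norm(d)
            for k in range(1, arm + 1):
                pts.append(list(5.0 * k * d))
        edges = []
        for a in range(3):
            base = 1 + a * arm
            edges.append((0, base))
            edges.extend((base + k, base + k + 1) for k in range(arm - 1))
        n0 = len(pts)
        for k in range(spur):
            pts.append([0.0, 0.0, 5.0 * (k + 1)])
            edges.append((n0 + k - 1 if k else 0, n0 + k))
        cs = to_cs(np.asarray(pts))
        g = build_node_graph(cs)
        for a, b in edges:
            g.add_edge(a, b, length=float(np.linalg.norm(
                np.asarray(pts[a]) - np.asarray(pts[b]))), stage=1)
        return g

    def test_one_node_spur_removed(self):
        g = self._y_graph(spur=1)
        n = g.number_of_nodes()
        vt.prune_artifacts(g)
        assert g.number_of_nodes() == n - 1
        assert all(d in (1, 2, 3) for _, d in g.degree)

    def test_two_node_spur_removed(self):
        g = self._y_graph(spur=2)
        n = g.number_of_nodes()
        vt.prune_artifacts(g)
        assert g.number_of_nodes() == n - 2

    def test_long_arms_unchanged(self):
        g = self._y_graph(spur=0)
        n = g.number_of_nodes()
        vt.prune_artifacts(g)
        assert g.number_of_nodes() == n

    def test_minor_component_removed(self):
        g = self._y_graph(spur=0)
        n = g.number_of_nodes()
        for k in range(5):
            g.add_node(n + k, pos=(500.0 + 5 * k, 0.0, 0.0), diameter=10.0)
        for k in range(4):
            g.add_edge(n + k, n + k + 1, length=5.0, stage=1)
        vt.prune_artifacts(g)
        assert g.number_of_nodes() == n

    def test_isolated_nodes_removed(self):
        g = self._y_graph(spur=0)
        n = g.number_of_nodes()
        g.add_node(n, pos=(900.0, 900.0, 0.0), diameter=10.0)
        vt.prune_artifacts(g)
        assert n not in g

    def test_empty_after_pruning_raises(self):
        cs = to_cs(np.array([[0, 0, 0], [100, 0, 0.0]]))
        g = build_node_graph(cs)  # two isolated nodes
        with pytest.raises(DataError, match="empty"):
            vt.prune_artifacts(g)


class TestSegments:
    def test_y_tree_three_segments(self):
        g = TestPruning()._y_graph(spur=0)
        segs = vt.extract_segments(g)
        assert len(segs) == 3
        assert all(s.endpoints[0] != s.endpoints[1] for s in segs)

    def test_chain_length(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0], [4, 0, 0.0]])
        cs = to_cs(pts)
        g = build_node_graph(cs)
        for k in range(4):
            g.add_edge(k, k + 1, length=1.0, stage=1)
        segs = vt.extract_segments(g)
        assert len(segs) == 1
        assert segs[0].length == pytest.approx(4.0)

    def test_length_conservation(self, default_centerline):
        g = vt.reconstruct(default_centerline)
        segs = vt.extract_segments(g)
        total_edges = sum(d["length"] for _, _, d in g.edges(data=True))
        assert sum(s.length for s in segs) == pytest.approx(total_edges, rel=1e-12)

    def test_segment_count_matches_ground_truth(self, default_tree, default_centerline):
        _, gt = default_tree
        g = vt.reconstruct(default_centerline)
        assert nx.is_tree(g)
        segs = vt.extract_segments(g)
        assert len(segs) == gt.n_segments


class TestOracleEquivalence:
    """The spatial-index implementation must replay the literal rules exactly."""

    @pytest.mark.parametrize("seed", range(10))
    def test_stagewise_edge_sets_identical(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(40, 150))
        pts = random_point_mix(rng, n)
        cs = to_cs(pts)
        scales = vt.compute_neighbor_scales(cs)
        g1 = vt.link_stage1(cs, scales)
        e1 = {tuple(sorted(e)) for e in g1.edges}
        g2 = vt.link_stage2(g1, scales)
        e2 = {tuple(sorted(e)) for e in g2.edges}
        g3 = vt.link_stage3(g2, scales)
        e3 = {tuple(sorted(e)) for e in g3.edges}
        o1, o2, o3 = replay_linking(pts, scales.nn2, scales.nn5, scales.nn10)
        assert e1 == o1
        assert e2 == o2
        assert e3 == o3
        # pruning replay on the linked graph
        nodes_o, edges_o = replay_prune(len(pts), e3)
        try:
            vt.prune_artifacts(g3)
        except DataError:
            assert not nodes_o
            return
        assert set(g3.nodes) == nodes_o
        assert {tuple(sorted(e)) for e in g3.edges} == edges_o

    @pytest.mark.parametrize("seed", range(5))
    def test_stage2_creates_no_cycles(self, seed):
        rng = np.random.default_rng(2000 + seed)
        pts = random_point_mix(rng, int(rng.integers(50, 200)))
        cs = to_cs(pts)
        scales = vt.compute_neighbor_scales(cs)
        g = vt.link_stage2(vt.link_stage1(cs, scales), scales)
        assert len(nx.cycle_basis(g)) == 0

    def test_reconstruction_deterministic(self):
        rng = np.random.default_rng(3)
        pts = random_point_mix(rng, 120)
        e = [
            {tuple(sorted(ed)) for ed in vt.reconstruct(to_cs(pts), prune=False).edges}
            for _ in range(2)
        ]
        assert e[0] == e[1]


class TestRootAndOrientation:
    def test_root_is_largest_diameter_tip(self, default_centerline):
        g = vt.reconstruct(default_centerline)
        root = vt.select_root(g)
        assert g.degree[root] == 1
        tips = [n for n in g.nodes if g.degree[n] == 1]
        assert g.nodes[root]["diameter"] == max(g.nodes[t]["diameter"] for t in tips)

    def test_orientation_covers_all_edges(self, default_centerline):
        g = vt.reconstruct(default_centerline)
        root = vt.select_root(g)
        dg = vt.orient_from_root(g, root)
        assert dg.number_of_edges() == g.number_of_edges()
        assert dg.in_degree(root) == 0

    def test_exports(self, tmp_path, default_centerline):
        g = vt.reconstruct(default_centerline)
        from vasctree.graph import export_graphml, graph_to_edge_table

        table = graph_to_edge_table(g)
        assert len(table) == g.number_of_edges()
        out = export_graphml(g, tmp_path / "g.graphml")
        back = nx.read_graphml(out)
        assert back.number_of_edges() == g.number_of_edges()
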