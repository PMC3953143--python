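import math

import networkx as nx
import numpy as np
import pytest
from scipy.spatial.distance import directed_hausdorff as scipy_dh

from looprule.io_formats import HelixAxis, SkeletonCloud
from looprule.loop_finder import (
    EndpointPair,
    attach_endpoints,
    bfs_path,
    directed_hausdorff,
    enumerate_endpoint_pairs,
    find_loop_paths,
    select_lcg,
)
from looprule.preprocess import LCG, build_lcgs


def brute_force_dh(z, nodes):
    """Textbook double loop: max over endpoints of the min Euclidean distance."""

    def dist(a, b):
        dx, dy, dz = float(a[0] - b[0]), float(a[1] - b[1]), float(a[2] - b[2])
        return math.sqrt(dx * dx + dy * dy + dz * dz)

    return max(min(dist(zi, bj) for bj in nodes) for zi in z)


def make_lcg(nodes, lcg_id="lcg0"):
    """Build an LCG over explicit nodes, fully connected (edges irrelevant for
    Hausdorff/selection tests)."""
    nodes = np.asarray(nodes, dtype=float)
    order = np.lexsort((nodes[:, 2], nodes[:, 1], nodes[:, 0]))
    nodes = nodes[order]
    edges = [(i, i + 1) for i in range(len(nodes) - 1)]
    return LCG(id=lcg_id, nodes=nodes, edges=edges)


class TestEndpointPairs:
    def test_four_pairs_in_canonical_order(self):
        h1 = HelixAxis("H1", [0, 0, 0], [0, 0, 10])
        h2 = HelixAxis("H2", [8, 0, 0], [8, 0, 10])
        pairs = enumerate_endpoint_pairs(h1, h2)
        assert [p.label for p in pairs] == ["p-r", "p-s", "q-r", "q-s"]
        np.testing.assert_allclose(pairs[0].e1, h1.p)
        np.testing.assert_allclose(pairs[3].e2, h2.q)

    def test_swapping_helices_gives_same_unordered_pairs(self, rng):
        h1 = HelixAxis("H1", rng.uniform(0, 5, 3), rng.uniform(5, 10, 3))
        h2 = HelixAxis("H2", rng.uniform(10, 15, 3), rng.uniform(15, 20, 3))
        fwd = {frozenset((tuple(p.e1), tuple(p.e2))) for p in enumerate_endpoint_pairs(h1, h2)}
        rev = {frozenset((tuple(p.e1), tuple(p.e2))) for p in enumerate_endpoint_pairs(h2, h1)}
        assert fwd == rev and len(fwd) == 4


class TestDirectedHausdorff:
    def test_endpoints_on_lcg_give_zero(self):
        lcg = make_lcg([[0, 0, 0], [3, 0, 0], [5, 1, 0]])
        assert directed_hausdorff([[0, 0, 0], [3, 0, 0]], lcg) == 0.0

    def test_worked_example(self):
        lcg = make_lcg([[0, 1, 0], [3, 4, 0]])
        z = [[0, 0, 0], [3, 0, 0]]
        # min distances are 1 and √10; the directed distance is the max
        assert directed_hausdorff(z, lcg) == pytest.approx(np.sqrt(10), abs=1e-12)

    def test_single_point_sets_reduce_to_euclidean(self):
        lcg = make_lcg([[1, 2, 2]])
        assert directed_hausdorff([[4, 6, 2]], lcg) == pytest.approx(5.0)

    def test_asymmetry(self):
        # z far from one node, but every LCG node close to z: h(z,b) != h(b,z)
        z = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        nodes = np.array([[0.0, 1, 0], [1.0, 1, 0]])
        lcg = make_lcg(nodes)
        h_zb = directed_hausdorff(z, lcg)
        h_bz = brute_force_dh(nodes, z)
        assert h_zb != pytest.approx(h_bz)

    def test_matches_brute_force_and_scipy(self, rng):
        for _ in range(500):
            z = rng.uniform(-10, 10, size=(2, 3))
            nodes = rng.uniform(-10, 10, size=(rng.integers(1, 12), 3))
            lcg = make_lcg(nodes)
            ours = directed_hausdorff(z, lcg)
            assert ours == brute_force_dh(z, lcg.nodes)
            assert ours == pytest.approx(scipy_dh(z, lcg.nodes)[0], abs=1e-12)


class TestSelectLcg:
    def test_single_lcg(self):
        lcg = make_lcg([[0, 0, 0]])
        pair = EndpointPair("q-r", np.zeros(3), np.ones(3))
        assert select_lcg(pair, [lcg]) is lcg

    def test_six_cluster_configuration_selects_nearest(self, rng):
        # endpoint pair bracketing cluster 1; five decoys farther away
        pair = EndpointPair("q-r", np.array([0.0, 0, 0]), np.array([10.0, 0, 0]))
        true_cluster = make_lcg(np.linspace([1, 1, 0], [9, 1, 0], 9), "true")
        decoys = [
            make_lcg(rng.normal(0, 1.5, size=(8, 3)) + c, f"decoy{i}")
            for i, c in enumerate(np.array([[5, 15, 0], [-12, 0, 0], [22, 0, 0], [5, -14, 3], [5, 0, 18]]))
        ]
        assert select_lcg(pair, [true_cluster] + decoys).id == "true"

    def test_matches_exhaustive_argmin(self, rng):
        for _ in range(30):
            pair = EndpointPair("q-r", rng.uniform(0, 10, 3), rng.uniform(0, 10, 3))
            lcgs = [
                make_lcg(rng.uniform(-20, 20, size=(rng.integers(2, 10), 3)), f"lcg{i}")
                for i in range(5)
            ]
            z = pair.as_array()
            best = min(lcgs, key=lambda b: (brute_force_dh(z, b.nodes), -len(b), b.id))
            assert select_lcg(pair, lcgs).id == best.id


class TestAttachEndpoints:
    def setup_method(self):
        self.lcg = make_lcg([[2, 0, 0], [3, 0, 0], [4, 0, 0]])

    def test_close_endpoints_attach(self):
        pair = EndpointPair("q-r", np.array([1.0, 0, 0]), np.array([5.0, 0, 0]))
        adjacency, coords, lengths = attach_endpoints(pair, self.lcg)
        assert lengths == (1.0, 1.0)
        np.testing.assert_allclose(coords[3], pair.e1)
        assert adjacency[3] == [0]  # e1 attaches to nearest node (2,0,0)

    def test_endpoint_beyond_cutoff_is_infeasible(self):
        pair = EndpointPair("q-r", np.array([-3.1, 0, 0]), np.array([5.0, 0, 0]))
        assert attach_endpoints(pair, self.lcg, cutoff=5.0) is None

    def test_exactly_cutoff_is_feasible(self):
        pair = EndpointPair("q-r", np.array([-3.0, 0, 0]), np.array([5.0, 0, 0]))
        assert attach_endpoints(pair, self.lcg, cutoff=5.0) is not None


class TestBfsPath:
    def test_straight_chain_visits_all(self):
        lcg = make_lcg([[1, 0, 0], [2, 0, 0], [3, 0, 0], [4, 0, 0], [5, 0, 0]])
        pair = EndpointPair("q-r", np.array([0.0, 0, 0]), np.array([6.0, 0, 0]))
        adjacency, coords, _ = attach_endpoints(pair, lcg)
        path = bfs_path(adjacency, coords, 5, 6)
        np.testing.assert_allclose(
            coords[path],
            [[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0], [4, 0, 0], [5, 0, 0], [6, 0, 0]],
        )

    def test_prefers_fewer_hops(self):
        # ring where one side is 2 hops and the other 4
        nodes = np.array(
            [[0, 0, 0], [1, 1, 0], [2, 0, 0], [0.5, -1, 0], [1, -1.5, 0], [1.5, -1, 0]], dtype=float
        )
        lcg = LCG(id="ring", nodes=nodes, edges=[(0, 1), (1, 2), (0, 3), (3, 4), (4, 5), (5, 2)])
        adjacency = {i: [] for i in range(6)}
        for a, b in lcg.edges:
            adjacency[a].append(b)
            adjacency[b].append(a)
        path = bfs_path(adjacency, nodes, 0, 2)
        assert path == [0, 1, 2]

    def test_hop_count_matches_networkx_on_random_graphs(self, rng):
        for _ in range(20):
            pts = np.unique(rng.integers(0, 5, size=(40, 3)), axis=0).astype(float)
            cloud = SkeletonCloud(points=pts)
            lcgs = build_lcgs(cloud)
            g = lcgs[0]
            if len(g) < 3:
                continue
            adjacency = {i: sorted({b for a, b in g.edges if a == i} | {a for a, b in g.edges if b == i})
                         for i in range(len(g))}
            G = nx.Graph(g.edges)
            G.add_nodes_from(range(len(g)))
            src, dst = 0, len(g) - 1
            path = bfs_path(adjacency, g.nodes, src, dst)
            assert path is not None
            assert len(path) - 1 == nx.shortest_path_length(G, src, dst)

    def test_branch_excluded_by_exhaustive_enumeration(self):
        # Y-shaped skeleton: trunk to target plus a dead-end branch
        pts = np.array(
            [[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0], [4, 0, 0],
             [2, 1, 0], [2, 2, 0], [2, 3, 0]], dtype=float
        )
        cloud = SkeletonCloud(points=pts)
        g = build_lcgs(cloud)[0]
        adjacency = {i: [] for i in range(len(g))}
        for a, b in g.edges:
            adjacency[a].append(b)
            adjacency[b].append(a)
        for v in adjacency.values():
            v.sort()
        idx_of = {tuple(p): i for i, p in enumerate(map(tuple, g.nodes))}
        src, dst = idx_of[(0, 0, 0)], idx_of[(4, 0, 0)]
        path = bfs_path(adjacency, g.nodes, src, dst)
        # oracle: minimum-hop simple path by exhaustive enumeration
        G = nx.Graph(g.edges)
        best = min(nx.all_simple_paths(G, src, dst), key=len)
        assert len(path) == len(best)
        branch = {idx_of[(2, 2, 0)], idx_of[(2, 3, 0)]}
        assert not (set(path) & branch)


class TestFindLoopPaths:
    def _fixture(self, rng, decoys=0):
        from looprule.synthetic import generate_hlh

        return generate_hlh(4, seed=int(rng.integers(0, 2**31)), decoy_clusters=decoys)

    def test_clean_fixture_true_pair_feasible(self, rng):
        hlh = self._fixture(rng)
        lcgs = build_lcgs(hlh.cloud)
        paths = find_loop_paths(hlh.helices[0], hlh.helices[1], lcgs)
        assert len(paths) == 4
        by_label = {p.pair.label: p for p in paths}
        assert by_label[hlh.true_pair_label].feasible

    def test_all_lcgs_beyond_cutoff_gives_four_infeasible(self):
        h1 = HelixAxis("H1", [0, 0, 0], [0, 0, 10])
        h2 = HelixAxis("H2", [8, 0, 0], [8, 0, 10])
        far = make_lcg([[100, 100, 100], [101, 100, 100]])
        paths = find_loop_paths(h1, h2, [far])
        assert all(not p.feasible for p in paths)

    def test_decoys_do_not_steal_true_pair(self, rng):
        hlh = self._fixture(rng, decoys=2)
        lcgs = build_lcgs(hlh.cloud)
        paths = find_loop_paths(hlh.helices[0], hlh.helices[1], lcgs)
        true_path = {p.pair.label: p for p in paths}[hlh.true_pair_label]
        assert true_path.feasible
        selected = next(g for g in lcgs if g.id == true_path.lcg_id)
        true_set = set(map(tuple, np.round(hlh.true_lcg_points, 6)))
        sel_set = set(map(tuple, np.round(selected.nodes, 6)))
        assert true_set <= sel_set

    def test_invariant_under_lcg_permutation(self, rng):
        hlh = self._fixture(rng, decoys=3)
        lcgs = build_lcgs(hlh.cloud)
        paths_a = find_loop_paths(hlh.helices[0], hlh.helices[1], lcgs)
        paths_b = find_loop_paths(hlh.helices[0], hlh.helices[1], lcgs[::-1])
        for a, b in zip(paths_a, paths_b):
            assert a.feasible == b.feasible and a.lcg_id == b.lcg_id
            if a.feasible:
                np.testing.assert_allclose(a.vertices, b.vertices)
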