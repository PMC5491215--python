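"""Geometry kernel tests: construction, shortest paths, m(u, t),
circumradius and snapping, validated against independent brute-force
oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import netdendro as nd
from conftest import random_location, random_locations, rigid_transform
from oracles import oracle_circumradius, oracle_distance, oracle_m


class TestBuildNetwork:
    def test_single_segment_length(self, single_segment):
        assert single_segment.total_length == pytest.approx(3.0 + 7.0)

    def test_y_tree_total_length(self, y_tree):
        assert y_tree.total_length == pytest.approx(10.0)

    def test_total_length_equals_resummed_polylines(self, small_tree_factory):
        net = small_tree_factory(7)
        direct = sum(
            np.linalg.norm(net.vertices[b] - net.vertices[a])
            for a, b in net.segments)
        assert net.total_length == pytest.approx(direct, abs=1e-9)

    @pytest.mark.parametrize("edges,err", [
        ([(0, 1)], "disconnected"),                       # vertex 2 isolated
        ([(0, 1), (1, 2), (2, 0)], "cycle"),
        ([(0, 0)], "distinct"),
    ])
    def test_invalid_topologies_rejected(self, edges, err):
        verts = [(0, 0, 0), (1, 0, 0), (0, 1, 0)]
        with pytest.raises(nd.NetworkError, match=err):
            nd.build_network(verts, edges)

    def test_zero_length_edge_rejected(self):
        with pytest.raises(nd.NetworkError, match="zero length"):
            nd.build_network([(0, 0, 0), (0, 0, 0)], [(0, 1)])


class TestShortestPath:
    def test_identity_and_same_segment(self, single_segment):
        u = nd.NetworkLocation(0, 2.0)
        v = nd.NetworkLocation(0, 6.0)
        assert nd.shortest_path_distance(single_segment, u, u) == 0.0
        assert nd.shortest_path_distance(single_segment, u, v) == pytest.approx(4.0)

    def test_distance_to_root_y_tree(self, y_tree):
        tip = y_tree.canonicalize(nd.NetworkLocation(1, 3.0))
        assert nd.distance_to_root(y_tree, tip) == pytest.approx(7.0)
        assert nd.distance_to_root(y_tree, y_tree.root) == 0.0

    def test_off_network_location_rejected(self, single_segment):
        with pytest.raises(nd.NetworkError):
            nd.shortest_path_distance(single_segment,
                                      nd.NetworkLocation(0, 1.0),
                                      nd.NetworkLocation(3, 1.0))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_dijkstra_oracle(self, small_tree_factory, seed):
        net = small_tree_factory(seed)
        rng = np.random.default_rng(100 + seed)
        for _ in range(8):
            u, v = random_locations(net, rng, 2)
            d = nd.shortest_path_distance(net, u, v)
            assert d == pytest.approx(oracle_distance(net, u, v), abs=1e-6)
            assert d == pytest.approx(nd.shortest_path_distance(net, v, u))

    def test_triangle_inequality(self, small_tree_factory):
        net = small_tree_factory(11)
        rng = np.random.default_rng(42)
        for _ in range(10):
            u, v, w = random_locations(net, rng, 3)
            duv = nd.shortest_path_distance(net, u, v)
            assert duv <= (nd.shortest_path_distance(net, u, w)
                           + nd.shortest_path_distance(net, w, v) + 1e-9)

    def test_distance_to_root_vectorized(self, small_tree_factory):
        net = small_tree_factory(5)
        rng = np.random.default_rng(5)
        locs = random_locations(net, rng, 6)
        vec = nd.distance_to_root(net, locs)
        one = [nd.shortest_path_distance(net, net.root, u) for u in locs]
        np.testing.assert_allclose(vec, one, atol=1e-9)

    def test_root_unset_errors(self):
        net = nd.build_network([(0, 0, 0), (1, 0, 0)], [(0, 1)])
        with pytest.raises(nd.NetworkError, match="root"):
            nd.distance_to_root(net, nd.NetworkLocation(0, 0.5))


class TestCountAtDistance:
    def test_single_segment_fronts(self, single_segment):
        u = nd.NetworkLocation(0, 3.0)
        assert nd.count_at_distance(single_segment, u, 2.0) == 2
        assert nd.count_at_distance(single_segment, u, 7.0) == 1  # far vertex
        assert nd.count_at_distance(single_segment, u, 8.0) == 0
        assert nd.count_at_distance(single_segment, u, 0.0) == 1

    def test_negative_distance_rejected(self, single_segment):
        with pytest.raises(ValueError):
            nd.count_at_distance(single_segment, nd.NetworkLocation(0, 3.0), -1.0)

    def test_vertex_counts_once_across_branches(self, y_tree):
        # the degree-3 vertex sits at distance 4 from the root: one location
        u = y_tree.root
        assert nd.count_at_distance(y_tree, u, 4.0) == 1
        # just past the branch vertex the front crosses both branches
        assert nd.count_at_distance(y_tree, u, 5.0) == 2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_discretization_oracle(self, small_tree_factory, seed):
        eps = 0.01
        net = small_tree_factory(30 + seed)
        rng = np.random.default_rng(200 + seed)
        for _ in range(4):
            u = random_location(net, rng)
            ecc = nd.eccentricity(net, u)
            dv = net.distances_to_vertices(u)
            for _ in range(20):
                t = float(rng.uniform(0.05, 0.95) * ecc)
                if np.min(np.abs(dv - t)) > 2 * eps:
                    break
            assert nd.count_at_distance(net, u, t) == oracle_m(net, u, t, eps=eps)

    def test_positive_below_eccentricity(self, small_tree_factory):
        net = small_tree_factory(9)
        rng = np.random.default_rng(9)
        u = random_location(net, rng)
        ecc = nd.eccentricity(net, u)
        ts = rng.uniform(1e-3, ecc * 0.999, size=50)
        m = nd.counts_at_distances(net, u, ts)
        assert np.all(m >= 1)
        assert nd.count_at_distance(net, u, ecc * 1.01) == 0

    def test_vectorized_matches_scalar(self, small_tree_factory):
        net = small_tree_factory(3)
        rng = np.random.default_rng(33)
        u = random_location(net, rng)
        ts = rng.uniform(0, nd.eccentricity(net, u) * 1.1, size=40)
        vec = nd.counts_at_distances(net, u, ts)
        assert list(vec) == [nd.count_at_distance(net, u, t) for t in ts]


class TestCircumradius:
    def test_single_segment_midpoint(self, single_segment):
        assert nd.circumradius(single_segment) == pytest.approx(5.0)

    def test_three_arm_star(self):
        net = nd.build_network([(0, 0, 0), (3, 0, 0), (0, 4, 0), (0, 0, 5)],
                               [(0, 1), (0, 2), (0, 3)])
        assert nd.circumradius(net) == pytest.approx(4.5)
        assert nd.circumradius(net) == pytest.approx(
            oracle_circumradius(net, eps=0.001), abs=1e-3)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_discretization_oracle(self, small_tree_factory, seed):
        net = small_tree_factory(60 + seed)
        assert nd.circumradius(net) == pytest.approx(
            oracle_circumradius(net, eps=0.001), abs=1e-3)

    def test_consistent_with_sup_definition(self, small_tree_factory):
        net = small_tree_factory(8)
        rng = np.random.default_rng(88)
        r = nd.circumradius(net)
        for _ in range(10):
            u = random_location(net, rng)
            t = rng.uniform(0, r * 0.999)
            assert nd.count_at_distance(net, u, float(t)) > 0


class TestSnap:
    def test_on_network_point_returns_itself(self, y_tree):
        u = nd.NetworkLocation(1, 1.5)
        p = y_tree.coordinates(u)
        got = nd.snap_to_network(y_tree, p, max_dist=1.0)
        assert y_tree.same_location(got, u)

    def test_orthogonal_projection(self, single_segment):
        got = nd.snap_to_network(single_segment, (4.0, 1.0, 0.0), max_dist=2.0)
        assert got.segment == 0
        assert got.offset == pytest.approx(4.0)

    def test_too_far_errors_with_point(self, single_segment):
        with pytest.raises(nd.NetworkError, match="3"):
            nd.snap_to_network(single_segment, (3.0, 9.0, 0.0), max_dist=2.0)

    def test_noisy_points_recovered(self, small_tree_factory):
        net = small_tree_factory(4)
        rng = np.random.default_rng(44)
        sigma = 0.2
        within = 0
        for _ in range(30):
            u = random_location(net, rng)
            noise = rng.normal(0, sigma, size=3)
            p = net.coordinates(u) + noise
            got = nd.snap_to_network(net, p, max_dist=5 * sigma)
            resid = np.linalg.norm(net.coordinates(got) - net.coordinates(u))
            # the nearest network point is never farther than twice the noise
            assert resid <= 2 * np.linalg.norm(noise) + 1e-9
            within += resid <= 3 * sigma
        assert within >= 27  # 3D noise norm itself exceeds 3 sigma ~3% of draws


class TestInvariances:
    def test_rigid_motion_preserves_metrics(self, small_tree_factory):
        net = small_tree_factory(12)
        rng = np.random.default_rng(120)
        moved = nd.build_network(rigid_transform(net.vertices, rng),
                                 net.segments, root_vertex=0)
        assert moved.total_length == pytest.approx(net.total_length, rel=1e-9)
        assert nd.circumradius(moved) == pytest.approx(nd.circumradius(net),
                                                       rel=1e-9)
        for _ in range(5):
            u, v = random_locations(net, rng, 2)
            assert nd.shortest_path_distance(moved, u, v) == pytest.approx(
                nd.shortest_path_distance(net, u, v), rel=1e-9)
            t = rng.uniform(0, nd.eccentricity(net, u))
            assert (nd.count_at_distance(moved, u, t)
                    == nd.count_at_distance(net, u, t))

    def test_planar_network_matches_2d_projection(self):
        rng = np.random.default_rng(77)
        xy = rng.uniform(0, 30, size=(6, 2))
        edges = [(0, 1), (1, 2), (1, 3), (3, 4), (3, 5)]
        flat = nd.build_network(np.column_stack([xy, np.full(6, 12.5)]),
                                edges, root_vertex=0)
        proj = nd.build_network(np.column_stack([xy, np.zeros(6)]),
                                edges, root_vertex=0)
        assert flat.total_length == proj.total_length
        assert nd.circumradius(flat) == nd.circumradius(proj)
        for _ in range(5):
            u, v = random_locations(flat, rng, 2)
            assert (nd.shortest_path_distance(flat, u, v)
                    == nd.shortest_path_distance(proj, u, v))


class TestDistanceProperties:
    # Y-tree: trunk (segment 0, length 4) then two branches of length 3
    _seg_len = {0: 4.0, 1: 3.0, 2: 3.0}

    @staticmethod
    def _hand_distance(s1, o1, s2, o2):
        """Closed-form geodesic on the Y-tree, written independently."""
        if s1 == s2:
            return abs(o1 - o2)
        # distance of each location to the branch vertex
        to_branch = {0: lambda o: 4.0 - o, 1: lambda o: o, 2: lambda o: o}
        return to_branch[s1](o1) + to_branch[s2](o2)

    @given(s1=st.integers(0, 2), s2=st.integers(0, 2),
           f1=st.floats(0, 1), f2=st.floats(0, 1))
    @settings(max_examples=60, deadline=None)
    def test_y_tree_distance_closed_form(self, s1, s2, f1, f2):
        net = nd.build_network([(0, 0, 0), (0, 0, 4), (3, 0, 4), (0, 3, 4)],
                               [(0, 1), (1, 2), (1, 3)], root_vertex=0)
        u = nd.NetworkLocation(s1, f1 * self._seg_len[s1])
        v = nd.NetworkLocation(s2, f2 * self._seg_len[s2])
        d = nd.shortest_path_distance(net, u, v)
        assert d == pytest.approx(
            self._hand_distance(s1, u.offset, s2, v.offset), abs=1e-9)
        assert d == pytest.approx(nd.shortest_path_distance(net, v, u),
                                  abs=1e-12)
        assert nd.count_at_distance(net, u, 0.0) == 1


class TestLocations:
    def test_vertex_location_equality_across_segments(self, y_tree):
        # the branch vertex is the end of segment 0 and start of segments 1, 2
        a = nd.NetworkLocation(0, 4.0)
        b = nd.NetworkLocation(1, 0.0)
        c = nd.NetworkLocation(2, 0.0)
        assert y_tree.same_location(a, b)
        assert y_tree.same_location(b, c)
        assert y_tree.canonicalize(a) == y_tree.canonicalize(c)

    def test_invalid_offset_rejected(self, single_segment):
        with pytest.raises(nd.NetworkError):
            single_segment.validate_location(nd.NetworkLocation(0, 11.0))
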