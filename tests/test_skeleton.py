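"""Skeletonization, node classification, pruning, and radius assignment."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import vasculate as v
from vasculate.skeleton import classify_and_split, prune, assign_radii, skeletonize


def _kinds(sk):
    kinds = [n.kind for n in sk.nodes]
    return kinds.count("terminal"), kinds.count("bifurcation")


def _chain_skeleton(positions):
    """Skeleton from an explicit polyline of node positions."""
    nodes = [v.SkeletonNode(i, np.asarray(p, float)) for i, p in enumerate(positions)]
    edges = [(i, i + 1) for i in range(len(nodes) - 1)]
    sk = v.Skeleton(nodes=nodes, edges=edges)
    sk.recompute_degrees()
    return sk


class TestSkeletonize:
    def test_straight_cylinder_topology(self, tube_phantom):
        vol, _ = tube_phantom
        sk = classify_and_split(skeletonize(vol))
        n_term, n_bif = _kinds(sk)
        assert n_term == 2
        assert n_bif == 0
        assert len(sk.segments) == 1

    def test_skeleton_voxels_subset_of_foreground(self, tube_phantom):
        vol, _ = tube_phantom
        sk = skeletonize(vol)
        assert vol.data[tuple(sk.voxels.T)].all()

    def test_one_voxel_thick(self, tube_phantom):
        # no 2x2x2 solid block of skeleton voxels
        vol, _ = tube_phantom
        sk = skeletonize(vol)
        mask = np.zeros(vol.data.shape, bool)
        mask[tuple(sk.voxels.T)] = True
        blocks = (mask[:-1, :-1, :-1] & mask[1:, :-1, :-1] & mask[:-1, 1:, :-1]
                  & mask[:-1, :-1, 1:] & mask[1:, 1:, :-1] & mask[1:, :-1, 1:]
                  & mask[:-1, 1:, 1:] & mask[1:, 1:, 1:])
        assert not blocks.any()

    def test_single_voxel(self):
        vol = v.VoxelVolume(np.zeros((5, 5, 5), bool))
        vol.data[2, 2, 2] = True
        sk = skeletonize(vol)
        assert len(sk.nodes) == 1
        assert sk.nodes[0].degree == 0
        assert sk.nodes[0].kind == "terminal"

    def test_y_phantom(self, y_phantom):
        vol, _ = y_phantom
        sk = classify_and_split(skeletonize(vol))
        n_term, n_bif = _kinds(sk)
        assert n_term == 3
        assert n_bif == 1
        assert len(sk.segments) == 3

    def test_empty_volume_raises(self):
        with pytest.raises(ValueError, match="no foreground"):
            skeletonize(v.VoxelVolume(np.zeros((4, 4, 4), bool)))

    def test_idempotent_on_thin_volume(self, tube_phantom):
        vol, _ = tube_phantom
        sk1 = skeletonize(vol)
        thin = np.zeros(vol.data.shape, bool)
        thin[tuple(sk1.voxels.T)] = True
        sk2 = skeletonize(v.VoxelVolume(thin, spacing=vol.spacing))
        assert np.array_equal(np.sort(sk1.voxels, axis=0),
                              np.sort(sk2.voxels, axis=0))

    def test_component_count_preserved(self):
        vol = np.zeros((24, 24, 24), bool)
        vol[4:9, 4:9, 2:20] = True
        vol[14:19, 14:19, 2:20] = True
        sk = skeletonize(v.VoxelVolume(vol))
        import networkx as nx

        assert nx.number_connected_components(sk.to_networkx()) == 2


class TestClassifyAndSplit:
    def test_plain_path(self):
        sk = _chain_skeleton([(i, 0, 0) for i in range(10)])
        classify_and_split(sk)
        n_term, n_bif = _kinds(sk)
        assert (n_term, n_bif) == (2, 0)
        assert len(sk.segments) == 1

    def test_h_shape_five_segments(self):
        # two bifurcations joined by a bridge, four arms
        nodes = {}
        edges = []
        pts = {"b1": (0, 0, 0), "b2": (5, 0, 0)}
        idx = 0
        pos = []
        id_of = {}
        for key, p in pts.items():
            id_of[key] = idx
            pos.append(p)
            idx += 1
        for arm_end, root in [((-3, 3, 0), "b1"), ((-3, -3, 0), "b1"),
                              ((8, 3, 0), "b2"), ((8, -3, 0), "b2")]:
            pos.append(arm_end)
            edges.append((id_of[root], idx))
            idx += 1
        edges.append((id_of["b1"], id_of["b2"]))
        sk = v.Skeleton(nodes=[v.SkeletonNode(i, np.asarray(p, float))
                               for i, p in enumerate(pos)], edges=edges)
        sk.recompute_degrees()
        classify_and_split(sk)
        assert len(sk.segments) == 5
        assert _kinds(sk)[1] == 2

    def test_pure_cycle_is_one_closed_segment(self):
        n = 8
        nodes = [v.SkeletonNode(i, np.array([np.cos(2 * np.pi * i / n),
                                             np.sin(2 * np.pi * i / n), 0.0]))
                 for i in range(n)]
        edges = [(i, (i + 1) % n) for i in range(n)]
        sk = v.Skeleton(nodes=nodes, edges=edges)
        sk.recompute_degrees()
        classify_and_split(sk)
        assert len(sk.segments) == 1

    @given(st.integers(min_value=2, max_value=12), st.integers(0, 10_000))
    def test_segment_count_matches_bruteforce_on_random_trees(self, n_extra, seed):
        """#segments equals the edge count of the bifurcation-contracted
        graph, checked against explicit path enumeration."""
        rng = np.random.default_rng(seed)
        pos = [np.array([0.0, 0.0, 0.0])]
        edges = []
        for i in range(1, n_extra + 1):
            parent = int(rng.integers(0, i))
            pos.append(pos[parent] + rng.normal(size=3))
            edges.append((parent, i))
        sk = v.Skeleton(nodes=[v.SkeletonNode(i, p) for i, p in enumerate(pos)],
                        edges=edges)
        sk.recompute_degrees()
        classify_and_split(sk)
        # brute force: count maximal paths whose interior nodes have degree 2
        import networkx as nx

        g = sk.to_networkx()
        deg = dict(g.degree())
        expected = 0
        seen = set()
        for a, b in g.edges():
            if (a, b) in seen or (b, a) in seen:
                continue
            # walk both directions to the nearest non-degree-2 node
            def walk(start, nxt):
                chain = [(start, nxt)]
                prev, cur = start, nxt
                while deg[cur] == 2:
                    nxt2 = next(x for x in g.neighbors(cur) if x != prev)
                    chain.append((cur, nxt2))
                    prev, cur = cur, nxt2
                return chain
            left = walk(b, a)
            right = walk(a, b)
            for e in left + right:
                seen.add(e)
                seen.add((e[1], e[0]))
            expected += 1
        assert len(sk.segments) == expected


class TestPrune:
    def _y(self, short_len=1.0):
        pts = ([(float(i), 0, 0) for i in range(6)]
               + [(5 + float(i + 1), 0, 0) for i in range(5)]
               + [(5.0, float(i + 1) * short_len / 2, 0) for i in range(2)])
        edges = ([(i, i + 1) for i in range(5)]
                 + [(5, 6)] + [(i, i + 1) for i in range(6, 10)]
                 + [(5, 11), (11, 12)])
        sk = v.Skeleton(nodes=[v.SkeletonNode(i, np.asarray(p, float))
                               for i, p in enumerate(pts)], edges=edges)
        sk.recompute_degrees()
        return classify_and_split(sk)

    def test_short_branch_removed_and_bifurcation_reclassified(self):
        sk = self._y(short_len=1.0)
        assert len(sk.segments) == 3
        pruned = prune(sk, min_length_mm=2.0)
        assert len(pruned.segments) == 1
        assert _kinds(pruned) == (2, 0)

    def test_zero_min_length_is_identity(self):
        sk = self._y()
        assert prune(sk, min_length_mm=0.0) is sk

    def test_keep_all_labels_is_identity(self):
        sk = self._y()
        assert prune(sk, keep_labels=set(sk.segments)) is sk

    def test_pruning_everything_raises(self):
        sk = self._y()
        with pytest.raises(ValueError, match="every segment"):
            prune(sk, keep_labels=set())


class TestAssignRadii:
    def test_cylinder_radii_match_bruteforce(self, tube_phantom):
        vol, _ = tube_phantom
        sk = classify_and_split(skeletonize(vol))
        assign_radii(sk, vol)
        bg = np.argwhere(~vol.data).astype(float)
        spacing = np.asarray(vol.spacing)
        for n in sk.nodes[::5]:
            idx = n.position / spacing
            brute = np.min(np.linalg.norm((bg - idx) * spacing, axis=1))
            assert n.radius == pytest.approx(brute, rel=1e-12)
        interior = [n.radius for n in sk.nodes if n.kind == "plain"]
        assert all(2.5 <= r <= 3.5 for r in interior)

    def test_spacing_scales_radii(self, tube_phantom):
        vol, _ = tube_phantom
        sk1 = assign_radii(classify_and_split(skeletonize(vol)), vol)
        r1 = np.array([n.radius for n in sk1.nodes])
        vol2 = v.VoxelVolume(vol.data, spacing=(0.5, 0.5, 0.5))
        sk2 = assign_radii(classify_and_split(skeletonize(vol2)), vol2)
        r2 = np.array([n.radius for n in sk2.nodes])
        assert np.allclose(r2, 0.5 * r1)

    def test_thin_plate_radius_bounded(self):
        vol = np.zeros((9, 9, 9), bool)
        vol[:, :, 4] = True
        volume = v.VoxelVolume(vol)
        sk = v.Skeleton(nodes=[v.SkeletonNode(0, np.array([4.0, 4.0, 4.0]))])
        assign_radii(sk, volume)
        assert sk.nodes[0].radius <= 1.0

    def test_node_outside_foreground_raises(self, tube_phantom):
        vol, _ = tube_phantom
        sk = v.Skeleton(nodes=[v.SkeletonNode(7, np.array([0.0, 0.0, 0.0]))])
        with pytest.raises(ValueError, match="node 7"):
            assign_radii(sk, vol)
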