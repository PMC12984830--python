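"""Skeletonization, distance-transform diameters, graph build and pruning."""

import numpy as np
import pytest

from octaquant import ImageSpec
from octaquant.graph import (build_graph, diameter_map, prune_graph,
                             skeletonize)

SPEC = ImageSpec()  # 512 px over 3 mm -> 5.859375 um/px


def raster(shape, coords):
    arr = np.zeros(shape, dtype=bool)
    for r, c in coords:
        arr[r, c] = True
    return arr


def plus_sign(shape=(64, 64), centre=(32, 32), arm=10):
    r0, c0 = centre
    coords = [(r0, c0)]
    for k in range(1, arm + 1):
        coords += [(r0 + k, c0), (r0 - k, c0), (r0, c0 + k), (r0, c0 - k)]
    return raster(shape, coords)


class TestSkeletonize:
    def test_ribbon_thins_to_single_centre_path(self):
        mask = np.zeros((64, 128), dtype=bool)
        mask[31:34, 10:110] = True  # 3 px wide, 100 px long
        skel = skeletonize(mask).skeleton
        assert 90 <= skel.sum() <= 102
        rows = np.argwhere(skel)[:, 0]
        assert np.all(np.abs(rows - 32) <= 1)

    def test_one_pixel_line_is_unchanged(self):
        mask = np.zeros((32, 64), dtype=bool)
        mask[16, 5:60] = True
        assert np.array_equal(skeletonize(mask).skeleton, mask)

    def test_filled_disk_collapses_to_small_connected_locus(self):
        from scipy import ndimage

        rr, cc = np.mgrid[0:64, 0:64]
        mask = (rr - 32) ** 2 + (cc - 32) ** 2 <= 10 ** 2
        skel = skeletonize(mask).skeleton
        assert 0 < skel.sum() <= 20
        _, n = ndimage.label(skel, structure=np.ones((3, 3)))
        assert n == 1

    def test_empty_mask_gives_empty_skeleton(self):
        assert not skeletonize(np.zeros((16, 16), bool)).skeleton.any()

    def test_skeleton_subset_of_mask(self, rng):
        mask = rng.uniform(size=(64, 64)) < 0.4
        skel = skeletonize(mask).skeleton
        assert not (skel & ~mask).any()


class TestDiameterMap:
    def test_ribbon_width_five_diameter(self):
        mask = np.zeros((64, 128), dtype=bool)
        mask[30:35, 10:110] = True
        skel = skeletonize(mask)
        dmap = diameter_map(mask, skel, SPEC)
        med = np.median(dmap.skeleton_diameters_px)
        assert 4.0 <= med <= 6.0
        med_um = np.median(dmap.skeleton_diameters_um)
        assert 23.4 <= med_um <= 35.2

    def test_disk_centre_diameter_equals_twice_radius(self):
        rr, cc = np.mgrid[0:64, 0:64]
        mask = (rr - 32) ** 2 + (cc - 32) ** 2 <= 10 ** 2
        centre_only = np.zeros_like(mask)
        centre_only[32, 32] = True
        dmap = diameter_map(mask, centre_only, SPEC)
        assert abs(dmap.diameters_px[32, 32] - 20.0) <= 2.0  # ±1 px on diameter

    def test_pixel_size_from_scan_geometry(self):
        assert SPEC.pixel_size_um == pytest.approx(5.859375)

    def test_skeleton_outside_mask_rejected(self):
        mask = np.zeros((16, 16), bool)
        mask[4:8, 4:8] = True
        bad = np.zeros_like(mask)
        bad[0, 0] = True
        with pytest.raises(ValueError):
            diameter_map(mask, bad, SPEC)


class TestBuildGraph:
    def test_plus_sign_topology(self):
        g = build_graph(plus_sign(), spec=SPEC)
        assert g.n_branch_nodes == 1
        assert len(g.endpoints) == 4
        assert len(g.segments) == 4

    def test_straight_line_single_segment(self):
        skel = np.zeros((32, 128), bool)
        skel[16, 10:110] = True  # 100 pixels
        g = build_graph(skel, spec=SPEC)
        assert g.n_branch_nodes == 0
        assert len(g.endpoints) == 2
        assert len(g.segments) == 1
        assert g.segments[0].length_um(SPEC) == pytest.approx(99 * 5.859375)

    def test_empty_skeleton_empty_graph(self):
        g = build_graph(np.zeros((16, 16), bool), spec=SPEC)
        assert not g.nodes and not g.segments

    def test_pixel_conservation(self, rng):
        # every skeleton pixel is either a node pixel or interior to
        # exactly one segment
        for _ in range(20):
            mask = rng.uniform(size=(32, 32)) < 0.35
            skel = skeletonize(mask).skeleton
            g = build_graph(skel, spec=SPEC)
            node_px = sum(len(n.pixels) for n in g.nodes.values())
            interior_px = sum(s.interior_count for s in g.segments)
            assert node_px + interior_px == skel.sum()

    def test_degree_consistency(self):
        g = build_graph(plus_sign(), spec=SPEC)
        total_incidence = sum(
            sum(nid is not None for nid in s.node_ids) for s in g.segments
        )
        total_degree = sum(g.degree(nid) for nid in g.nodes)
        assert total_degree == total_incidence


class TestBruteForceOracle:
    def test_branch_endpoint_classification_matches_neighbour_oracle(self, rng):
        # 512 random 16x16 masks: compare against per-pixel enumeration
        for _ in range(512):
            skel = rng.uniform(size=(16, 16)) < 0.3
            g = build_graph(skel, spec=ImageSpec(width_px=16))
            got_branch = {p for n in g.nodes.values() if n.kind == "branch" for p in n.pixels}
            got_end = {p for n in g.nodes.values() if n.kind == "endpoint" for p in n.pixels}
            exp_branch, exp_end = set(), set()
            for r in range(16):
                for c in range(16):
                    if not skel[r, c]:
                        continue
                    cnt = 0
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            if dr == dc == 0:
                                continue
                            rr, cc = r + dr, c + dc
                            if 0 <= rr < 16 and 0 <= cc < 16 and skel[rr, cc]:
                                cnt += 1
                    if cnt >= 3:
                        exp_branch.add((r, c))
                    elif cnt == 1:
                        exp_end.add((r, c))
            assert got_branch == exp_branch
            assert got_end == exp_end


class TestPruneGraph:
    def test_y_shape_short_arm_pruned_and_node_dissolved(self):
        skel = np.zeros((32, 32), bool)
        skel[16, 6:17] = True          # left arm to centre (16,16)
        skel[16, 17:27] = True         # right arm
        skel[15, 16] = True            # one-pixel third arm
        g = build_graph(skel, spec=SPEC)
        assert g.n_branch_nodes == 1
        pruned = prune_graph(g, twig_px=2.0)
        assert pruned.n_branch_nodes == 0
        assert len(pruned.segments) == 1
        # merged segment spans the two long arms
        assert pruned.segments[0].length_px >= 18

    def test_graph_without_twigs_unchanged(self):
        g = build_graph(plus_sign(arm=10), spec=SPEC)
        pruned = prune_graph(g, twig_px=2.0)
        assert pruned.n_branch_nodes == g.n_branch_nodes
        assert len(pruned.segments) == len(g.segments)
        assert sum(s.length_px for s in pruned.segments) == pytest.approx(
            sum(s.length_px for s in g.segments)
        )

    def test_isolated_specks_removed(self):
        skel = np.zeros((32, 32), bool)
        skel[5, 5] = True
        skel[20, 20] = True
        pruned = prune_graph(build_graph(skel, spec=SPEC), twig_px=2.0)
        assert not pruned.nodes and not pruned.segments

    def test_pruning_is_monotone(self, rng):
        for _ in range(20):
            mask = rng.uniform(size=(48, 48)) < 0.35
            g = build_graph(skeletonize(mask).skeleton, spec=SPEC)
            p = prune_graph(g, twig_px=2.0)
            assert p.n_branch_nodes <= g.n_branch_nodes
            assert sum(s.length_px for s in p.segments) <= sum(
                s.length_px for s in g.segments
            ) + 1e-9

    def test_exports_edgelist_and_graphml(self, tmp_path):
        import networkx as nx

        g = build_graph(plus_sign(), spec=SPEC)
        df = g.to_edgelist()
        assert list(df.columns)[:4] == ["segment_id", "node_u", "node_v", "length_um"]
        assert len(df) == 4
        nxg = g.to_networkx()
        nx.write_graphml(nxg, tmp_path / "g.graphml")
        assert (tmp_path / "g.graphml").stat().st_size > 0

    def test_iterated_pruning_reaches_fixpoint(self, rng):
        mask = rng.uniform(size=(64, 64)) < 0.4
        g = build_graph(skeletonize(mask).skeleton, spec=SPEC)
        once = prune_graph(g, twig_px=3.0, iterate=True)
        again = prune_graph(once, twig_px=3.0, iterate=True)
        assert len(again.segments) == len(once.segments)
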