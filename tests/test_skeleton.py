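"""Skeletonization, graph construction, and junction/branch censuses."""

import numpy as np
import pytest
from scipy import ndimage
from skimage.measure import euler_number
from skimage.morphology import disk

from conftest import random_thinned_patterns
from ensquant.preprocess import ImageStack
from ensquant.skeleton import (
    branch_stats,
    build_graph,
    contract_short_branches,
    drop_small_components,
    erode,
    junction_census,
    prune_spurs,
    ridge_detect_3d,
    skeletonize_2d,
)
from oracles import brute_force_census


def plus_shape(arm=5):
    n = 2 * arm + 1
    m = np.zeros((n, n), bool)
    m[arm, :] = True
    m[:, arm] = True
    return m


class TestErode:
    def test_zero_iterations_identity(self):
        m = np.random.default_rng(0).random((9, 9)) < 0.5
        np.testing.assert_array_equal(erode(m, 0), m)

    def test_solid_square_one_erosion_matches_oracle(self):
        m = np.zeros((9, 9), bool)
        m[2:7, 2:7] = True
        got = erode(m, 1)
        cross = ndimage.generate_binary_structure(2, 1)
        expected = ndimage.binary_erosion(m, structure=cross)
        np.testing.assert_array_equal(got, expected)
        assert got.sum() < m.sum()

    def test_thin_line_vanishes(self):
        m = np.zeros((5, 9), bool)
        m[2, 1:8] = True
        assert erode(m, 1).sum() == 0

    def test_monotone_shrinking(self):
        m = disk(6).astype(bool)
        prev = m
        for it in range(1, 4):
            cur = erode(m, it)
            assert (cur <= prev).all()
            prev = cur


class TestSkeletonize:
    def test_thick_bar_thins_to_line(self):
        m = np.zeros((9, 20), bool)
        m[3:6, 2:18] = True
        sk = skeletonize_2d(m)
        # a single 1-px-wide path: every row of the skeleton has <= 1 pixel per column
        assert sk.sum() <= 16
        g = build_graph(sk)
        assert junction_census(g).total == 0
        assert branch_stats(g).n_branches == 1

    def test_disc_preserves_euler_number(self):
        m = disk(10).astype(bool)
        sk = skeletonize_2d(m)
        assert euler_number(sk, connectivity=2) == euler_number(m, connectivity=2)

    def test_empty_in_empty_out(self):
        assert skeletonize_2d(np.zeros((8, 8), bool)).sum() == 0

    def test_idempotent(self):
        m = disk(9).astype(bool)
        sk = skeletonize_2d(m)
        np.testing.assert_array_equal(skeletonize_2d(sk), sk)


class TestBuildGraph:
    def test_plus_shape_one_quadruple(self):
        g = build_graph(plus_shape(5))
        c = junction_census(g)
        assert (c.total, c.n_triple, c.n_quadruple) == (1, 0, 1)
        b = branch_stats(g)
        assert b.n_branches == 4
        # the four arm pixels adjacent to the centre merge into the junction
        # cluster (8-connectivity), leaving 4-px arms
        lengths = sorted(e.length_px for e in g.edges)
        assert lengths == [4.0] * 4

    def test_t_shape_one_triple(self):
        m = np.zeros((9, 9), bool)
        m[0, :] = True
        m[:, 4] = True
        g = build_graph(m)
        assert junction_census(g) == (1, 1, 0, 0)
        assert branch_stats(g).n_branches == 3

    def test_straight_line_single_branch(self):
        m = np.zeros((3, 12), bool)
        m[1, 1:11] = True
        b = branch_stats(build_graph(m))
        assert b == (1, 9.0, 9.0)

    def test_two_disjoint_ts(self):
        m = np.zeros((9, 20), bool)
        m[0, 0:9] = True
        m[:, 4] = True
        m[0, 11:20] = True
        m[:, 15] = True
        c = junction_census(build_graph(m))
        assert (c.total, c.n_triple, c.n_quadruple) == (2, 2, 0)

    def test_diagonal_step_metric(self):
        m = np.eye(6, dtype=bool)
        b = branch_stats(build_graph(m))
        assert b.total_length_px == pytest.approx(5 * np.sqrt(2))

    def test_non_thinned_input_rejected(self):
        m = np.zeros((8, 8), bool)
        m[2:6, 2:6] = True
        with pytest.raises(ValueError, match="thinned"):
            build_graph(m)

    def test_graph_covers_all_skeleton_pixels(self):
        for sk in random_thinned_patterns(50, size=8, seed=1):
            g = build_graph(sk, check=False)
            assert g.node_pixel_count() + g.edge_pixel_count() == sk.sum()

    def test_handshake_lemma(self):
        for sk in random_thinned_patterns(50, size=8, seed=2):
            g = build_graph(sk, check=False)
            assert sum(n.degree for n in g.nodes.values()) == 2 * len(g.edges)

    def test_matches_brute_force_oracle_on_random_patterns(self):
        for sk in random_thinned_patterns(300, size=6, seed=3):
            g = build_graph(sk, check=False)
            c = junction_census(g)
            b = branch_stats(g)
            oracle = brute_force_census(sk)
            got = {
                "n_triple": c.n_triple,
                "n_quadruple": c.n_quadruple,
                "n_higher": c.n_higher,
                "n_junctions": c.total,
                "n_branches": b.n_branches,
            }
            assert got == oracle, f"mismatch on pattern\n{sk.astype(int)}"


class TestGraphRewrites:
    def test_contract_merges_split_quadruple(self):
        # two triples joined by a 1-step stub == one thick crossing
        m = np.zeros((9, 9), bool)
        m[4, 0:4] = True   # left arm into (4,3)
        m[0:4, 4] = True   # up arm into (3,4)
        m[4, 5:9] = True   # right arm from (4,5)
        m[5:9, 4] = True   # down arm from (5,4)
        m[4, 4] = False
        m[3, 4] = True
        m[4, 3] = True
        m[3, 3] = True  # junction pixel pair
        m[5, 5] = True
        g = build_graph(m, check=False)
        merged = contract_short_branches(g, max_length=2.0)
        c = junction_census(merged)
        assert c.total <= junction_census(g).total

    def test_prune_spurs_removes_short_twig(self):
        # long horizontal line with a 3-px vertical twig: one triple junction
        m = np.zeros((8, 15), bool)
        m[0, :] = True
        m[1:4, 7] = True
        g = build_graph(m, check=False)
        assert junction_census(g).total == 1
        pruned = prune_spurs(g, min_length=4.0)
        c = junction_census(pruned)
        assert c.total == 0
        # the two half-lines merge back into a single through-branch
        assert branch_stats(pruned).n_branches == 1

    def test_drop_small_components(self):
        m = np.zeros((20, 20), bool)
        m[2, 2:15] = True  # long line, length 12
        m[10, 3:6] = True  # 3-px speck, length 2
        g = build_graph(m, check=False)
        filtered = drop_small_components(g, min_total_length=5.0)
        assert branch_stats(filtered).n_branches == 1
        assert branch_stats(filtered).total_length_px == 12.0


class TestRidge3D:
    def test_straight_tube_centerline_recovered(self):
        from scipy.ndimage import gaussian_filter

        vol = np.zeros((21, 64, 64))
        vol[10, 32, 8:56] = 1.0
        vol = gaussian_filter(vol, (1.5, 2.0, 2.0)) * 100
        sk3 = ridge_detect_3d(ImageStack(vol), sigma=2.0)
        inner = np.argwhere(sk3)
        inner = inner[(inner[:, 2] > 12) & (inner[:, 2] < 52)]
        dev = np.sqrt((inner[:, 0] - 10.0) ** 2 + (inner[:, 1] - 32.0) ** 2)
        assert len(inner) > 20
        assert dev.mean() <= 1.0

    def test_z_separated_crossing_has_no_3d_junction(self):
        from scipy.ndimage import gaussian_filter

        from ensquant.segment import auto_threshold

        vol = np.zeros((21, 64, 64))
        vol[6, 32, 4:60] = 1.0
        vol[14, 4:60, 32] = 1.0
        vol = gaussian_filter(vol, (1.2, 1.5, 1.5)) * 1000
        sk3 = ridge_detect_3d(ImageStack(vol), sigma=1.5)
        c3 = junction_census(build_graph(sk3, check=False))
        proj_sk = skeletonize_2d(auto_threshold(vol.max(axis=0)))
        c2 = junction_census(build_graph(proj_sk, check=False))
        assert c3.total == 0
        assert c2.total >= 1

    def test_blank_stack_empty_skeleton(self):
        assert ridge_detect_3d(ImageStack(np.zeros((9, 32, 32))), sigma=1.5).sum() == 0

    def test_sigma_too_large_rejected(self):
        with pytest.raises(ValueError, match="too large"):
            ridge_detect_3d(ImageStack(np.zeros((5, 32, 32))), sigma=2.0)
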