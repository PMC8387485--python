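"""Synthetic-scene generator: geometry, determinism, ground-truth consistency."""

import numpy as np
import pytest

from ensquant.simulate import (
    NetworkSpec,
    PlacementError,
    RenderParams,
    SizingError,
    generate_cohort,
    generate_graded_ablation,
    generate_network_graph,
    generate_soma_scene,
    render_stack,
)


def lattice_spec(rows, cols, **kw):
    base = dict(
        ganglion_radius_px=5, jitter_px=0, connective_prob=1.0,
        extra_branch_rate=0.0, fibre_width_px=3,
    )
    base.update(kw)
    return NetworkSpec(grid_rows=rows, grid_cols=cols, **base)


class TestNetworkGraph:
    def test_full_2x2_lattice_is_a_square(self):
        net = generate_network_graph(lattice_spec(2, 2), 0, shape=(5, 128, 128))
        assert net.n_nodes == 4
        assert net.n_edges == 4
        assert sorted(d for _, d in net.graph.degree()) == [2, 2, 2, 2]
        gt = net.census()
        assert (gt.n_triple, gt.n_quadruple) == (0, 0)

    def test_full_3x3_lattice_degrees(self):
        net = generate_network_graph(lattice_spec(3, 3), 0, shape=(5, 200, 200))
        degs = sorted(d for _, d in net.graph.degree())
        assert degs == [2, 2, 2, 2, 3, 3, 3, 3, 4]
        gt = net.census()
        assert (gt.n_triple, gt.n_quadruple) == (4, 1)
        assert gt.n_branches == 8  # corner way-points dissolve into through-branches

    def test_branch_count_matches_emitted_edge_list(self):
        spec = lattice_spec(3, 3, extra_branch_rate=2.0, jitter_px=2)
        net = generate_network_graph(spec, 7, shape=(7, 220, 220))
        # brute-force enumeration of the emitted edges
        assert net.n_edges == len(list(net.graph.edges()))
        assert net.n_edges == len(net.polylines())
        # sprouting adds 2 edges per degree-3 way-point (split + sprout)
        n_sprouts = sum(1 for _, d in net.graph.nodes(data=True) if d["kind"] == "sprout")
        assert net.n_edges == 12 + 2 * n_sprouts

    def test_census_consistency_with_degrees(self, small_spec, small_render):
        net = generate_network_graph(small_spec, 3, small_render.shape)
        gt = net.census()
        assert gt.n_junctions == gt.n_triple + gt.n_quadruple + gt.n_higher
        assert gt.n_nodes == net.graph.number_of_nodes()

    def test_deterministic_for_fixed_seed(self, small_spec, small_render):
        a = generate_network_graph(small_spec, 11, small_render.shape)
        b = generate_network_graph(small_spec, 11, small_render.shape)
        assert a.n_edges == b.n_edges
        for pa, pb in zip(a.polylines(), b.polylines()):
            np.testing.assert_array_equal(pa, pb)

    def test_lattice_too_large_raises(self):
        with pytest.raises(SizingError):
            generate_network_graph(lattice_spec(8, 8, ganglion_radius_px=10), 0,
                                   shape=(5, 64, 64))

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            NetworkSpec(grid_rows=1)
        with pytest.raises(ValueError):
            NetworkSpec(connective_prob=1.5)
        with pytest.raises(ValueError):
            NetworkSpec(fibre_width_px=0)


class TestRenderStack:
    def test_noiseless_render_equals_support(self, noiseless_render):
        net = generate_network_graph(lattice_spec(3, 3), 1, noiseless_render.shape)
        stack, gt = render_stack(net, noiseless_render, 1)
        np.testing.assert_array_equal(stack.voxels > 0, gt.true_mask)
        assert stack.voxels[gt.true_mask].min() == stack.voxels.max() == 1.0

    def test_same_graph_two_seeds_share_truth(self, small_spec, small_render):
        net = generate_network_graph(small_spec, 5, small_render.shape)
        s1, g1 = render_stack(net, small_render, 100)
        s2, g2 = render_stack(net, small_render, 101)
        np.testing.assert_array_equal(g1.true_mask, g2.true_mask)
        assert not np.array_equal(s1.voxels, s2.voxels)

    def test_bit_identical_for_same_seed(self, small_spec, small_render):
        net = generate_network_graph(small_spec, 5, small_render.shape)
        s1, _ = render_stack(net, small_render, 42)
        s2, _ = render_stack(net, small_render, 42)
        np.testing.assert_array_equal(s1.voxels, s2.voxels)

    def test_signal_above_background_at_default_snr(self, small_spec, small_render):
        net = generate_network_graph(small_spec, 2, small_render.shape)
        stack, gt = render_stack(net, small_render, 2)
        assert stack.voxels[gt.true_mask].mean() > 3 * stack.voxels[~gt.true_mask].mean()

    def test_density_truth_recomputable_by_counting(self, small_spec, small_render):
        net = generate_network_graph(small_spec, 9, small_render.shape)
        _, gt = render_stack(net, small_render, 9)
        proj = gt.true_mask.any(axis=0)
        assert gt.true_density_fraction == proj.sum() / proj.size
        assert 0.0 <= gt.true_density_fraction <= 1.0


class TestSomaScene:
    def test_zero_somata_blank_scene(self, small_render):
        stack, gt = generate_soma_scene(0, 6.0, small_render, 0)
        assert gt.true_soma_count == 0
        assert not gt.true_mask.any()

    def test_count_by_construction(self, small_render):
        stack, gt = generate_soma_scene(8, 6.0, small_render, 1)
        assert gt.true_soma_count == 8

    def test_debris_below_size_threshold(self, small_render):
        stack, gt = generate_soma_scene(5, 6.0, small_render, 2, n_debris=10)
        # debris lives outside the soma truth mask and each blob is < 10 um^2
        r_max_px = 1.8
        assert np.pi * (r_max_px * small_render.pixel_size_um) ** 2 < 10.0

    def test_placement_error_when_overfull(self):
        rp = RenderParams(shape=(1, 64, 64))
        with pytest.raises(PlacementError):
            generate_soma_scene(100, 6.0, rp, 0, max_attempts_per_soma=50)


class TestCohort:
    def test_cohort_shape_and_subject_effects(self, small_render):
        recs = generate_cohort(
            NetworkSpec.control_small(), NetworkSpec.control_small(),
            n_subjects=2, fields_per_subject=2, render=small_render, seed=0,
        )
        assert len(recs) == 8  # 2 groups x 2 subjects x 2 fields
        groups = {r.group for r in recs}
        assert groups == {"control", "variant"}

    def test_variant_with_more_branching_has_higher_truth(self, small_render):
        recs = generate_cohort(
            NetworkSpec.control_small(), NetworkSpec.variant_small(),
            n_subjects=3, fields_per_subject=2, render=small_render, seed=4,
        )
        ctrl = np.mean([r.truth.n_branches for r in recs if r.group == "control"])
        var = np.mean([r.truth.n_branches for r in recs if r.group == "variant"])
        assert var > ctrl

    def test_rejects_single_subject(self, small_render):
        with pytest.raises(ValueError):
            generate_cohort(NetworkSpec.control_small(), NetworkSpec.control_small(),
                            1, 5, small_render, 0)


class TestGradedAblation:
    def test_full_retention_identical_to_base(self, small_spec, small_render):
        scenes = generate_graded_ablation(small_spec, [1.0], small_render, 3)
        net = generate_network_graph(small_spec, 3, small_render.shape)
        full, gt_full = scenes[0]
        gt_base = net.census()
        assert gt_full.n_branches == gt_base.n_branches
        assert gt_full.n_junctions == gt_base.n_junctions

    def test_zero_retention_leaves_only_ganglia(self, small_spec, small_render):
        scenes = generate_graded_ablation(small_spec, [0.0], small_render, 3)
        _, gt = scenes[0]
        assert gt.n_branches == 0
        assert gt.true_density_fraction > 0  # ganglion blobs remain

    def test_truth_monotone_in_expectation(self, small_spec, small_render):
        means = np.zeros(3)
        for seed in range(10):
            scenes = generate_graded_ablation(
                small_spec, [1.0, 0.5, 0.1], small_render, seed
            )
            means += [gt.n_junctions for _, gt in scenes]
        assert means[0] > means[1] > means[2]

    def test_increasing_fractions_rejected(self, small_spec, small_render):
        with pytest.raises(ValueError):
            generate_graded_ablation(small_spec, [0.5, 1.0], small_render, 0)
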