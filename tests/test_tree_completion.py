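"""Volume filling, Horsfield ordering and stochastic diameter assignment."""

import numpy as np
import pytest

from pulmoflow import (
    ConstrictionStats,
    FillParams,
    LobeSeed,
    assign_horsfield_orders,
    assign_unresolved_diameters,
    fill_lobe,
    healthy_diameter_from_order,
)
from pulmoflow.tree import AirwayTree, Branch

from .conftest import build_symmetric_tree


def single_branch_tree(lobe="LUL", diameter=6.0, generation=2):
    tree = AirwayTree(volume_state="TLC")
    tree.add_node(0, (0.0, 0.0, 0.0))
    tree.add_node(1, (0.0, 0.0, -30.0))
    tree.add_branch(Branch(id=0, parent=None, prox_node=0, dist_node=1,
                           lobe=lobe, generation=generation, order=None,
                           diameter_mm=diameter, length_mm=30.0, resolved=True))
    return tree


def seed_for(points, lobe="LUL"):
    return LobeSeed(lobe=lobe, points=np.asarray(points, dtype=float),
                    volume_tlc_L=1.0, volume_frc_L=0.5)


class TestFillLobe:
    def test_nearby_points_terminate_immediately(self):
        tree = single_branch_tree()
        # both halves give candidate lengths 0.4 * |offset| < 1.2 mm
        pts = [(0.5, 0.0, -30.5), (-0.5, 0.0, -30.5), (0.0, 0.5, -31.0)]
        added = fill_lobe(tree, seed_for(pts), FillParams(), attachment_id=0)
        assert added == []

    def test_two_separated_points_give_two_children(self):
        tree = single_branch_tree()
        pts = [(-25.0, 0.0, -55.0), (25.0, 0.0, -55.0)]
        added = fill_lobe(tree, seed_for(pts), FillParams(point_threshold=1),
                          attachment_id=0)
        assert len(added) == 2
        # each child heads toward one cluster, scaled by the branching fraction
        tips = sorted(tuple(tree.nodes[tree.branches[b].dist_node]) for b in added)
        expect = sorted([(0.4 * -25.0, 0.0, -30.0 + 0.4 * -25.0),
                         (0.4 * 25.0, 0.0, -30.0 + 0.4 * -25.0)])
        for got, want in zip(tips, expect):
            assert got == pytest.approx(want)

    def test_terminal_count_bounded_by_point_count(self):
        rng = np.random.default_rng(0)
        tree = single_branch_tree()
        pts = rng.uniform(-40, 40, size=(256, 3)) + np.array([0, 0, -80.0])
        fill_lobe(tree, seed_for(pts), FillParams(point_threshold=1,
                                                  length_limit_mm=0.1),
                  attachment_id=0)
        terminals = tree.terminal_ids()
        assert 1 <= len(terminals) <= 256
        assert len(tree.branches) <= 2 * 256  # binary-tree counting bound

    def test_growth_is_deterministic(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(-30, 30, size=(64, 3)) + np.array([0, 0, -70.0])
        trees = []
        for _ in range(2):
            tree = single_branch_tree()
            fill_lobe(tree, seed_for(pts.copy()), FillParams(), attachment_id=0)
            trees.append(tree)
        a, b = trees
        assert set(a.branches) == set(b.branches)
        for bid in a.branches:
            assert a.branches[bid].length_mm == b.branches[bid].length_mm

    def test_doubling_point_threshold_never_adds_terminals(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(-35, 35, size=(128, 3)) + np.array([0, 0, -75.0])
        counts = []
        for thr in (1, 2, 4, 8):
            tree = single_branch_tree()
            fill_lobe(tree, seed_for(pts.copy()),
                      FillParams(point_threshold=thr), attachment_id=0)
            counts.append(len(tree.terminal_ids()))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_empty_and_degenerate_point_sets_rejected(self):
        tree = single_branch_tree()
        with pytest.raises(ValueError):
            fill_lobe(tree, seed_for(np.zeros((0, 3))), attachment_id=0)
        with pytest.raises(ValueError, match="coincide|degenerate|2 points"):
            fill_lobe(tree, seed_for([(1.0, 2.0, 3.0)] * 5), attachment_id=0)

    def test_grown_branches_are_unresolved_with_incremented_generation(self):
        tree = single_branch_tree()
        pts = [(-25.0, 0.0, -55.0), (25.0, 0.0, -55.0)]
        added = fill_lobe(tree, seed_for(pts), attachment_id=0)
        for bid in added:
            b = tree.branches[bid]
            assert not b.resolved
            assert b.generation == tree.branches[b.parent].generation + 1


class TestHorsfieldOrders:
    def test_single_branch_is_order_one(self):
        tree = single_branch_tree()
        assign_horsfield_orders(tree)
        assert tree.branches[0].order == 1

    def test_root_with_two_terminals_is_order_two(self):
        tree = build_symmetric_tree(levels=2)
        assign_horsfield_orders(tree)
        assert all(tree.branches[t].order == 1 for t in tree.terminal_ids())
        assert tree.root.order == 2

    def test_parent_of_orders_one_and_two_is_three(self):
        tree = build_symmetric_tree(levels=2)
        # extend one child so the root's children have orders {1, 2}
        child = [b for b in tree.branches.values() if b.parent == 0][0]
        for k in range(2):
            nid = tree.next_node_id()
            tree.add_node(nid, tree.nodes[child.dist_node] + np.array([k, 0, -5.0]))
            tree.add_branch(Branch(id=tree.next_branch_id(), parent=child.id,
                                   prox_node=child.dist_node, dist_node=nid,
                                   lobe="LUL", generation=3, order=None,
                                   diameter_mm=1.0, length_mm=5.0, resolved=True))
        assign_horsfield_orders(tree)
        assert tree.root.order == 3


class TestHealthyDiameter:
    def test_anchor_identity(self):
        assert healthy_diameter_from_order(6, 6, 4.5, 1.5) == 4.5

    def test_power_law_worked_example(self):
        assert healthy_diameter_from_order(1, 6, 4.5, 1.5) == \
            pytest.approx(4.5 * 1.5 ** -5, rel=1e-12)
        assert healthy_diameter_from_order(1, 6, 4.5, 1.5) == \
            pytest.approx(0.593, abs=1e-3)

    def test_ratio_near_one_flattens(self):
        assert healthy_diameter_from_order(1, 9, 3.0, 1.0 + 1e-9) == \
            pytest.approx(3.0, rel=1e-6)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            healthy_diameter_from_order(1, 6, -4.5, 1.5)
        with pytest.raises(ValueError):
            healthy_diameter_from_order(1, 6, 4.5, 0.9)


class TestDiameterAssignment:
    def _grown_tree(self, n_points=200, seed=0):
        # a generation-5 segmental attachment: its predicted diameter
        # (~4.8 mm) sits below the measured 5.0 mm so the parent-child cap
        # stays inactive for healthy multipliers <= 1
        rng = np.random.default_rng(seed)
        tree = single_branch_tree(lobe="LLL", diameter=5.0, generation=5)
        pts = rng.uniform(-35, 35, size=(n_points, 3)) + np.array([0, 0, -80.0])
        fill_lobe(tree, seed_for(pts, lobe="LLL"), FillParams(), attachment_id=0)
        assign_horsfield_orders(tree)
        return tree

    def test_degenerate_stats_give_healthy_diameters(self, male_60y, daver_table):
        tree = self._grown_tree()
        stats = ConstrictionStats(state="TLC", mean={"LLL": 1.0}, sd={"LLL": 0.0})
        assign_unresolved_diameters(tree, male_60y, daver_table, stats,
                                    np.random.default_rng(0), ratio=1.4)
        # order-1 terminals all share the anchored power-law value
        anchor = tree.branches[0]
        from pulmoflow import predict_generation_diameter
        pred = predict_generation_diameter(male_60y, "LLL", anchor.generation,
                                           daver_table)
        for tid in tree.terminal_ids():
            b = tree.branches[tid]
            assert b.diameter_mm == pytest.approx(
                pred * 1.4 ** (1 - anchor.order), rel=1e-9)

    def test_uniform_scaling_with_zero_sd(self, male_60y, daver_table):
        ref = self._grown_tree()
        scaled = self._grown_tree()
        one = ConstrictionStats(state="TLC", mean={"LLL": 1.0}, sd={"LLL": 0.0})
        point8 = ConstrictionStats(state="TLC", mean={"LLL": 0.8}, sd={"LLL": 0.0})
        assign_unresolved_diameters(ref, male_60y, daver_table, one,
                                    np.random.default_rng(0), ratio=1.4)
        assign_unresolved_diameters(scaled, male_60y, daver_table, point8,
                                    np.random.default_rng(0), ratio=1.4)
        for bid, b in scaled.branches.items():
            if not b.resolved:
                assert b.diameter_mm == pytest.approx(
                    0.8 * ref.branches[bid].diameter_mm, rel=1e-9)

    def test_monte_carlo_multiplier_mean(self, male_60y, daver_table):
        tree = self._grown_tree(n_points=700, seed=3)
        healthy = self._grown_tree(n_points=700, seed=3)
        stats = ConstrictionStats(state="FRC", mean={"LLL": 0.85}, sd={"LLL": 0.13})
        one = ConstrictionStats(state="FRC", mean={"LLL": 1.0}, sd={"LLL": 0.0})
        assign_unresolved_diameters(tree, male_60y, daver_table, stats,
                                    np.random.default_rng(12), ratio=1.4)
        assign_unresolved_diameters(healthy, male_60y, daver_table, one,
                                    np.random.default_rng(12), ratio=1.4)
        mults = [tree.branches[bid].diameter_mm / healthy.branches[bid].diameter_mm
                 for bid, b in tree.branches.items() if not b.resolved]
        assert len(mults) >= 500
        assert np.mean(mults) == pytest.approx(0.85, abs=0.02)

    def test_child_never_exceeds_parent(self, male_60y, daver_table):
        tree = self._grown_tree(seed=4)
        stats = ConstrictionStats(state="TLC", mean={"LLL": 0.9}, sd={"LLL": 0.2})
        assign_unresolved_diameters(tree, male_60y, daver_table, stats,
                                    np.random.default_rng(1), ratio=1.4)
        for b in tree.branches.values():
            if b.parent is not None:
                assert b.diameter_mm <= tree.branches[b.parent].diameter_mm + 1e-12

    def test_missing_lobe_stats_raise(self, male_60y, daver_table):
        tree = self._grown_tree()
        stats = ConstrictionStats(state="TLC", mean={"RUL": 1.0}, sd={"RUL": 0.0})
        with pytest.raises(KeyError, match="LLL"):
            assign_unresolved_diameters(tree, male_60y, daver_table, stats,
                                        np.random.default_rng(0))

    def test_orders_required_before_assignment(self, male_60y, daver_table):
        tree = single_branch_tree(lobe="LLL")
        pts = [(-25.0, 0.0, -55.0), (25.0, 0.0, -55.0)]
        fill_lobe(tree, seed_for(pts, "LLL"), attachment_id=0)
        stats = ConstrictionStats(state="TLC", mean={"LLL": 1.0}, sd={"LLL": 0.0})
        with pytest.raises(ValueError, match="order"):
            assign_unresolved_diameters(tree, male_60y, daver_table, stats,
                                        np.random.default_rng(0))
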