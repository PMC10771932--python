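"""1D network solver: flow apportionment, resistance physics, pressure decomposition."""

import numpy as np
import pytest

from pulmoflow import (
    BreathConfig,
    SolverConfig,
    branch_pressure_drop,
    distribute_flow,
    pleural_decomposition,
    simulate_breath,
    solve_timestep,
)
from pulmoflow.flow_solver import CMH2O_TO_PA, terminal_weights
from pulmoflow.tree import AirwayTree, Branch

from .conftest import build_symmetric_tree


def single_tube(diameter=2.0, length=20.0):
    tree = AirwayTree()
    tree.add_node(0, (0, 0, 0))
    tree.add_node(1, (0, 0, -length))
    tree.add_branch(Branch(id=0, parent=None, prox_node=0, dist_node=1,
                           lobe="LUL", generation=1, order=1,
                           diameter_mm=diameter, length_mm=length, resolved=True))
    return tree


def three_terminal_tree():
    tree = build_symmetric_tree(levels=2)
    # split one child into two grandchildren -> 3 terminals
    child = [b for b in tree.branches.values() if b.parent == 0][0]
    for k in range(2):
        nid = tree.next_node_id()
        tree.add_node(nid, tree.nodes[child.dist_node] + np.array([k - 0.5, 0, -5.0]))
        tree.add_branch(Branch(id=tree.next_branch_id(), parent=child.id,
                               prox_node=child.dist_node, dist_node=nid,
                               lobe="LUL", generation=3, order=None,
                               diameter_mm=1.5, length_mm=5.0, resolved=True))
    return tree


class TestDistributeFlow:
    def test_symmetric_tree_splits_evenly(self, symmetric_tree):
        w = terminal_weights(symmetric_tree)
        flows = distribute_flow(symmetric_tree, 1.0, w)
        terminals = symmetric_tree.terminal_ids()
        assert all(flows[t] == pytest.approx(1.0 / len(terminals))
                   for t in terminals)

    def test_zero_total_flow_gives_zero_everywhere(self, symmetric_tree):
        w = terminal_weights(symmetric_tree)
        flows = distribute_flow(symmetric_tree, 0.0, w)
        assert all(v == 0.0 for v in flows.values())

    def test_root_flow_is_sum_of_terminal_weights(self):
        tree = three_terminal_tree()
        terminals = tree.terminal_ids()
        weights = dict(zip(terminals, (0.5, 0.3, 0.2)))
        flows = distribute_flow(tree, 1.0, weights)
        assert flows[tree.root.id] == pytest.approx(1.0, abs=1e-12)

    def test_junction_conservation(self):
        tree = three_terminal_tree()
        rng = np.random.default_rng(0)
        raw = rng.random(len(tree.terminal_ids()))
        weights = dict(zip(tree.terminal_ids(), raw / raw.sum()))
        flows = distribute_flow(tree, 0.785, weights)
        kids = tree.child_map()
        for bid, ch in kids.items():
            if ch:
                total = sum(flows[c] for c in ch)
                assert abs(flows[bid] - total) <= 1e-9 * max(abs(flows[bid]), 1e-30)

    def test_unnormalized_weights_rejected(self, symmetric_tree):
        w = {t: 0.4 for t in symmetric_tree.terminal_ids()}
        with pytest.raises(ValueError, match="sum"):
            distribute_flow(symmetric_tree, 1.0, w)


class TestBranchPressureDrop:
    def test_zero_flow_zero_drop(self):
        assert branch_pressure_drop(2.0, 20.0, 0.0, SolverConfig()) == 0.0

    def test_poiseuille_worked_example(self):
        # D=2 mm, L=20 mm, Q=1e-5 m^3/s = 1e-2 L/s
        cfg = SolverConfig(resistance_model="poiseuille")
        dp = branch_pressure_drop(2.0, 20.0, 1e-2, cfg)
        expect = 128 * 1.81e-5 * 0.02 * 1e-5 / (np.pi * 0.002 ** 4)
        assert dp == pytest.approx(expect, rel=1e-12)
        assert dp == pytest.approx(9.218, abs=1e-3)

    def test_pedley_reduces_to_poiseuille_at_low_reynolds(self):
        pois = SolverConfig(resistance_model="poiseuille")
        ped = SolverConfig(resistance_model="pedley")
        # tiny flow in a long narrow tube -> gamma formula < 1 -> clamped to 1
        assert branch_pressure_drop(0.5, 50.0, 1e-6, ped) == \
            branch_pressure_drop(0.5, 50.0, 1e-6, pois)

    def test_pedley_exceeds_poiseuille_at_high_reynolds(self):
        pois = SolverConfig(resistance_model="poiseuille")
        ped = SolverConfig(resistance_model="pedley")
        assert branch_pressure_drop(18.0, 100.0, 0.8, ped) > \
            branch_pressure_drop(18.0, 100.0, 0.8, pois)

    def test_sign_follows_flow(self):
        cfg = SolverConfig()
        assert branch_pressure_drop(2.0, 20.0, 1e-2, cfg) > 0
        assert branch_pressure_drop(2.0, 20.0, -1e-2, cfg) < 0

    def test_hagen_poiseuille_closed_form_across_flow_sweep(self):
        cfg = SolverConfig(resistance_model="poiseuille")
        d_m, l_m = 0.003, 0.05
        resistance = 128 * cfg.viscosity_Pa_s * l_m / (np.pi * d_m ** 4)
        for q_Ls in np.logspace(-4, -1, 10):
            dp = branch_pressure_drop(3.0, 50.0, q_Ls, cfg)
            assert dp == pytest.approx(resistance * q_Ls * 1e-3, rel=5e-3)

    def test_nonpositive_geometry_rejected(self):
        with pytest.raises(ValueError):
            branch_pressure_drop(0.0, 20.0, 1e-2, SolverConfig())


class TestSolveTimestep:
    def test_zero_flow_zero_pressure(self, symmetric_tree):
        flows = {bid: 0.0 for bid in symmetric_tree.branches}
        pressures, p_alv = solve_timestep(symmetric_tree, flows, SolverConfig())
        assert all(v == 0.0 for v in pressures.values())
        assert p_alv == 0.0

    def test_single_tube_sign_convention(self):
        tree = single_tube()
        cfg = SolverConfig(resistance_model="poiseuille")
        pressures, p_alv = solve_timestep(tree, {0: 1e-2}, cfg)
        assert p_alv == pytest.approx(-branch_pressure_drop(2.0, 20.0, 1e-2, cfg))
        assert p_alv < 0

    def test_path_sum_matches_brute_force_enumeration(self):
        tree = three_terminal_tree()
        w = terminal_weights(tree)
        cfg = SolverConfig()
        flows = distribute_flow(tree, 0.5, w)
        pressures, p_alv = solve_timestep(tree, flows, cfg)
        # brute force: independently walk root->terminal summing drops
        totals = []
        for tid in tree.terminal_ids():
            drop = 0.0
            b = tree.branches[tid]
            while b is not None:
                drop += branch_pressure_drop(b.diameter_mm, b.length_mm,
                                             flows[b.id], cfg)
                b = tree.branches[b.parent] if b.parent is not None else None
            totals.append(-drop)
            assert pressures[tree.branches[tid].dist_node] == \
                pytest.approx(-drop, abs=1e-12)
        assert p_alv == pytest.approx(np.mean(totals), abs=1e-12)


class TestPleuralDecomposition:
    def test_unit_conversion_worked_example(self):
        cfg = SolverConfig()
        p_pl, p_tp = pleural_decomposition(0.0, 1.6, cfg)
        assert p_tp == pytest.approx(8 * CMH2O_TO_PA, rel=1e-12)
        assert p_tp == pytest.approx(784.532, abs=1e-3)
        assert p_pl == pytest.approx(-784.532, abs=1e-3)

    def test_identity_holds_exactly(self):
        cfg = SolverConfig()
        for p_alv, vol in [(-53.254, 1.777), (69.56, 1.61), (0.0, 0.0)]:
            p_pl, p_tp = pleural_decomposition(p_alv, vol, cfg)
            assert p_tp == p_alv - p_pl  # exact, not approx


@pytest.fixture
def breathing_tree_pair():
    frc = build_symmetric_tree(levels=4, diameter=6.0)
    frc.volume_state = "FRC"
    tlc = frc.copy()
    tlc.volume_state = "TLC"
    for b in tlc.branches.values():
        b.diameter_mm *= 1.4
        b.length_mm *= 1.15
    return frc, tlc


class TestSimulateBreath:
    def test_pressure_signs_at_peak_phases(self, breathing_tree_pair):
        frc, tlc = breathing_tree_pair
        cfg = BreathConfig(frc_volume_L=2.0, tlc_volume_L=5.0)
        sol = simulate_breath(frc, tlc, cfg, SolverConfig())
        assert sol.summary["P_alv_PI_Pa"] < 0
        assert sol.summary["P_alv_PE_Pa"] > 0

    def test_transpulmonary_identity_at_machine_precision(self, breathing_tree_pair):
        frc, tlc = breathing_tree_pair
        cfg = BreathConfig(frc_volume_L=2.0, tlc_volume_L=5.0)
        sol = simulate_breath(frc, tlc, cfg, SolverConfig())
        assert np.max(np.abs(sol.p_tp - (sol.p_alv - sol.p_pl))) < 1e-9

    def test_halving_diameters_scales_pressure_drop_16x(self, breathing_tree_pair):
        frc, tlc = breathing_tree_pair
        cfg = BreathConfig(frc_volume_L=2.0, tlc_volume_L=5.0)
        solver = SolverConfig(resistance_model="poiseuille")
        base = simulate_breath(frc, tlc, cfg, solver)
        frc2, tlc2 = frc.copy(), tlc.copy()
        for t in (frc2, tlc2):
            for b in t.branches.values():
                b.diameter_mm *= 0.5
        halved = simulate_breath(frc2, tlc2, cfg, solver)
        ratio = halved.summary["P_alv_PI_Pa"] / base.summary["P_alv_PI_Pa"]
        assert ratio == pytest.approx(16.0, rel=1e-9)

    def test_uniform_shrink_increases_pressure_drop(self, breathing_tree_pair):
        frc, tlc = breathing_tree_pair
        cfg = BreathConfig(frc_volume_L=2.0, tlc_volume_L=5.0)
        prev = None
        for s in (1.0, 0.8, 0.6):
            f2, t2 = frc.copy(), tlc.copy()
            for t in (f2, t2):
                for b in t.branches.values():
                    b.diameter_mm *= s
            sol = simulate_breath(f2, t2, cfg, SolverConfig())
            mag = abs(sol.summary["P_alv_PI_Pa"])
            if prev is not None:
                assert mag > prev
            prev = mag

    def test_matches_scalar_reference_path(self, breathing_tree_pair):
        """Vectorized cycle solve equals the per-step scalar operations."""
        from pulmoflow.breathing import breathing_schedule, flow_waveform
        frc, tlc = breathing_tree_pair
        cfg = BreathConfig(frc_volume_L=2.0, tlc_volume_L=5.0, steps_per_cycle=8)
        solver = SolverConfig()
        sol = simulate_breath(frc, tlc, cfg, solver)
        sched = breathing_schedule(frc, tlc, cfg)
        for i in (1, 3, 6):
            t = sol.times[i]
            tree_t = sched.tree_at(t)
            w = terminal_weights(tree_t)
            flows = distribute_flow(tree_t, float(flow_waveform(t, cfg)), w)
            pressures, pa = solve_timestep(tree_t, flows, solver)
            assert sol.p_alv[i] == pytest.approx(pa, rel=1e-12, abs=1e-12)
            got = sol.flows_at(i)
            assert all(got[bid] == pytest.approx(flows[bid], abs=1e-15)
                       for bid in flows)

    def test_workload_is_loop_area(self, breathing_tree_pair):
        frc, tlc = breathing_tree_pair
        cfg = BreathConfig(frc_volume_L=2.0, tlc_volume_L=5.0, steps_per_cycle=200)
        sol = simulate_breath(frc, tlc, cfg, SolverConfig())
        area = abs(np.trapezoid(sol.p_pl, sol.volumes_L)) * 1e-3
        assert sol.workload_J == pytest.approx(area, rel=1e-12)
        assert sol.workload_J > 0
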