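"""Quasi-static 1D airway-network pressure solver.

At each instant of the breathing cycle the inlet flow is apportioned to
the terminal branches (by lobar volume-change share by default), summed
up the tree so that flow is conserved at every junction by construction,
and converted to a pressure field by accumulating viscous branch pressure
drops from the tracheal inlet (gauge reference 0) down every path.  The
branch resistance is Poiseuille, optionally with Pedley's entrance-effect
correction gamma = (c / 4 sqrt(2)) sqrt(Re D / L) bounded below by 1.

Alveolar pressure P_alv is the mean pressure over the distal nodes of the
terminal branches; it is negative during inspiration (a pressure drop
relative to the trachea) and positive during expiration.  Pleural
pressure follows from a fixed global lung compliance C:
P_tp = V_lung / C and P_pl = P_alv - P_tp.  Workload is the area of the
P_pl-volume loop over one cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .breathing import (
    BreathConfig,
    GeometrySchedule,
    breathing_schedule,
    flow_waveform,
    volume_waveform,
)
from .tree import AirwayTree

__all__ = [
    "SolverConfig",
    "PressureSolution",
    "terminal_weights",
    "distribute_flow",
    "branch_pressure_drop",
    "solve_timestep",
    "pleural_decomposition",
    "simulate_breath",
]

CMH2O_TO_PA = 98.0665


@dataclass
class SolverConfig:
    viscosity_Pa_s: float = 1.81e-5
    density_kg_m3: float = 1.20
    compliance_L_per_cmH2O: float = 0.2
    resistance_model: str = "pedley"  # "poiseuille" or "pedley"
    pedley_coefficient: float = 1.85
    #: whole-lung air volume at FRC entering the compliance relation (L)
    frc_air_volume_L: float = 1.28

    def __post_init__(self) -> None:
        for name in ("viscosity_Pa_s", "density_kg_m3", "compliance_L_per_cmH2O",
                     "pedley_coefficient", "frc_air_volume_L"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.resistance_model not in ("poiseuille", "pedley"):
            raise ValueError(f"unknown resistance model {self.resistance_model!r}")


@dataclass
class PressureSolution:
    """Per-step flows/pressures and cycle summaries of one simulated breath."""

    times: np.ndarray
    volumes_L: np.ndarray  # inhaled volume above FRC
    p_alv: np.ndarray  # Pa, relative to trachea
    p_pl: np.ndarray  # Pa
    p_tp: np.ndarray  # Pa
    branch_ids: np.ndarray  # branch id per column of branch_flows
    branch_flows: np.ndarray  # (steps, branches) L/s, positive peripheral
    node_ids: np.ndarray  # node id per column of node_pressures
    node_pressures: np.ndarray  # (steps, nodes) Pa, tracheal inlet = 0
    pi_time: float
    pe_time: float
    workload_J: float
    summary: dict = field(default_factory=dict)

    def at_time(self, t: float) -> int:
        return int(np.argmin(np.abs(self.times - t)))

    def flows_at(self, step: int) -> dict[int, float]:
        return dict(zip(self.branch_ids.tolist(), self.branch_flows[step]))

    def pressures_at(self, step: int) -> dict[int, float]:
        return dict(zip(self.node_ids.tolist(), self.node_pressures[step]))


def terminal_weights(tree: AirwayTree, lobe_volume_change: dict[str, float] | None = None
                     ) -> dict[int, float]:
    """Default per-terminal flow fractions.

    Each lobe receives a share proportional to its air-volume change
    between TLC and FRC (uniform across lobes when not provided), split
    uniformly over the lobe's terminal branches.
    """
    terminals = tree.terminal_ids()
    if not terminals:
        raise ValueError("tree has no terminal branches")
    by_lobe: dict[str, list[int]] = {}
    for tid in terminals:
        by_lobe.setdefault(tree.branches[tid].lobe, []).append(tid)
    if lobe_volume_change is None:
        lobe_volume_change = {lobe: 1.0 for lobe in by_lobe}
    total = sum(lobe_volume_change[lobe] for lobe in by_lobe)
    weights: dict[int, float] = {}
    for lobe, tids in by_lobe.items():
        share = lobe_volume_change[lobe] / total
        for tid in tids:
            weights[tid] = share / len(tids)
    return weights


def distribute_flow(tree: AirwayTree, q_total_Ls: float,
                    weights: dict[int, float]) -> dict[int, float]:
    """Per-branch flow (L/s): terminals get weight * Q, parents sum children.

    Junction conservation holds by construction.
    """
    terminals = set(tree.terminal_ids())
    if set(weights) != terminals:
        raise ValueError("weights must cover exactly the terminal branches")
    wsum = sum(weights.values())
    if abs(wsum - 1.0) > 1e-9:
        raise ValueError(f"terminal weights sum to {wsum}, expected 1 within 1e-9")
    if any(w < 0 for w in weights.values()):
        raise ValueError("terminal weights must be nonnegative")
    flows = {bid: 0.0 for bid in tree.branches}
    kids = tree.child_map()
    for bid in reversed(tree.topological_order()):
        if bid in terminals:
            flows[bid] = weights[bid] * q_total_Ls
        else:
            flows[bid] = sum(flows[c] for c in kids[bid])
    return flows


def branch_pressure_drop(diameter_mm: float, length_mm: float, flow_Ls: float,
                         config: SolverConfig) -> float:
    """Viscous pressure drop (Pa) along one branch; sign follows the flow.

    Poiseuille: dP = 128 mu L Q / (pi D^4) in SI units.  The Pedley model
    multiplies by gamma = max(1, (c / 4 sqrt(2)) sqrt(Re D / L)) with
    Re = 4 rho |Q| / (pi mu D), capturing entrance effects in the central
    airways while reducing to Poiseuille in the small-Re periphery.
    """
    if diameter_mm <= 0 or length_mm <= 0:
        raise ValueError("diameter and length must be positive")
    d = diameter_mm * 1e-3
    ln = length_mm * 1e-3
    q = flow_Ls * 1e-3  # m^3/s
    dp = 128.0 * config.viscosity_Pa_s * ln * q / (np.pi * d ** 4)
    if config.resistance_model == "pedley" and q != 0.0:
        re = 4.0 * config.density_kg_m3 * abs(q) / (np.pi * config.viscosity_Pa_s * d)
        gamma = (config.pedley_coefficient / (4.0 * np.sqrt(2.0))) * np.sqrt(re * d / ln)
        dp *= max(1.0, gamma)
    return float(dp)


def solve_timestep(tree: AirwayTree, flows: dict[int, float],
                   config: SolverConfig) -> tuple[dict[int, float], float]:
    """Node pressures (Pa, trachea inlet = 0) and mean terminal pressure P_alv.

    Pressure at a node is minus the accumulated branch pressure drops along
    the unique path from the tracheal inlet, so inspiratory flow yields
    negative peripheral pressures.
    """
    root = tree.root
    pressures: dict[int, float] = {root.prox_node: 0.0}
    for bid in tree.topological_order():
        b = tree.branches[bid]
        if b.prox_node not in pressures:
            raise ValueError(f"disconnected node {b.prox_node} on branch {bid}")
        dp = branch_pressure_drop(b.diameter_mm, b.length_mm, flows[bid], config)
        pressures[b.dist_node] = pressures[b.prox_node] - dp
    terminal_nodes = [tree.branches[tid].dist_node for tid in tree.terminal_ids()]
    p_alv = float(np.mean([pressures[n] for n in terminal_nodes]))
    return pressures, p_alv


def pleural_decomposition(p_alv_Pa: float, lung_air_volume_L: float,
                          config: SolverConfig) -> tuple[float, float]:
    """(P_pl, P_tp) in Pa from the fixed global compliance.

    P_tp = V / C (converted from cmH2O) is the elastic recoil load and
    P_pl = P_alv - P_tp, so the identity P_tp = P_alv - P_pl is exact.
    """
    if lung_air_volume_L < 0:
        raise ValueError("lung air volume must be nonnegative")
    p_tp = (lung_air_volume_L / config.compliance_L_per_cmH2O) * CMH2O_TO_PA
    return p_alv_Pa - p_tp, p_tp


def simulate_breath(
    tree_frc: AirwayTree,
    tree_tlc: AirwayTree,
    breath: BreathConfig | None = None,
    solver: SolverConfig | None = None,
    lobe_volume_change: dict[str, float] | None = None,
    schedule: GeometrySchedule | None = None,
) -> PressureSolution:
    """Simulate one breathing cycle on the moving completed tree.

    Per step: interpolate geometry, distribute the instantaneous inlet
    flow to terminals, solve the pressure field, and decompose into
    P_alv / P_pl / P_tp.  Reports the three pressures at peak inspiration
    and expiration (peak-flow instants T/4 and 3T/4 by default), the
    workload |closed integral of P_pl dV| per cycle and the P_pl-volume
    hysteresis loop.
    """
    breath = breath or BreathConfig()
    solver = solver or SolverConfig()
    if schedule is None:
        schedule = breathing_schedule(tree_frc, tree_tlc, breath)
    times = schedule.times

    # static topology: precompute per-branch subtended terminal weight so
    # branch flow is weight * Q(t) with junction conservation built in
    topo = tree_frc.topological_order()
    pos = {bid: k for k, bid in enumerate(topo)}
    n = len(topo)
    parent_pos = np.array(
        [-1 if tree_frc.branches[b].parent is None else pos[tree_frc.branches[b].parent]
         for b in topo])
    terminal_set = set(tree_frc.terminal_ids())
    term_mask = np.array([b in terminal_set for b in topo])
    weights = terminal_weights(tree_frc, lobe_volume_change)
    w = np.zeros(n)
    w[term_mask] = [weights[b] for b in topo if b in terminal_set]
    for k in range(n - 1, 0, -1):  # accumulate toward the root
        w[parent_pos[k]] += w[k]
    d_frc = np.array([tree_frc.branches[b].diameter_mm for b in topo]) * 1e-3
    d_tlc = np.array([tree_tlc.branches[b].diameter_mm for b in topo]) * 1e-3
    l_frc = np.array([tree_frc.branches[b].length_mm for b in topo]) * 1e-3
    l_tlc = np.array([tree_tlc.branches[b].length_mm for b in topo]) * 1e-3
    # group branches by depth so path sums vectorize level by level
    depth = np.zeros(n, dtype=int)
    for k in range(1, n):
        depth[k] = depth[parent_pos[k]] + 1
    levels = [np.nonzero(depth == lv)[0] for lv in range(depth.max() + 1)]

    volumes = np.zeros_like(times)
    p_alv = np.zeros_like(times)
    p_pl = np.zeros_like(times)
    p_tp = np.zeros_like(times)
    branch_flows = np.zeros((times.size, n))
    cum_drops = np.zeros((times.size, n))
    mu, rho = solver.viscosity_Pa_s, solver.density_kg_m3
    for i, t in enumerate(times):
        lam = schedule.lam_at(t)
        q_total = float(flow_waveform(t, breath))
        d = (1 - lam) * d_frc + lam * d_tlc
        ln = (1 - lam) * l_frc + lam * l_tlc
        q = w * q_total  # L/s
        q_si = q * 1e-3
        dp = 128.0 * mu * ln * q_si / (np.pi * d ** 4)
        if solver.resistance_model == "pedley":
            re = 4.0 * rho * np.abs(q_si) / (np.pi * mu * d)
            gamma = (solver.pedley_coefficient / (4.0 * np.sqrt(2.0))) * np.sqrt(
                re * d / ln)
            dp *= np.maximum(1.0, gamma)
        # cum[b] = cum[parent] + dp[b], level by level from the root
        cum = dp.copy()
        for idx in levels[1:]:
            cum[idx] += cum[parent_pos[idx]]
        pa = float(np.mean(-cum[term_mask]))
        v = float(volume_waveform(t, breath))
        pl, tp = pleural_decomposition(pa, solver.frc_air_volume_L + v, solver)
        volumes[i], p_alv[i], p_pl[i], p_tp[i] = v, pa, pl, tp
        branch_flows[i] = q
        cum_drops[i] = cum

    # node pressures: inlet plus the distal node of every branch
    root = tree_frc.root
    node_ids = np.concatenate([[root.prox_node],
                               [tree_frc.branches[b].dist_node for b in topo]])
    node_pressures = np.hstack([np.zeros((times.size, 1)), -cum_drops])

    if breath.phase_convention == "peak_flow":
        pi_time, pe_time = breath.period_s / 4.0, 3.0 * breath.period_s / 4.0
    else:
        pi_time, pe_time = breath.period_s / 2.0, breath.period_s
    workload = abs(float(np.trapezoid(p_pl, volumes))) * 1e-3  # Pa*L -> J

    sol = PressureSolution(
        times=times, volumes_L=volumes, p_alv=p_alv, p_pl=p_pl, p_tp=p_tp,
        branch_ids=np.array(topo), branch_flows=branch_flows,
        node_ids=node_ids, node_pressures=node_pressures,
        pi_time=pi_time, pe_time=pe_time, workload_J=workload,
    )
    i_pi, i_pe = sol.at_time(pi_time), sol.at_time(pe_time)
    sol.summary = {
        "P_alv_PI_Pa": float(p_alv[i_pi]), "P_alv_PE_Pa": float(p_alv[i_pe]),
        "P_pl_PI_Pa": float(p_pl[i_pi]), "P_pl_PE_Pa": float(p_pl[i_pe]),
        "P_tp_PI_Pa": float(p_tp[i_pi]), "P_tp_PE_Pa": float(p_tp[i_pe]),
        "workload_J": workload,
    }
    return sol
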