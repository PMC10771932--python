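"""Breathing waveform and time-resolved airway geometry.

Ventilation is driven by a sinusoidal tidal waveform (defaults: 1 L tidal
volume, 4 s period).  Geometry is known at two static lung-volume states,
FRC and TLC; intermediate geometry is a one-parameter family in the
inflation fraction lambda = V_above_FRC / (V_TLC - V_FRC), with node
coordinates and branch diameters/lengths interpolated per branch between
the two anchor states.  The lambda(t) time series can optionally be
reconstructed through an Akima spline over the discrete time knots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import Akima1DInterpolator

from .tree import AirwayTree

__all__ = [
    "BreathConfig",
    "GeometrySchedule",
    "volume_waveform",
    "flow_waveform",
    "inflation_fraction",
    "geometry_at",
    "breathing_schedule",
]


@dataclass
class BreathConfig:
    tidal_volume_L: float = 1.0
    period_s: float = 4.0
    steps_per_cycle: int = 40
    frc_volume_L: float = 2.0  # whole-lung air volume at FRC
    tlc_volume_L: float = 5.0
    interp_method: str = "linear"  # "linear" or "akima" for lambda(t)
    #: "peak_flow" reports pressures at t = T/4 and 3T/4; "end_inspiration"
    #: at t = T/2 and T.
    phase_convention: str = "peak_flow"

    def __post_init__(self) -> None:
        if self.tidal_volume_L <= 0:
            raise ValueError("tidal volume must be positive")
        if self.period_s <= 0:
            raise ValueError("breathing period must be positive")
        if not self.frc_volume_L < self.frc_volume_L + self.tidal_volume_L <= self.tlc_volume_L:
            raise ValueError(
                "need FRC < FRC + tidal volume <= TLC "
                f"(FRC={self.frc_volume_L}, Vt={self.tidal_volume_L}, TLC={self.tlc_volume_L})"
            )
        if self.interp_method not in ("linear", "akima"):
            raise ValueError(f"unknown interpolation method {self.interp_method!r}")
        if self.phase_convention not in ("peak_flow", "end_inspiration"):
            raise ValueError(f"unknown phase convention {self.phase_convention!r}")


def volume_waveform(t, config: BreathConfig):
    """Inhaled volume above FRC (L) at time t: (Vt/2)(1 - cos(2 pi t / T)).

    Times outside one cycle wrap modulo the period.
    """
    t = np.mod(np.asarray(t, dtype=float), config.period_s)
    return (config.tidal_volume_L / 2.0) * (1.0 - np.cos(2.0 * np.pi * t / config.period_s))


def flow_waveform(t, config: BreathConfig):
    """Inlet flow dV/dt (L/s): (pi Vt / T) sin(2 pi t / T); positive inspiring."""
    t = np.mod(np.asarray(t, dtype=float), config.period_s)
    return (np.pi * config.tidal_volume_L / config.period_s) * np.sin(
        2.0 * np.pi * t / config.period_s
    )


def inflation_fraction(v_above_frc: float, config: BreathConfig) -> float:
    """Map inhaled volume to the FRC(0) -> TLC(1) geometric axis."""
    span = config.tlc_volume_L - config.frc_volume_L
    if not -1e-12 <= v_above_frc <= span + 1e-12:
        raise ValueError(f"volume {v_above_frc} L outside [0, {span}] L")
    return float(np.clip(v_above_frc / span, 0.0, 1.0))


def geometry_at(tree_frc: AirwayTree, tree_tlc: AirwayTree, lam: float,
                method: str = "linear") -> AirwayTree:
    """Tree at inflation fraction lam: per-branch interpolation FRC -> TLC.

    The two anchor trees must share topology and ids.  lam = 0 returns the
    FRC tree exactly and lam = 1 the TLC tree exactly.  With only two
    anchor states every interpolant through both endpoints is linear in
    lam, so ``method`` is accepted for interface symmetry but does not
    change the geometry.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"inflation fraction {lam} outside [0, 1]")
    for bid in tree_frc.branches:
        if bid not in tree_tlc.branches:
            raise ValueError(f"topology mismatch: branch {bid} missing from TLC tree")
    for bid in tree_tlc.branches:
        if bid not in tree_frc.branches:
            raise ValueError(f"topology mismatch: branch {bid} missing from FRC tree")
    if lam == 0.0:
        return tree_frc.copy()
    if lam == 1.0:
        out = tree_tlc.copy()
        out.volume_state = "TLC"
        return out
    out = tree_frc.copy()
    out.volume_state = "interpolated"
    for nid in out.nodes:
        out.nodes[nid] = (1 - lam) * tree_frc.nodes[nid] + lam * tree_tlc.nodes[nid]
    for bid, b in out.branches.items():
        bf, bt = tree_frc.branches[bid], tree_tlc.branches[bid]
        b.diameter_mm = (1 - lam) * bf.diameter_mm + lam * bt.diameter_mm
        b.length_mm = (1 - lam) * bf.length_mm + lam * bt.length_mm
    return out


@dataclass
class GeometrySchedule:
    """Time grid over one cycle with the inflation fraction and tree factory."""

    times: np.ndarray
    lam: np.ndarray
    tree_frc: AirwayTree
    tree_tlc: AirwayTree
    config: BreathConfig

    def lam_at(self, t: float) -> float:
        if self.config.interp_method == "akima":
            return float(np.clip(self._akima(np.mod(t, self.config.period_s)), 0.0, 1.0))
        return inflation_fraction(float(volume_waveform(t, self.config)), self.config)

    def tree_at(self, t: float) -> AirwayTree:
        return geometry_at(self.tree_frc, self.tree_tlc, self.lam_at(t))

    def __post_init__(self) -> None:
        if self.config.interp_method == "akima":
            # periodic padding so the spline is well-behaved at the cycle ends
            t, y = self.times, self.lam
            T = self.config.period_s
            tt = np.concatenate([t[-3:-1] - T, t, t[1:3] + T])
            yy = np.concatenate([y[-3:-1], y, y[1:3]])
            self._akima = Akima1DInterpolator(tt, yy)


def breathing_schedule(tree_frc: AirwayTree, tree_tlc: AirwayTree,
                       config: BreathConfig) -> GeometrySchedule:
    """Build the periodic schedule of inflation fractions over one cycle."""
    if config.steps_per_cycle < 4:
        raise ValueError("need at least 4 steps per cycle")
    times = np.linspace(0.0, config.period_s, config.steps_per_cycle + 1)
    lam = np.array([
        inflation_fraction(float(volume_waveform(t, config)), config) for t in times
    ])
    lam[-1] = lam[0]  # exact cycle closure
    return GeometrySchedule(times=times, lam=lam, tree_frc=tree_frc,
                            tree_tlc=tree_tlc, config=config)
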