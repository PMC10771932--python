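"""Growth of CT-unresolved airways and stochastic diameter assignment.

CT resolves airways down to roughly 2 mm diameter (segmental level); the
conducting tree continues for several more generations.  This module grows
the missing branches into each lobe by recursive volume filling (binary
bisection of a lobar point cloud), assigns bottom-up Horsfield orders,
gives every grown branch a healthy diameter from a power law in order
anchored at its lobe's attachment branch, and then multiplies each by a
random per-lobe constriction factor ``Dave*`` so the completed tree
inherits the subject's measured lobar constriction statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .reference_model import (
    ConstrictionStats,
    DaverTable,
    Demographics,
    predict_generation_diameter,
    sample_constriction_multiplier,
)
from .tree import AirwayTree, Branch

__all__ = [
    "LobeSeed",
    "FillParams",
    "fill_lobe",
    "assign_horsfield_orders",
    "healthy_diameter_from_order",
    "assign_unresolved_diameters",
    "complete_tree",
]


@dataclass
class LobeSeed:
    """Target geometry for one lobe: a point cloud to fill and air volumes."""

    lobe: str
    points: np.ndarray  # (n, 3) coordinates in mm
    volume_tlc_L: float
    volume_frc_L: float

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 2 or self.points.shape[1] != 3:
            raise ValueError(f"lobe {self.lobe}: need >= 2 points of dimension 3")
        if self.volume_tlc_L <= 0 or self.volume_frc_L <= 0:
            raise ValueError(f"lobe {self.lobe}: volumes must be positive")
        if self.volume_tlc_L <= self.volume_frc_L:
            raise ValueError(f"lobe {self.lobe}: TLC volume must exceed FRC volume")


@dataclass
class FillParams:
    """Volume-filling termination and geometry parameters.

    branching_fraction : child length as a fraction of the distance from
        the parent's distal node to the assigned half-cloud centroid.
    length_limit_mm : candidate branches shorter than this terminate growth.
    point_threshold : halves with fewer points than this stop recursing.
    """

    branching_fraction: float = 0.4
    length_limit_mm: float = 1.2
    point_threshold: int = 1
    #: Horsfield diameter ratio: diameter multiplies by this per unit order.
    #: Used as given when ``terminal_diameter_mm`` is None.
    diameter_ratio: float = 1.4
    #: healthy terminal-bronchiole caliber anchoring the far end of the
    #: power law; when set, the ratio is derived per lobe from the anchor
    #: diameter and depth so terminals land at this scale
    terminal_diameter_mm: float | None = 0.6
    #: placeholder diameter/length floor for degenerate geometry
    min_length_mm: float = 1e-3


def _split_plane_normal(direction: np.ndarray, centroid_offset: np.ndarray,
                        centered_points: np.ndarray) -> np.ndarray:
    """Normal of the plane containing the branch direction and the centroid.

    The bisection plane passes through the point-set centroid and contains
    the parent branch direction; its normal is perpendicular to both the
    direction and the line from the branch tip to the centroid.  When the
    centroid lies on the branch axis (no lateral lever arm) the normal
    falls back to the principal axis of the point spread perpendicular to
    the branch, which still separates laterally spread clusters.
    """
    n = np.cross(direction, centroid_offset)
    norm = np.linalg.norm(n)
    if norm < 1e-9 * max(np.linalg.norm(direction) * np.linalg.norm(centroid_offset), 1.0):
        d = direction / np.linalg.norm(direction)
        perp = centered_points - np.outer(centered_points @ d, d)
        cov = perp.T @ perp
        eigval, eigvec = np.linalg.eigh(cov)
        n = eigvec[:, -1]
        norm = np.linalg.norm(n)
        if eigval[-1] < 1e-12 or norm < 1e-12:
            raise ValueError("degenerate branch direction")
    return n / norm


def fill_lobe(tree: AirwayTree, seed: LobeSeed, params: FillParams | None = None,
              attachment_id: int | None = None) -> list[int]:
    """Grow unresolved branches into a lobe by recursive bisection.

    Starting from the lobe's attachment branch (its most distal resolved
    branch, auto-detected unless given), the assigned point set is split
    by the plane through its centroid containing the branch direction; for
    each half a child branch is appended from the parent's distal node
    toward the half's centroid with length ``branching_fraction`` times
    the distance, and the procedure recurses.  A half with fewer than
    ``point_threshold`` points, or a candidate shorter than
    ``length_limit_mm``, terminates.  Growth is purely binary and fully
    deterministic given the point cloud and parameters.

    Returns the ids of the branches added.
    """
    params = params or FillParams()
    if seed.points.shape[0] == 0:
        raise ValueError("empty point set")
    if np.allclose(seed.points.std(axis=0), 0.0):
        raise ValueError("degenerate point set: all points coincide")
    if attachment_id is None:
        candidates = [b for b in tree.branches.values()
                      if b.resolved and b.lobe == seed.lobe]
        if not candidates:
            raise ValueError(f"no resolved attachment branch for lobe {seed.lobe}")
        # most distal resolved branches: those without resolved children;
        # each receives the seed points nearest its distal node
        resolved_ids = {b.id for b in candidates}
        with_kids = {b.parent for b in candidates if b.parent in resolved_ids}
        attachments = sorted((b for b in candidates if b.id not in with_kids),
                             key=lambda b: b.id)
    else:
        attachments = [tree.branches[attachment_id]]

    added: list[int] = []

    def grow(parent: Branch, points: np.ndarray) -> None:
        if points.shape[0] < max(2, params.point_threshold):
            return
        direction = tree.branch_vector(parent.id)
        tip = tree.nodes[parent.dist_node]
        centroid = points.mean(axis=0)
        offset = centroid - tip
        normal = _split_plane_normal(direction, offset, points - centroid)
        side = (points - centroid) @ normal
        halves = [points[side >= 0], points[side < 0]]
        for half in halves:
            if half.shape[0] < params.point_threshold or half.shape[0] == 0:
                continue
            target = half.mean(axis=0)
            vec = target - tip
            dist = np.linalg.norm(vec)
            length = params.branching_fraction * dist
            if length < params.length_limit_mm:
                continue
            new_node = tree.next_node_id()
            tree.add_node(new_node, tip + params.branching_fraction * vec)
            child = tree.add_branch(Branch(
                id=tree.next_branch_id(),
                parent=parent.id,
                prox_node=parent.dist_node,
                dist_node=new_node,
                lobe=seed.lobe,
                generation=parent.generation + 1,
                order=None,
                diameter_mm=parent.diameter_mm,  # placeholder until assignment
                length_mm=max(length, params.min_length_mm),
                resolved=False,
            ))
            added.append(child.id)
            if half.shape[0] > 1:
                grow(child, half)

    if len(attachments) == 1:
        grow(attachments[0], seed.points)
    else:
        tips = np.stack([tree.nodes[b.dist_node] for b in attachments])
        nearest = np.linalg.norm(
            seed.points[:, None, :] - tips[None, :, :], axis=2).argmin(axis=1)
        for k, attachment in enumerate(attachments):
            subset = seed.points[nearest == k]
            if subset.shape[0] >= max(2, params.point_threshold):
                grow(attachment, subset)
    return added


def assign_horsfield_orders(tree: AirwayTree) -> AirwayTree:
    """Bottom-up Horsfield orders: terminals 1, parent = max(children) + 1."""
    kids = tree.child_map()
    for bid in reversed(tree.topological_order()):
        ch = kids[bid]
        tree.branches[bid].order = (
            1 if not ch else max(tree.branches[c].order for c in ch) + 1
        )
    return tree


def healthy_diameter_from_order(order: int, anchor_order: int,
                                anchor_diameter_mm: float, ratio: float) -> float:
    """Power-law healthy diameter: D(order) = D_anchor * ratio**(order - anchor)."""
    if anchor_diameter_mm <= 0:
        raise ValueError("anchor diameter must be positive")
    if ratio <= 1:
        raise ValueError("Horsfield diameter ratio must exceed 1")
    return anchor_diameter_mm * ratio ** (order - anchor_order)


def assign_unresolved_diameters(
    tree: AirwayTree,
    demographics: Demographics,
    daver_table: DaverTable,
    stats: ConstrictionStats,
    rng: np.random.Generator,
    ratio: float = 1.4,
    terminal_diameter_mm: float | None = None,
    shared_z: dict[int, float] | None = None,
) -> AirwayTree:
    """Assign diameters to grown branches: healthy power law times ``Dave*`` draw.

    Each lobe's power law is anchored at its attachment branch's *predicted*
    healthy diameter (not its measured one), so constriction enters only
    through the stochastic multipliers.  When ``terminal_diameter_mm`` is
    given the diameter ratio is derived per attachment so that order-1
    branches land at that healthy terminal caliber; otherwise the fixed
    ``ratio`` applies.  A per-branch multiplier is drawn from the lobe's
    Normal(mean, SD) of ``Dave*``; ``shared_z`` optionally supplies a
    standard-normal deviate per branch id so draws can be correlated
    across lung-volume states.  Child diameters are capped at the
    parent's to prevent inversions.
    """
    if any(b.order is None for b in tree.branches.values()):
        raise ValueError("Horsfield orders must be assigned first")
    anchors: dict[int, tuple[int, float, float]] = {}

    def anchor_for(branch: Branch) -> tuple[int, float, float]:
        # walk up to the lobe's most distal resolved ancestor
        b = branch
        while not tree.branches[b.parent].resolved:
            b = tree.branches[b.parent]
        attach = tree.branches[b.parent]
        if attach.id not in anchors:
            pred = predict_generation_diameter(
                demographics, attach.lobe, attach.generation, daver_table
            )
            if terminal_diameter_mm is not None and attach.order > 1:
                r = max((pred / terminal_diameter_mm) ** (1.0 / (attach.order - 1)),
                        1.0 + 1e-6)
            else:
                r = ratio
            anchors[attach.id] = (attach.order, pred, r)
        return anchors[attach.id]

    for bid in tree.topological_order():
        b = tree.branches[bid]
        if b.resolved:
            continue
        if b.lobe not in stats.mean:
            raise KeyError(f"no constriction statistics for lobe {b.lobe!r}")
        anchor_order, anchor_diam, anchor_ratio = anchor_for(b)
        healthy = healthy_diameter_from_order(b.order, anchor_order, anchor_diam, anchor_ratio)
        if shared_z is not None and bid in shared_z:
            mean, sd = stats.require(b.lobe)
            mult = mean + sd * shared_z[bid]
            if mult <= 0.05:  # same positivity floor as the sampler
                mult = sample_constriction_multiplier(stats, b.lobe, rng)
        else:
            mult = sample_constriction_multiplier(stats, b.lobe, rng)
        d = healthy * mult
        parent = tree.branches[b.parent]
        b.diameter_mm = min(d, parent.diameter_mm)
    return tree


def complete_tree(
    tree: AirwayTree,
    seeds: list[LobeSeed],
    demographics: Demographics,
    daver_table: DaverTable,
    stats: ConstrictionStats,
    rng: np.random.Generator,
    params: FillParams | None = None,
    shared_z: dict[int, float] | None = None,
) -> AirwayTree:
    """Fill all lobes, order, and assign unresolved diameters in place."""
    params = params or FillParams()
    for seed in seeds:
        fill_lobe(tree, seed, params)
    assign_horsfield_orders(tree)
    assign_unresolved_diameters(
        tree, demographics, daver_table, stats, rng,
        ratio=params.diameter_ratio,
        terminal_diameter_mm=params.terminal_diameter_mm,
        shared_z=shared_z,
    )
    tree.validate()
    return tree
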