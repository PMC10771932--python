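"""Synthetic two-group cohort generator.

Builds complete synthetic subjects — demographics, CT-resolved airway
trees at TLC and FRC, lobar target volumes and point clouds, registered
inspiratory/expiratory density samples, central/segmental structural
measurements and lung-function values — for an asthma cohort without
(group A) and with (group B) fixed airway obstruction.  Default group
distributions carry the published group means/SDs for demographics,
lobar constriction indices, parametric-response-map percentages,
normalized central-airway structure and spirometry, so a generated
cohort has the statistical structure the downstream analysis assumes
while containing no patient data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .qct import CENTRAL_REGIONS, PRMThresholds, SUBGROUP_SEGMENTS
from .reference_model import (
    LOBES,
    DaverTable,
    Demographics,
    predict_generation_diameter,
    predict_trachea_diameter,
)
from .tree import AirwayTree, Branch
from .tree_completion import LobeSeed

__all__ = [
    "CohortParams",
    "SubjectRecord",
    "generate_subject",
    "generate_cohort",
    "qc_filter",
    "solve_mixture_weights",
    "build_resolved_template",
]

# ---------------------------------------------------------------------------
# Default group-level distributions (mean, SD), group A = without FAO,
# group B = with FAO.
# ---------------------------------------------------------------------------

#: lobar constriction index Dave* at FRC, per group
DAVE_STAR_FRC = {
    "A": {"LUL": (0.918, 0.107), "LLL": (0.927, 0.110), "RUL": (0.864, 0.147),
          "RML": (0.873, 0.139), "RLL": (0.876, 0.140)},
    "B": {"LUL": (0.969, 0.101), "LLL": (0.836, 0.123), "RUL": (0.809, 0.143),
          "RML": (0.864, 0.137), "RLL": (0.881, 0.158)},
}

#: parametric-response-map targets (percent) per lobe, (Emph%, fSAD%)
PRM_TARGETS = {
    "A": {"LUL": (0.192, 5.613), "LLL": (0.222, 3.228), "RUL": (0.084, 4.708),
          "RML": (0.397, 12.356), "RLL": (0.176, 3.316)},
    "B": {"LUL": (0.631, 17.236), "LLL": (1.951, 16.373), "RUL": (0.792, 14.129),
          "RML": (1.266, 26.318), "RLL": (1.126, 9.097)},
}

#: SDs of per-subject lobar PRM targets, (Emph%, fSAD%)
PRM_TARGET_SD = {
    "A": {"LUL": (0.219, 6.676), "LLL": (0.350, 6.350), "RUL": (0.101, 6.135),
          "RML": (0.445, 9.659), "RLL": (0.221, 5.033)},
    "B": {"LUL": (1.103, 11.241), "LLL": (3.158, 18.437), "RUL": (2.067, 12.925),
          "RML": (2.404, 14.621), "RLL": (1.731, 6.254)},
}

#: normalized hydraulic diameter Dh* of the six central regions, per group
CENTRAL_DH_STAR = {
    "A": {"Trachea": (1.035, 0.117), "RMB": (0.833, 0.094), "BronInt": (0.624, 0.066),
          "TriRLL": (0.423, 0.066), "LMB": (0.662, 0.073), "TriLLB": (0.467, 0.051)},
    "B": {"Trachea": (1.191, 0.160), "RMB": (0.926, 0.079), "BronInt": (0.691, 0.056),
          "TriRLL": (0.447, 0.055), "LMB": (0.755, 0.108), "TriLLB": (0.497, 0.059)},
}

#: normalized wall thickness WT* for all 11 regions, per group
WT_STAR = {
    "A": {"Trachea": (0.996, 0.120), "RMB": (0.891, 0.188), "BronInt": (0.676, 0.064),
          "TriRLL": (0.611, 0.041), "LMB": (0.710, 0.115), "TriLLB": (0.640, 0.051),
          "sRUL": (0.595, 0.033), "sRML": (0.570, 0.069), "sRLL": (0.573, 0.038),
          "sLUL": (0.535, 0.037), "sLLL": (0.589, 0.041)},
    "B": {"Trachea": (1.061, 0.097), "RMB": (1.042, 0.095), "BronInt": (0.712, 0.077),
          "TriRLL": (0.671, 0.075), "LMB": (0.845, 0.193), "TriLLB": (0.704, 0.060),
          "sRUL": (0.645, 0.075), "sRML": (0.632, 0.059), "sRLL": (0.606, 0.057),
          "sLUL": (0.578, 0.054), "sLLL": (0.642, 0.069)},
}

#: spirometry distributions per group (percent predicted, or percent ratio)
PFT_DISTRIBUTIONS = {
    "A": {"BMI": (25.219, 4.888),
          "FEV1_pre": (101.125, 18.755), "FVC_pre": (95.792, 13.584),
          "FEV1_FVC_pre": (75.833, 5.113), "FEV1_post": (102.913, 17.962),
          "FVC_post": (96.087, 12.986), "FEV1_FVC_post": (77.130, 4.404)},
    "B": {"BMI": (24.382, 3.819),
          "FEV1_pre": (76.917, 20.025), "FVC_pre": (87.417, 16.638),
          "FEV1_FVC_pre": (61.250, 8.476), "FEV1_post": (81.083, 21.284),
          "FVC_post": (91.500, 18.158), "FEV1_FVC_post": (61.750, 7.461)},
}

#: fraction of total lung air volume per lobe
LOBE_VOLUME_FRACTION = {"LUL": 0.22, "LLL": 0.20, "RUL": 0.20, "RML": 0.08, "RLL": 0.30}

#: HU mixture components (mean, SD) for (inspiratory, expiratory) density
HU_COMPONENTS = {
    "Emph": ((-980.0, 15.0), (-940.0, 25.0)),
    "fSAD": ((-880.0, 20.0), (-880.0, 20.0)),
    "Normal": ((-840.0, 30.0), (-720.0, 40.0)),
}

HU_RANGE = (-1024.0, 200.0)

_SEGMENT_LOBE = {seg: sub[1:] for sub, segs in SUBGROUP_SEGMENTS.items() for seg in segs}


@dataclass
class CohortParams:
    """Generator conditions for both groups; defaults carry the published values."""

    n_a: int = 24
    n_b: int = 12
    male_fraction: dict = field(default_factory=lambda: {"A": 4 / 24, "B": 8 / 12})
    age: dict = field(default_factory=lambda: {"A": (62.583, 11.100), "B": (63.667, 13.089)})
    height_male: tuple = (1.70, 0.06)
    height_female: tuple = (1.57, 0.055)
    dave_star_frc: dict = field(default_factory=lambda: {g: dict(v) for g, v in DAVE_STAR_FRC.items()})
    #: TLC Dave* means = FRC means + tlc_inflation_offset (minus the
    #: group-B decrement), reflecting the inspiratory-CT reference
    tlc_inflation_offset: float = 0.15
    group_b_tlc_decrement: float = 0.05
    prm_targets: dict = field(default_factory=lambda: {g: dict(v) for g, v in PRM_TARGETS.items()})
    prm_target_sd: dict = field(default_factory=lambda: {g: dict(v) for g, v in PRM_TARGET_SD.items()})
    central_dh_star: dict = field(default_factory=lambda: {g: dict(v) for g, v in CENTRAL_DH_STAR.items()})
    wt_star: dict = field(default_factory=lambda: {g: dict(v) for g, v in WT_STAR.items()})
    pft: dict = field(default_factory=lambda: {g: dict(v) for g, v in PFT_DISTRIBUTIONS.items()})
    wt_reference_mm: float = 1.5
    #: whole-lung air volumes (L): FRC calibrated so transpulmonary
    #: pressure magnitudes land near the published group means
    frc_air_volume: dict = field(default_factory=lambda: {"A": (1.28, 0.35), "B": (1.82, 0.45)})
    tlc_air_volume: dict = field(default_factory=lambda: {"A": (4.6, 0.7), "B": (4.9, 0.8)})
    voxels_per_lobe: int = 2000
    #: seed points per lobe for volume filling; ~3800 terminals over the
    #: lung, a desk-scale stand-in for the ~30k terminal bronchioles that
    #: keeps the peripheral pressure drop on a physiological footing
    points_per_lobe: int = 768
    thresholds: PRMThresholds = field(default_factory=PRMThresholds)
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_a < 2 or self.n_b < 2:
            raise ValueError("each group needs n >= 2")
        for group in ("A", "B"):
            for lobe, (emph, fsad) in self.prm_targets[group].items():
                if emph < 0 or fsad < 0 or emph + fsad > 100:
                    raise ValueError(
                        f"infeasible PRM targets for {group}/{lobe}: "
                        f"Emph {emph}% + fSAD {fsad}% must fit in [0, 100]"
                    )

    def tlc_dave_star(self, group: str) -> dict[str, tuple[float, float]]:
        dec = self.group_b_tlc_decrement if group == "B" else 0.0
        return {
            lobe: (mean + self.tlc_inflation_offset - dec, sd)
            for lobe, (mean, sd) in self.dave_star_frc[group].items()
        }


@dataclass
class SubjectRecord:
    subject_id: str
    group: str
    demographics: Demographics
    tree_tlc: AirwayTree
    tree_frc: AirwayTree
    seeds: list  # LobeSeed per lobe
    densities: pd.DataFrame  # insp_hu, exp_hu, lobe
    structure: pd.DataFrame  # region, dh_mm, wt_mm (11 regions + segments)
    pft: dict
    inspiratory_volume_L: float
    expiratory_volume_L: float

    @property
    def lobe_volume_change_L(self) -> dict[str, float]:
        return {s.lobe: s.volume_tlc_L - s.volume_frc_L for s in self.seeds}


# ---------------------------------------------------------------------------
# Resolved-tree template
# ---------------------------------------------------------------------------

# (name, parent name, tip coordinates in mm at TLC, lobe, region label)
_TEMPLATE = [
    ("trachea", None, (0, 0, -100), "central", "Trachea"),
    ("RMB", "trachea", (45, 0, -125), "central", "RMB"),
    ("LMB", "trachea", (-50, 0, -130), "central", "LMB"),
    ("RULb", "RMB", (70, 10, -105), "RUL", None),
    ("BronInt", "RMB", (55, -5, -160), "central", "BronInt"),
    ("LULb", "LMB", (-70, 5, -110), "LUL", None),
    ("TriLLB", "LMB", (-60, -5, -165), "central", "TriLLB"),
    ("RB1", "RULb", (80, 15, -80), "RUL", "RB1"),
    ("RB2", "RULb", (95, 5, -100), "RUL", "RB2"),
    ("RB3", "RULb", (90, 20, -115), "RUL", "RB3"),
    ("RMLb", "BronInt", (75, 25, -185), "RML", None),
    ("TriRLL", "BronInt", (60, -10, -195), "central", "TriRLL"),
    ("RB4", "RMLb", (95, 40, -195), "RML", "RB4"),
    ("RB5", "RMLb", (85, 30, -210), "RML", "RB5"),
    ("RB6", "TriRLL", (75, -25, -205), "RLL", "RB6"),
    ("RB8", "TriRLL", (80, 0, -225), "RLL", "RB8"),
    ("RB9", "TriRLL", (65, -15, -235), "RLL", "RB9"),
    ("RB10", "TriRLL", (55, -5, -245), "RLL", "RB10"),
    ("LB1", "LULb", (-80, 15, -85), "LUL", "LB1"),
    ("LB2", "LULb", (-95, 5, -100), "LUL", "LB2"),
    ("LB3", "LULb", (-90, 20, -115), "LUL", "LB3"),
    ("LB4", "LULb", (-100, 25, -135), "LUL", "LB4"),
    ("LB5", "LULb", (-85, 30, -150), "LUL", "LB5"),
    ("LB6", "TriLLB", (-75, -20, -185), "LLL", "LB6"),
    ("LB7", "TriLLB", (-90, 10, -195), "LLL", "LB7"),
    ("LB8", "TriLLB", (-85, -5, -210), "LLL", "LB8"),
    ("LB9", "TriLLB", (-70, -15, -225), "LLL", "LB9"),
    ("LB10", "TriLLB", (-60, 0, -240), "LLL", "LB10"),
]

#: approximate centers of the lobar point clouds (mm, TLC scale)
_LOBE_CENTERS = {
    "RUL": (95, 10, -95), "RML": (100, 40, -210), "RLL": (85, -15, -250),
    "LUL": (-100, 20, -115), "LLL": (-90, -5, -245),
}


def _subsegmental_entries():
    """Two resolved subsegmental children per labeled segment.

    CT typically resolves one to two generations beyond the segmental
    bronchi (the study's subjects averaged ~94-143 resolved airways);
    carrying them in the template also gives each lobe enough resolved
    branches (~13) for a stable per-subject estimate of the lobar
    constriction SD.
    """
    by_name = {name: (parent, np.asarray(tip, float)) for name, parent, tip, _, _ in _TEMPLATE}
    entries = []
    for name, parent, tip, lobe, region in _TEMPLATE:
        if region is None or region in ("Trachea", "RMB", "BronInt", "TriRLL",
                                        "LMB", "TriLLB"):
            continue
        tip = np.asarray(tip, float)
        d = tip - by_name[parent][1]
        u = np.cross(d, [0.0, 0.0, 1.0])
        if np.linalg.norm(u) < 1e-9:
            u = np.array([1.0, 0.0, 0.0])
        u = u / np.linalg.norm(u)
        span = 0.35 * np.linalg.norm(d)
        for suffix, sign in (("a", 1.0), ("b", -1.0)):
            child_tip = tip + 0.5 * d + sign * span * u
            entries.append((f"{name}{suffix}", name, tuple(child_tip), lobe, None))
    return entries


def build_resolved_template() -> tuple[AirwayTree, dict[str, int]]:
    """Canonical CT-resolved tree (trachea through subsegments) at TLC scale.

    Diameters are placeholders (1 mm) until the subject-specific draws are
    applied.  Returns the tree and a name -> branch id map.
    """
    tree = AirwayTree(volume_state="TLC")
    tree.add_node(0, (0.0, 0.0, 0.0))
    name_to_branch: dict[str, int] = {}
    name_to_dist: dict[str, int] = {}
    for name, parent, tip, lobe, region in _TEMPLATE + _subsegmental_entries():
        dist = tree.add_node(tree.next_node_id(), tip)
        if parent is None:
            prox, parent_id, generation = 0, None, 1
        else:
            parent_id = name_to_branch[parent]
            prox = name_to_dist[parent]
            generation = tree.branches[parent_id].generation + 1
        length = float(np.linalg.norm(tree.nodes[dist] - tree.nodes[prox]))
        b = tree.add_branch(Branch(
            id=tree.next_branch_id(), parent=parent_id, prox_node=prox,
            dist_node=dist, lobe=lobe, generation=generation, order=None,
            diameter_mm=1.0, length_mm=length, resolved=True, region=region,
        ))
        name_to_branch[name] = b.id
        name_to_dist[name] = dist
    return tree, name_to_branch


# ---------------------------------------------------------------------------
# Density mixture
# ---------------------------------------------------------------------------

def _component_class_probs(thresholds: PRMThresholds) -> np.ndarray:
    """Per-component probabilities of classifying as (Emph, fSAD)."""
    rows = []
    for comp in ("Emph", "fSAD", "Normal"):
        (mi, si), (me, se) = HU_COMPONENTS[comp]
        p_emph = norm.cdf(thresholds.emphysema_insp_HU, mi, si)
        p_fsad = (1.0 - p_emph) * norm.cdf(thresholds.airtrap_exp_HU, me, se)
        rows.append((p_emph, p_fsad))
    return np.asarray(rows)  # (3 components, 2 classes)


def solve_mixture_weights(emph_pct: float, fsad_pct: float,
                          thresholds: PRMThresholds | None = None) -> np.ndarray:
    """Mixture weights over (Emph, fSAD, Normal) HU components.

    Solves the 3x3 linear system so that the *expected* classified
    percentages under the thresholds equal the targets exactly.  Raises
    for infeasible targets (outside the simplex the components span).
    """
    thresholds = thresholds or PRMThresholds()
    if emph_pct < 0 or fsad_pct < 0 or emph_pct + fsad_pct > 100:
        raise ValueError(f"infeasible targets Emph={emph_pct}%, fSAD={fsad_pct}%")
    probs = _component_class_probs(thresholds)  # rows: components
    a = np.vstack([probs.T, np.ones(3)])  # rows: Emph eq, fSAD eq, sum eq
    b = np.array([emph_pct / 100.0, fsad_pct / 100.0, 1.0])
    w = np.linalg.solve(a, b)
    # targets below the floor set by cross-threshold leakage of the other
    # components give slightly negative weights; tolerate and clip those
    if (w < -0.02).any():
        raise ValueError(
            f"targets Emph={emph_pct}%, fSAD={fsad_pct}% are not reachable "
            "with the configured HU components"
        )
    w = np.clip(w, 0.0, None)
    return w / w.sum()


def sample_density_pairs(emph_pct: float, fsad_pct: float, n: int,
                         rng: np.random.Generator,
                         thresholds: PRMThresholds | None = None) -> pd.DataFrame:
    """n registered (inspiratory, expiratory) HU pairs hitting the targets in expectation."""
    w = solve_mixture_weights(emph_pct, fsad_pct, thresholds)
    comps = rng.choice(3, size=n, p=w)
    insp = np.empty(n)
    exp = np.empty(n)
    for k, comp in enumerate(("Emph", "fSAD", "Normal")):
        (mi, si), (me, se) = HU_COMPONENTS[comp]
        mask = comps == k
        insp[mask] = rng.normal(mi, si, mask.sum())
        exp[mask] = rng.normal(me, se, mask.sum())
    return pd.DataFrame({
        "insp_hu": np.clip(insp, *HU_RANGE),
        "exp_hu": np.clip(exp, *HU_RANGE),
    })


# ---------------------------------------------------------------------------
# Subject generation
# ---------------------------------------------------------------------------

def _lognormal_matched(rng, mean, sd, upper=None, max_tries=1000):
    """Lognormal draw with the given mean and SD (moment-matched).

    Appropriate for right-skewed nonnegative quantities like lobar Emph%
    and fSAD%, whose printed SDs often exceed their means; a truncated
    normal would inflate the mean, a lognormal preserves it.
    """
    if mean <= 0:
        return 0.0
    if sd == 0:
        return float(mean)
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    for _ in range(max_tries):
        x = float(rng.lognormal(mu, math.sqrt(sigma2)))
        if upper is None or x < upper:
            return x
    raise RuntimeError("lognormal rejection failed")


def _truncated_normal(rng, mean, sd, lower=None, upper=None, max_tries=1000):
    if sd == 0:
        return mean
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if (lower is None or x > lower) and (upper is None or x < upper):
            return float(x)
    raise RuntimeError("truncated normal rejection failed")


def _ellipsoid_points(center, volume_L, n, rng):
    """Uniform fill of an axis-aligned ellipsoid of the given air volume."""
    volume_mm3 = volume_L * 1e6
    # semi-axis shape ratios (x, y, z) = (1, 0.8, 1.4) scaled to the volume
    ratios = np.array([1.0, 0.8, 1.4])
    r = (volume_mm3 / (4.0 / 3.0 * np.pi * np.prod(ratios))) ** (1.0 / 3.0)
    axes = ratios * r
    pts = []
    while len(pts) < n:
        cand = rng.uniform(-1.0, 1.0, size=(4 * n, 3))
        keep = (cand ** 2).sum(axis=1) <= 1.0
        pts.extend(cand[keep])
    pts = np.asarray(pts[:n]) * axes + np.asarray(center, dtype=float)
    return pts


def generate_subject(group: str, params: CohortParams, rng: np.random.Generator,
                     subject_id: str = "S000",
                     daver_table: DaverTable | None = None) -> SubjectRecord:
    """Draw one complete synthetic subject for the given group."""
    if group not in ("A", "B"):
        raise ValueError(f"group must be 'A' or 'B', got {group!r}")
    daver_table = daver_table or DaverTable.default()

    # demographics
    sex = int(rng.random() >= params.male_fraction[group])  # 0 male, 1 female
    h_mean, h_sd = params.height_male if sex == 0 else params.height_female
    demo = Demographics(
        sex=sex,
        height=_truncated_normal(rng, h_mean, h_sd, lower=1.3, upper=2.1),
        age=_truncated_normal(rng, *params.age[group], lower=18.0, upper=100.0),
    )
    d_pred = predict_trachea_diameter(demo)

    # lung air volumes; TLC kept above FRC + tidal reserve
    frc_vol = _truncated_normal(rng, *params.frc_air_volume[group], lower=0.6)
    tlc_vol = _truncated_normal(rng, *params.tlc_air_volume[group], lower=frc_vol + 1.3)

    # resolved trees at both states
    tree_tlc, name_to_branch = build_resolved_template()
    scale = (frc_vol / tlc_vol) ** (1.0 / 3.0)
    frc_means = params.dave_star_frc[group]
    tlc_means = params.tlc_dave_star(group)
    central_dh = params.central_dh_star[group]

    central_draws: dict[str, float] = {}
    for name, bid in name_to_branch.items():
        b = tree_tlc.branches[name_to_branch[name]]
        if b.region in central_dh:  # six central regions: direct Dh* draw
            mean, sd = central_dh[b.region]
            dh_star = _truncated_normal(rng, mean, sd, lower=0.05)
            central_draws[b.region] = dh_star
            b.diameter_mm = dh_star * d_pred
        else:  # lobe-labeled branch: predicted healthy diameter x Dave* draw
            z = rng.standard_normal()
            m_t, s_t = tlc_means[b.lobe]
            mult = max(m_t + s_t * z, 0.05)
            b.diameter_mm = predict_generation_diameter(
                demo, b.lobe, b.generation, daver_table) * mult
            b._frc_mult = max(frc_means[b.lobe][0] + frc_means[b.lobe][1] * z, 0.04)

    tree_frc = tree_tlc.copy()
    tree_frc.volume_state = "FRC"
    for nid in tree_frc.nodes:
        tree_frc.nodes[nid] = tree_tlc.nodes[nid] * scale
    for bid, b in tree_frc.branches.items():
        bt = tree_tlc.branches[bid]
        b.length_mm = bt.length_mm * scale
        if hasattr(bt, "_frc_mult"):  # lobe-labeled: FRC Dave* draw (shared z)
            b.diameter_mm = predict_generation_diameter(
                demo, b.lobe, b.generation, daver_table) * bt._frc_mult
            b.diameter_mm = min(b.diameter_mm, bt.diameter_mm * 0.999)
        else:  # central: deflate with the linear scale
            b.diameter_mm = bt.diameter_mm * scale
    for b in tree_tlc.branches.values():
        if hasattr(b, "_frc_mult"):
            del b._frc_mult
    tree_tlc.validate()
    tree_frc.validate()

    # lobar seeds: point clouds + volumes
    seeds = []
    for lobe in LOBES:
        frac = LOBE_VOLUME_FRACTION[lobe]
        pts = _ellipsoid_points(_LOBE_CENTERS[lobe], tlc_vol * frac,
                                params.points_per_lobe, rng)
        seeds.append(LobeSeed(lobe=lobe, points=pts,
                              volume_tlc_L=tlc_vol * frac,
                              volume_frc_L=frc_vol * frac))

    # registered density samples per lobe
    frames = []
    for lobe in LOBES:
        e_mean, f_mean = params.prm_targets[group][lobe]
        e_sd, f_sd = params.prm_target_sd[group][lobe]
        emph = _lognormal_matched(rng, e_mean, e_sd, upper=60.0)
        fsad = _lognormal_matched(rng, f_mean, f_sd, upper=95.0 - emph)
        df = sample_density_pairs(emph, fsad, params.voxels_per_lobe, rng,
                                  params.thresholds)
        df["lobe"] = lobe
        frames.append(df)
    densities = pd.concat(frames, ignore_index=True)

    # structural measurements over the 11 regions (+ per-segment rows)
    wt = params.wt_star[group]
    rows = []
    for region in CENTRAL_REGIONS:
        rows.append({
            "region": region,
            "dh_mm": central_draws[region] * d_pred,
            "wt_mm": _truncated_normal(rng, *wt[region], lower=0.05) * params.wt_reference_mm,
        })
    for sub, segments in SUBGROUP_SEGMENTS.items():
        for seg in segments:
            b = tree_tlc.branches[name_to_branch[seg]]
            rows.append({
                "region": seg,
                "dh_mm": b.diameter_mm,
                "wt_mm": _truncated_normal(rng, *wt[sub], lower=0.05) * params.wt_reference_mm,
            })
    structure = pd.DataFrame(rows)

    # spirometry; postbronchodilator FEV1/FVC respects the group definition
    pft = {}
    for var, (mean, sd) in params.pft[group].items():
        if var == "FEV1_FVC_post":
            bound = 70.0
            pft[var] = (_truncated_normal(rng, mean, sd, upper=bound) if group == "B"
                        else _truncated_normal(rng, mean, sd, lower=bound))
        else:
            pft[var] = _truncated_normal(rng, mean, sd, lower=5.0)

    return SubjectRecord(
        subject_id=subject_id, group=group, demographics=demo,
        tree_tlc=tree_tlc, tree_frc=tree_frc, seeds=seeds,
        densities=densities, structure=structure, pft=pft,
        inspiratory_volume_L=tlc_vol, expiratory_volume_L=frc_vol,
    )


def generate_cohort(params: CohortParams | None = None,
                    daver_table: DaverTable | None = None) -> list[SubjectRecord]:
    """Generate the full two-group cohort, deterministic under the master seed."""
    params = params or CohortParams()
    daver_table = daver_table or DaverTable.default()
    root = np.random.SeedSequence(params.master_seed)
    seeds = root.spawn(params.n_a + params.n_b)
    subjects = []
    for i in range(params.n_a + params.n_b):
        group = "A" if i < params.n_a else "B"
        rng = np.random.default_rng(seeds[i])
        subjects.append(generate_subject(
            group, params, rng, subject_id=f"S{i:03d}", daver_table=daver_table))
    return subjects


def qc_filter(subject: SubjectRecord) -> tuple[bool, str]:
    """Exclude subjects with inadequate expiration (exp/insp volume > 0.9)."""
    insp, exp = subject.inspiratory_volume_L, subject.expiratory_volume_L
    if insp is None or exp is None or not (insp > 0):
        raise ValueError("inspiratory and expiratory volumes required")
    ratio = exp / insp
    if ratio > 0.9:
        return False, "inadequate expiration"
    return True, ""
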