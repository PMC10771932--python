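"""Quantitative-CT functional and structural metrics.

Functional metrics come from the parametric response map: each voxel with
a registered inspiratory/expiratory density pair is classified as
emphysematous (inspiratory density below the emphysema threshold,
default -950 HU), functional small-airway disease (not emphysematous but
expiratory density below the air-trapping threshold, default -856 HU) or
normal.  Emph% and fSAD% are the class percentages per lobe and for the
pooled lung.

Structural metrics are the hydraulic diameter Dh = 4 A / P and airway
wall thickness WT of the 11 standard regions (6 central branches and 5
segmental subgroups), normalized by the subject's predicted tracheal
diameter and a reference wall thickness to give Dh* and WT*.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .reference_model import LOBES, Demographics, predict_trachea_diameter

__all__ = [
    "PRMThresholds",
    "CENTRAL_REGIONS",
    "SUBGROUP_SEGMENTS",
    "REGIONS_11",
    "classify_voxel",
    "classify_voxels",
    "lobe_percentages",
    "hydraulic_diameter",
    "normalize_structure",
    "region_structure_table",
]

#: the six central airway regions measured individually
CENTRAL_REGIONS = ("Trachea", "RMB", "BronInt", "TriRLL", "LMB", "TriLLB")

#: segmental subgroups and their constituent branch labels
SUBGROUP_SEGMENTS = {
    "sRUL": ("RB1", "RB2", "RB3"),
    "sRML": ("RB4", "RB5"),
    "sRLL": ("RB6", "RB8", "RB9", "RB10"),
    "sLUL": ("LB1", "LB2", "LB3", "LB4", "LB5"),
    "sLLL": ("LB6", "LB8", "LB9", "LB10"),
}

REGIONS_11 = CENTRAL_REGIONS + tuple(SUBGROUP_SEGMENTS)

#: default predicted tracheal wall thickness (mm); rescales WT* only
DEFAULT_WT_REFERENCE_MM = 1.5


@dataclass(frozen=True)
class PRMThresholds:
    """Density thresholds (HU) of the parametric response map."""

    emphysema_insp_HU: float = -950.0
    airtrap_exp_HU: float = -856.0

    def __post_init__(self) -> None:
        if self.emphysema_insp_HU >= self.airtrap_exp_HU:
            raise ValueError(
                "emphysema (inspiratory) threshold must lie below the "
                "air-trapping (expiratory) threshold"
            )


def classify_voxel(insp_HU: float, exp_HU: float,
                   thresholds: PRMThresholds | None = None) -> str:
    """One voxel's class: 'Emph', 'fSAD' or 'Normal'."""
    thresholds = thresholds or PRMThresholds()
    if insp_HU < thresholds.emphysema_insp_HU:
        return "Emph"
    if exp_HU < thresholds.airtrap_exp_HU:
        return "fSAD"
    return "Normal"


def classify_voxels(insp_HU, exp_HU, thresholds: PRMThresholds | None = None) -> np.ndarray:
    """Vectorized classification; returns an array of class labels."""
    thresholds = thresholds or PRMThresholds()
    insp = np.asarray(insp_HU, dtype=float)
    exp = np.asarray(exp_HU, dtype=float)
    out = np.full(insp.shape, "Normal", dtype=object)
    emph = insp < thresholds.emphysema_insp_HU
    fsad = ~emph & (exp < thresholds.airtrap_exp_HU)
    out[emph] = "Emph"
    out[fsad] = "fSAD"
    return out


def lobe_percentages(pairs: pd.DataFrame,
                     thresholds: PRMThresholds | None = None) -> pd.DataFrame:
    """Emph%/fSAD%/Normal% per lobe plus the pooled 'Total' row.

    ``pairs`` needs columns insp_hu, exp_hu, lobe.  The Total row pools
    voxels (voxel-count weighted), it is not a mean of lobe rows.
    """
    required = {"insp_hu", "exp_hu", "lobe"}
    if not required.issubset(pairs.columns):
        raise ValueError(f"density pairs need columns {sorted(required)}")
    present = [lobe for lobe in LOBES if lobe in set(pairs["lobe"])]
    missing = [lobe for lobe in set(pairs["lobe"]) if lobe not in LOBES]
    if missing:
        raise ValueError(f"unknown lobe label(s): {sorted(missing)}")
    if not present:
        raise ValueError("no density pairs in any lobe")
    cls = classify_voxels(pairs["insp_hu"], pairs["exp_hu"], thresholds)
    df = pairs.assign(prm_class=cls)
    rows = []
    for region, grp in [(lobe, df[df["lobe"] == lobe]) for lobe in present] + [("Total", df)]:
        n = len(grp)
        counts = grp["prm_class"].value_counts()
        rows.append({
            "region": region,
            "Emph%": 100.0 * counts.get("Emph", 0) / n,
            "fSAD%": 100.0 * counts.get("fSAD", 0) / n,
            "Normal%": 100.0 * counts.get("Normal", 0) / n,
            "n_voxels": n,
        })
    return pd.DataFrame(rows)


def hydraulic_diameter(lumen_area_mm2: float, lumen_perimeter_mm: float) -> float:
    """Dh = 4 A / P (mm); equals the geometric diameter for a circle."""
    if lumen_area_mm2 <= 0 or lumen_perimeter_mm <= 0:
        raise ValueError("lumen area and perimeter must be positive")
    return 4.0 * lumen_area_mm2 / lumen_perimeter_mm


def normalize_structure(
    dh_mm: float,
    wt_mm: float,
    demographics: Demographics,
    wt_reference: float | Callable[[Demographics], float] = DEFAULT_WT_REFERENCE_MM,
) -> tuple[float, float]:
    """(Dh*, WT*): measurements over their subject-specific predictions.

    Dh is normalized by the predicted tracheal diameter; WT by a reference
    wall thickness (a constant or a callable of demographics).
    """
    if dh_mm <= 0 or wt_mm <= 0:
        raise ValueError("measurements must be positive")
    ref = wt_reference(demographics) if callable(wt_reference) else float(wt_reference)
    if ref <= 0:
        raise ValueError("wall-thickness reference must be positive")
    return dh_mm / predict_trachea_diameter(demographics), wt_mm / ref


def region_structure_table(
    measurements: pd.DataFrame,
    demographics: Demographics,
    wt_reference: float | Callable[[Demographics], float] = DEFAULT_WT_REFERENCE_MM,
) -> pd.DataFrame:
    """Per-region Dh/WT with normalized Dh*/WT* over the 11 standard regions.

    ``measurements`` needs columns region, dh_mm, wt_mm, one row per
    measured branch; the six central regions are reported as-is and the
    s-prefixed subgroups as unweighted means over their constituent
    segmental branches (rows labeled with the segment names RB1..LB10).
    """
    required = {"region", "dh_mm", "wt_mm"}
    if not required.issubset(measurements.columns):
        raise ValueError(f"measurements need columns {sorted(required)}")
    by_label = measurements.set_index("region")
    rows = []
    for region in REGIONS_11:
        if region in CENTRAL_REGIONS:
            if region not in by_label.index:
                raise KeyError(f"missing measurement for central region {region}")
            dh = float(by_label.loc[region, "dh_mm"])
            wt = float(by_label.loc[region, "wt_mm"])
        else:
            segments = [s for s in SUBGROUP_SEGMENTS[region] if s in by_label.index]
            if not segments:
                raise KeyError(f"no segmental measurements for subgroup {region}")
            dh = float(by_label.loc[segments, "dh_mm"].mean())
            wt = float(by_label.loc[segments, "wt_mm"].mean())
        dh_star, wt_star = normalize_structure(dh, wt, demographics, wt_reference)
        rows.append({"region": region, "Dh_mm": dh, "WT_mm": wt,
                     "Dh_star": dh_star, "WT_star": wt_star})
    return pd.DataFrame(rows)
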