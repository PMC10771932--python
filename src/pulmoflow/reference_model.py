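"""Healthy-reference airway geometry.

The reference model predicts what a subject's airways *should* look like
given sex, height and age, using a regression of tracheal diameter fitted
on 222 healthy Korean adults together with a per-lobe, per-generation
table of healthy diameter ratios (``Daver``).  Dividing a measured average
diameter by its prediction yields the constriction/dilation index
``Dave*``, which is ~1 in health, <1 for constricted airways and >1 for
dilated ones.  Lobar means and SDs of ``Dave*`` over the CT-resolved
branches drive the stochastic diameter assignment for branches below CT
resolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "LOBES",
    "Demographics",
    "DaverTable",
    "ConstrictionStats",
    "predict_trachea_diameter",
    "lookup_daver",
    "predict_generation_diameter",
    "constriction_index",
    "lobar_constriction_stats",
    "sample_constriction_multiplier",
]

#: The five lung lobes: left/right upper, right middle, left/right lower.
LOBES = ("LUL", "LLL", "RUL", "RML", "RLL")

#: Multiplier draws at or below this value are rejected and redrawn; a
#: normal draw can be nonpositive and a nonpositive diameter is unphysical.
MULTIPLIER_FLOOR = 0.05


@dataclass(frozen=True)
class Demographics:
    """Subject covariates entering the tracheal-diameter regression.

    Parameters
    ----------
    sex : int
        0 for male, 1 for female (the regression's coding).
    height : float
        Standing height in meters.
    age : float
        Age in years (adults only).
    """

    sex: int
    height: float
    age: float

    def __post_init__(self) -> None:
        if self.sex not in (0, 1):
            raise ValueError(f"sex must be 0 (male) or 1 (female), got {self.sex!r}")
        if not 0.5 < self.height < 2.5:
            raise ValueError(f"height must be in (0.5, 2.5) m, got {self.height}")
        if self.age < 18:
            raise ValueError(f"age must be >= 18 years, got {self.age}")


class DaverTable:
    """Healthy diameter ratio ``Daver`` by (lobe, generation).

    Ratios are the mean CT-measured average diameter of a lobe/generation
    stratum divided by the predicted tracheal diameter, tabulated from 222
    healthy adults.  Upper lobes and LLL are tabulated for generations
    2-7, RML for 3-7 and RLL for 3-10.  Deeper generations reuse the
    deepest tabulated ratio (the ratios flatten with depth); shallower
    generations are undefined.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"lobe", "generation", "mean", "se"}
        if not required.issubset(frame.columns):
            raise ValueError(f"Daver table needs columns {sorted(required)}")
        frame = frame.copy()
        frame["generation"] = frame["generation"].astype(int)
        if ((frame["mean"] <= 0) | (frame["mean"] >= 1)).any():
            raise ValueError("all mean ratios must lie in (0, 1)")
        for lobe, grp in frame.groupby("lobe"):
            means = grp.sort_values("generation")["mean"].to_numpy()
            if not (np.diff(means) < 0).all():
                raise ValueError(f"mean ratios must strictly decrease with generation in {lobe}")
        self._frame = frame
        self._entries = {
            (row.lobe, int(row.generation)): (float(row.mean), float(row.se))
            for row in frame.itertuples()
        }
        self._gen_range = {
            lobe: (int(g.min()), int(g.max()))
            for lobe, g in frame.groupby("lobe")["generation"]
        }

    @classmethod
    def default(cls) -> "DaverTable":
        """The packaged healthy-Korean reference table."""
        with resources.files("pulmoflow.data").joinpath("daver_table.csv").open() as fh:
            return cls(pd.read_csv(fh))

    @classmethod
    def from_csv(cls, path) -> "DaverTable":
        return cls(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()

    def generation_range(self, lobe: str) -> tuple[int, int]:
        self._check_lobe(lobe)
        return self._gen_range[lobe]

    def _check_lobe(self, lobe: str) -> None:
        if lobe not in self._gen_range:
            raise KeyError(f"unknown lobe {lobe!r}; expected one of {sorted(self._gen_range)}")

    def mean(self, lobe: str, generation: int) -> float:
        """Mean ratio with deep-generation clamping (see class docstring)."""
        self._check_lobe(lobe)
        generation = int(generation)
        lo, hi = self._gen_range[lobe]
        if generation < lo:
            raise KeyError(
                f"Daver undefined for {lobe} generation {generation}; "
                f"first tabulated generation is {lo}"
            )
        return self._entries[(lobe, min(generation, hi))][0]

    def se(self, lobe: str, generation: int) -> float:
        self._check_lobe(lobe)
        lo, hi = self._gen_range[lobe]
        if generation < lo:
            raise KeyError(f"Daver undefined for {lobe} generation {generation}")
        return self._entries[(lobe, min(int(generation), hi))][1]


@dataclass
class ConstrictionStats:
    """Per-lobe sample mean and SD of ``Dave*`` over CT-resolved branches."""

    state: str  # "TLC" or "FRC"
    mean: dict = field(default_factory=dict)  # lobe -> mean Dave*
    sd: dict = field(default_factory=dict)  # lobe -> sample SD (ddof=1)
    n: dict = field(default_factory=dict)  # lobe -> branch count

    def require(self, lobe: str) -> tuple[float, float]:
        if lobe not in self.mean:
            raise KeyError(f"no constriction statistics for lobe {lobe!r}")
        return self.mean[lobe], self.sd[lobe]


def predict_trachea_diameter(demographics: Demographics) -> float:
    """Predicted tracheal diameter in mm from sex, height and age.

    D = 12.79 - 0.13 ln(age) - 5.82 ln(height) sex + 3.01 ln(age) ln(height),
    with height in meters, age in years and sex coded 0/1 (male/female).
    """
    d = demographics
    value = (
        12.79
        - 0.13 * math.log(d.age)
        - 5.82 * math.log(d.height) * d.sex
        + 3.01 * math.log(d.age) * math.log(d.height)
    )
    if value <= 0:
        raise ValueError(f"predicted tracheal diameter nonpositive ({value:.3f} mm)")
    return value


def lookup_daver(table: DaverTable, lobe: str, generation: int) -> float:
    """Healthy diameter ratio for a (lobe, generation) stratum."""
    return table.mean(lobe, generation)


def predict_generation_diameter(
    demographics: Demographics, lobe: str, generation: int, table: DaverTable
) -> float:
    """Predicted healthy average diameter (mm) at a lobe/generation."""
    return predict_trachea_diameter(demographics) * lookup_daver(table, lobe, generation)


def constriction_index(measured_diameter: float, predicted_diameter: float) -> float:
    """``Dave* = measured / predicted``; ~1 healthy, <1 constricted, >1 dilated."""
    if measured_diameter <= 0:
        raise ValueError(f"measured diameter must be positive, got {measured_diameter}")
    if predicted_diameter <= 0:
        raise ValueError(f"predicted diameter must be positive, got {predicted_diameter}")
    return measured_diameter / predicted_diameter


def lobar_constriction_stats(tree, demographics: Demographics, table: DaverTable, state: str) -> ConstrictionStats:
    """Per-lobe mean and sample SD of ``Dave*`` over CT-resolved branches.

    Only resolved branches with a lobe label contribute.  A lobe present
    in the tree with a single resolved branch reports SD = 0; a requested
    lobe with no resolved branch raises.
    """
    values: dict[str, list[float]] = {}
    for br in tree.branches.values():
        if not br.resolved or br.lobe not in LOBES:
            continue
        pred = predict_generation_diameter(demographics, br.lobe, br.generation, table)
        values.setdefault(br.lobe, []).append(constriction_index(br.diameter_mm, pred))
    present = {lobe for br in tree.branches.values() if br.lobe in LOBES for lobe in [br.lobe]}
    missing = sorted(present - set(values))
    if missing:
        raise ValueError(f"no CT-resolved branches in lobe(s): {', '.join(missing)}")
    stats = ConstrictionStats(state=state)
    for lobe, vals in values.items():
        arr = np.asarray(vals)
        stats.mean[lobe] = float(arr.mean())
        stats.sd[lobe] = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        stats.n[lobe] = int(arr.size)
    return stats


def sample_constriction_multiplier(
    stats: ConstrictionStats, lobe: str, rng: np.random.Generator
) -> float:
    """One positive draw from the lobe's Normal(mean, SD) of ``Dave*``.

    Draws at or below ``MULTIPLIER_FLOOR`` are rejected and redrawn so the
    resulting diameter stays physical.  With SD = 0 the mean is returned
    exactly.
    """
    mean, sd = stats.require(lobe)
    if sd == 0.0:
        if mean <= MULTIPLIER_FLOOR:
            raise ValueError(f"degenerate multiplier {mean} at or below floor {MULTIPLIER_FLOOR}")
        return mean
    while True:
        value = rng.normal(mean, sd)
        if value > MULTIPLIER_FLOOR:
            return float(value)
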