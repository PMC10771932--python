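"""End-to-end orchestration: generate -> QC -> complete -> simulate -> compare.

``run_pipeline`` generates (or accepts) a cohort, applies the expiration
quality filter, completes each subject's airway tree beyond CT resolution
at both lung-volume states, simulates one breathing cycle on the moving
geometry, extracts quantitative-CT and pressure variables, and runs the
two-group statistical battery with a single Benjamini-Hochberg family.
Outputs are tidy CSV tables (one per published-table analogue) plus a
correlation table and a provenance manifest.
"""

from __future__ import annotations

import configparser
import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .breathing import BreathConfig, breathing_schedule
from .cohort import CohortParams, SubjectRecord, generate_cohort, qc_filter
from .flow_solver import SolverConfig, simulate_breath
from .qct import PRMThresholds, lobe_percentages, region_structure_table, REGIONS_11
from .reference_model import DaverTable, lobar_constriction_stats
from .stats import build_report, compare_groups
from .tree_completion import FillParams, assign_unresolved_diameters, assign_horsfield_orders, fill_lobe

__all__ = ["RunConfig", "SubjectResult", "process_subject", "run_pipeline"]

#: segmental branches averaged for the "segmental airway diameter" variable
SEGMENTAL_AVERAGE_SET = (
    "LB1", "LB2", "LB3", "LB4", "LB5", "LB6", "LB9", "LB10",
    "RB1", "RB2", "RB3", "RB4", "RB5", "RB6", "RB8", "RB9", "RB10",
)

PFT_VARIABLES = ("FEV1_pre", "FVC_pre", "FEV1_FVC_pre",
                 "FEV1_post", "FVC_post", "FEV1_FVC_post")


@dataclass
class RunConfig:
    cohort: CohortParams = field(default_factory=CohortParams)
    breath: BreathConfig = field(default_factory=BreathConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    fill: FillParams = field(default_factory=FillParams)
    thresholds: PRMThresholds = field(default_factory=PRMThresholds)
    seed: int = 0
    out_dir: str = "pulmoflow_run"

    def __post_init__(self) -> None:
        if not isinstance(self.cohort, CohortParams):
            self.cohort = CohortParams(**self.cohort)
        self.cohort.master_seed = self.seed

    @classmethod
    def from_ini(cls, path, seed: int | None = None, out_dir: str | None = None) -> "RunConfig":
        """Load a plain key = value config with [cohort]/[breath]/[solver]/[fill]/[run] sections."""
        parser = configparser.ConfigParser()
        parser.optionxform = str  # keep case-sensitive keys (e.g. tidal_volume_L)
        with open(path) as fh:
            parser.read_file(fh)
        kwargs = {}
        section_types = {"cohort": CohortParams, "breath": BreathConfig,
                         "solver": SolverConfig, "fill": FillParams}
        for section, typ in section_types.items():
            if parser.has_section(section):
                allowed = {f.name: f.type for f in fields(typ)}
                values = {}
                for key, raw in parser.items(section):
                    if key not in allowed:
                        raise KeyError(f"unknown key {key!r} in section [{section}]")
                    try:
                        values[key] = json.loads(raw)
                    except json.JSONDecodeError:
                        values[key] = raw
                kwargs[section] = typ(**values)
        run = dict(parser.items("run")) if parser.has_section("run") else {}
        cfg = cls(
            **kwargs,
            seed=int(run.get("seed", 0)) if seed is None else seed,
            out_dir=run.get("out_dir", "pulmoflow_run") if out_dir is None else out_dir,
        )
        return cfg

    def config_hash(self) -> str:
        def default(o):
            try:
                return asdict(o)
            except TypeError:
                return repr(o)
        blob = json.dumps(
            {"cohort": asdict(self.cohort), "breath": asdict(self.breath),
             "solver": asdict(self.solver), "fill": asdict(self.fill),
             "seed": self.seed},
            sort_keys=True, default=default,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class SubjectResult:
    subject_id: str
    group: str
    included: bool
    exclusion_reason: str
    variables: dict  # flat name -> value used by the statistics battery


def complete_subject_trees(subject: SubjectRecord, daver: DaverTable,
                           fill: FillParams, rng: np.random.Generator):
    """Grow both state trees with shared topology and correlated diameters.

    Growth runs once on the TLC geometry; the FRC completed tree reuses the
    topology with coordinates/lengths contracted by the lung linear scale
    and unresolved diameters drawn from the FRC constriction statistics
    using the same per-branch standard-normal deviate as at TLC, so every
    branch is wider at TLC than at FRC.
    """
    demo = subject.demographics
    stats_tlc = lobar_constriction_stats(subject.tree_tlc, demo, daver, "TLC")
    stats_frc = lobar_constriction_stats(subject.tree_frc, demo, daver, "FRC")

    completed_tlc = subject.tree_tlc.copy()
    resolved_ids = set(completed_tlc.branches)
    for seed in subject.seeds:
        fill_lobe(completed_tlc, seed, fill)
    assign_horsfield_orders(completed_tlc)
    unresolved = [bid for bid in completed_tlc.branches if bid not in resolved_ids]
    shared_z = {bid: float(z) for bid, z in
                zip(unresolved, rng.standard_normal(len(unresolved)))}
    assign_unresolved_diameters(completed_tlc, demo, daver, stats_tlc, rng,
                                ratio=fill.diameter_ratio,
                                terminal_diameter_mm=fill.terminal_diameter_mm,
                                shared_z=shared_z)

    scale = (subject.expiratory_volume_L / subject.inspiratory_volume_L) ** (1.0 / 3.0)
    completed_frc = completed_tlc.copy()
    completed_frc.volume_state = "FRC"
    for nid in completed_frc.nodes:
        completed_frc.nodes[nid] *= scale
    for bid, b in completed_frc.branches.items():
        b.length_mm *= scale
        if bid in resolved_ids:
            b.diameter_mm = subject.tree_frc.branches[bid].diameter_mm
    assign_unresolved_diameters(completed_frc, demo, daver, stats_frc, rng,
                                ratio=fill.diameter_ratio,
                                terminal_diameter_mm=fill.terminal_diameter_mm,
                                shared_z=shared_z)
    completed_tlc.validate()
    completed_frc.validate()
    return completed_tlc, completed_frc, stats_tlc, stats_frc


def process_subject(subject: SubjectRecord, daver: DaverTable, config: RunConfig,
                    rng: np.random.Generator) -> SubjectResult:
    """All per-subject computation; returns the flat variable dictionary."""
    included, reason = qc_filter(subject)
    if not included:
        return SubjectResult(subject.subject_id, subject.group, False, reason, {})

    completed_tlc, completed_frc, stats_tlc, stats_frc = complete_subject_trees(
        subject, daver, config.fill, rng)

    breath = BreathConfig(
        tidal_volume_L=config.breath.tidal_volume_L,
        period_s=config.breath.period_s,
        steps_per_cycle=config.breath.steps_per_cycle,
        frc_volume_L=subject.expiratory_volume_L,
        tlc_volume_L=subject.inspiratory_volume_L,
        interp_method=config.breath.interp_method,
        phase_convention=config.breath.phase_convention,
    )
    solver = SolverConfig(
        viscosity_Pa_s=config.solver.viscosity_Pa_s,
        density_kg_m3=config.solver.density_kg_m3,
        compliance_L_per_cmH2O=config.solver.compliance_L_per_cmH2O,
        resistance_model=config.solver.resistance_model,
        pedley_coefficient=config.solver.pedley_coefficient,
        frc_air_volume_L=subject.expiratory_volume_L,
    )
    solution = simulate_breath(completed_frc, completed_tlc, breath, solver,
                               lobe_volume_change=subject.lobe_volume_change_L)

    variables: dict[str, float] = {
        "Age_years": subject.demographics.age,
        **{k: v for k, v in subject.pft.items()},
    }
    for key, val in solution.summary.items():
        variables[key] = val
    variables["neg_P_pl_PI_Pa"] = -solution.summary["P_pl_PI_Pa"]
    variables["neg_P_pl_PE_Pa"] = -solution.summary["P_pl_PE_Pa"]

    prm = lobe_percentages(subject.densities, config.thresholds)
    for row in prm.itertuples():
        variables[f"Emph%_{row.region}"] = row._2
        variables[f"fSAD%_{row.region}"] = row._3

    structure = region_structure_table(subject.structure, subject.demographics,
                                       config.cohort.wt_reference_mm)
    for row in structure.itertuples():
        variables[f"Dh*_{row.region}"] = row.Dh_star
        variables[f"WT*_{row.region}"] = row.WT_star

    # constriction index per lobe and pooled, both states
    for state, stats in (("FRC", stats_frc), ("TLC", stats_tlc)):
        total, ntot = 0.0, 0
        for lobe, mean in stats.mean.items():
            variables[f"Dave*_{state}_{lobe}"] = mean
            total += mean * stats.n[lobe]
            ntot += stats.n[lobe]
        variables[f"Dave*_{state}_Total"] = total / ntot

    # average diameters during breathing: mid-breath (TLC+FRC)/2
    seg = [
        0.5 * (completed_tlc.branches[bid].diameter_mm + completed_frc.branches[bid].diameter_mm)
        for bid, b in completed_tlc.branches.items()
        if b.region in SEGMENTAL_AVERAGE_SET
    ]
    variables["Dave_segmental_mm"] = float(np.mean(seg))
    term = [
        0.5 * (completed_tlc.branches[t].diameter_mm + completed_frc.branches[t].diameter_mm)
        for t in completed_tlc.terminal_ids()
    ]
    variables["Dave_terminal_mm"] = float(np.mean(term))
    variables["terminal_count"] = float(len(term))

    return SubjectResult(subject.subject_id, subject.group, True, "", variables)


#: variables entering the two-group comparison family, in report order
def _comparison_variables(results: list[SubjectResult]) -> list[str]:
    keys = set()
    for r in results:
        keys.update(r.variables)
    ordered = ["Age_years", "BMI", *PFT_VARIABLES]
    regions6 = ["LUL", "LLL", "RUL", "RML", "RLL", "Total"]
    ordered += [f"Emph%_{r}" for r in regions6] + [f"fSAD%_{r}" for r in regions6]
    ordered += [f"Dh*_{r}" for r in REGIONS_11] + [f"WT*_{r}" for r in REGIONS_11]
    ordered += ["Dave_segmental_mm", "Dave_terminal_mm"]
    ordered += [f"Dave*_FRC_{r}" for r in regions6] + [f"Dave*_TLC_{r}" for r in regions6]
    ordered += ["P_alv_PI_Pa", "P_alv_PE_Pa", "neg_P_pl_PI_Pa", "neg_P_pl_PE_Pa",
                "P_tp_PI_Pa", "P_tp_PE_Pa"]
    return [v for v in ordered if v in keys]


def run_pipeline(config: RunConfig | None = None,
                 subjects: list[SubjectRecord] | None = None,
                 write: bool = True):
    """Run the full pipeline; returns (results, StatReport, output directory)."""
    config = config or RunConfig()
    daver = DaverTable.default()
    if subjects is None:
        subjects = generate_cohort(config.cohort, daver)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2 ** 20]))

    results: list[SubjectResult] = []
    for subject in subjects:
        try:
            results.append(process_subject(subject, daver, config, rng))
        except Exception as err:
            raise RuntimeError(
                f"pipeline failed at subject {subject.subject_id}: {err}") from err

    included = [r for r in results if r.included]
    comparisons = []
    for var in _comparison_variables(included):
        a = [r.variables[var] for r in included if r.group == "A" and var in r.variables]
        b = [r.variables[var] for r in included if r.group == "B" and var in r.variables]
        if len(a) >= 3 and len(b) >= 3:
            comparisons.append(compare_groups(a, b, variable=var))

    outputs = ["P_alv_PI_Pa", "P_alv_PE_Pa", "neg_P_pl_PI_Pa", "neg_P_pl_PE_Pa",
               "P_tp_PI_Pa", "P_tp_PE_Pa", "Emph%_Total", "fSAD%_Total",
               "Dave*_FRC_Total", "Dave*_TLC_Total"]
    pairs = []
    for x in PFT_VARIABLES:
        for y in outputs:
            xs = np.array([r.variables[x] for r in included])
            ys = np.array([r.variables[y] for r in included])
            pairs.append((x, y, xs, ys))
    report = build_report(comparisons, pairs)

    out_dir = Path(config.out_dir)
    if write:
        _write_outputs(out_dir, config, subjects, results, report)
    return results, report, out_dir


def _write_outputs(out_dir: Path, config: RunConfig, subjects, results, report):
    out_dir.mkdir(parents=True, exist_ok=True)
    per_subject = pd.DataFrame([
        {"subject_id": r.subject_id, "group": r.group, "included": r.included,
         "exclusion_reason": r.exclusion_reason, **r.variables}
        for r in results
    ])
    per_subject.to_csv(out_dir / "subjects.csv", index=False)

    comp = report.comparison_frame()
    groups = {
        "demographics": ("Age_years", "BMI", "FEV1", "FVC"),
        "prm": ("Emph%", "fSAD%"),
        "structure": ("Dh*", "WT*"),
        "diameters": ("Dave_segmental", "Dave_terminal"),
        "constriction": ("Dave*",),
        "pressures": ("P_alv", "neg_P_pl", "P_tp"),
    }
    for name, prefixes in groups.items():
        mask = comp["variable"].str.startswith(prefixes)
        comp[mask].to_csv(out_dir / f"report_{name}.csv", index=False)
    comp.to_csv(out_dir / "report_all.csv", index=False)
    report.correlation_frame().to_csv(out_dir / "correlations.csv", index=False)

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_subjects": len(subjects),
        "n_included": int(sum(r.included for r in results)),
        "prm_thresholds": asdict(config.thresholds),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
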