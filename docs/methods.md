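# Methods

This note documents the models implemented in `pulmoflow`, the defaults
and why they were chosen, what the synthetic cohort does and does not
emulate, and the numerical choices a user should know before trusting or
extending the results.

## Healthy-reference geometry

Tracheal diameter is predicted from sex, height and age by a regression
fitted on 222 healthy Korean adults (natural logs; sex coded 0 male /
1 female; height in meters; age in years). Two properties of the
printed equation are implemented exactly as stated and worth knowing:
height has no standalone term for males (it enters only through the
sex interaction and the age×height interaction), and at height = 1 m
both height terms vanish. Inputs are validated to adult, physiological
ranges.

The per-lobe, per-generation healthy diameter ratio table (`Daver`)
ships as a versioned CSV (`pulmoflow/data/daver_table.csv`; columns
lobe, generation, mean, se) loaded at import and overridable by the
user. Upper lobes and the left lower lobe are tabulated for generations
2–7, the right middle lobe for 3–7 and the right lower lobe for 3–10.
Generations deeper than the deepest tabulated entry reuse it (the
ratios flatten with depth); shallower generations are an error rather
than an extrapolation. Standard errors are stored but unused — only the
mean ratio enters prediction. Generation numbering is anatomical:
trachea = 1, each child increments by one, so main bronchi are
generation 2.

The constriction index `Dave* = measured / predicted` is computed per
branch; lobar means and sample SDs (ddof = 1; a single-branch lobe
reports SD 0) over the CT-resolved branches summarize each subject's
constriction state. Multipliers for unresolved branches are drawn from
Normal(mean, SD) per lobe with a rejection floor at 0.05 — a plain
normal draw can be nonpositive and a nonpositive diameter is
unphysical; with SD = 0 the mean is returned exactly so degenerate
configurations stay deterministic.

## Completing the tree beyond CT resolution

Volume filling is recursive binary bisection of a lobar point cloud:
the point set assigned to a branch is split by the plane through its
centroid containing the branch direction; each half spawns a child from
the branch tip toward the half's centroid with length 0.4 × the
distance; recursion stops when a half has fewer than `point_threshold`
points (default 1) or the candidate is shorter than 1.2 mm. When a
lobe has several resolved tips (the usual case), each tip receives the
seed points nearest its distal node. If the centroid happens to lie on
the branch axis the splitting normal falls back to the principal axis
of the lateral point spread, which still separates two clusters.
Growth is fully deterministic given points and parameters; randomness
enters only through diameter multipliers.

Horsfield orders are assigned bottom-up (terminals 1, parent =
max(child orders) + 1). Healthy diameters for grown branches follow
`D(order) = D_anchor × r^(order − anchor_order)`, anchored at the
*predicted* (not measured) diameter of the lobe's attachment branch so
that constriction enters only through the stochastic multipliers. The
ratio `r` is derived per attachment by also anchoring the far end at a
healthy terminal-bronchiole caliber of 0.6 mm at order 1. A fixed
global ratio is available instead (`FillParams.diameter_ratio`), but
volume-filled subtrees are unbalanced — attachment orders vary by
several units between lobes — and a fixed ratio then scatters terminal
calibers over nearly an order of magnitude, which the fourth-power
resistance law amplifies into implausible pressure outliers. Two-point
anchoring keeps healthy terminals at the terminal-bronchiole scale
(population means ≈ 0.55 mm after constriction multipliers) regardless
of local tree depth. After scaling, a child wider than its parent is
capped at the parent's diameter.

## Breathing cycle and moving geometry

Ventilation is `V(t) = (V_t/2)(1 − cos 2πt/T)` with defaults
V_t = 1 L, T = 4 s; flow is its analytic derivative. Geometry is known
at exactly two states (FRC, TLC), so intermediate trees are the linear
per-branch family in the inflation fraction
λ = V/(V_TLC − V_FRC) — with two anchors every interpolant through both
endpoints is linear, and endpoint exactness at λ ∈ {0, 1} is bitwise.
The optional "akima" mode reconstructs the λ(t) time series through an
Akima spline over the discrete knots (with periodic padding), which is
where a spline is meaningful; it cannot and does not change the two
anchor geometries.

Peak inspiration and expiration are the *peak-flow* instants T/4 and
3T/4 by default (`phase_convention`), not the zero-flow turnarounds:
the alveolar pressure is a flow-driven drop, largest in magnitude and
opposite in sign at peak flow, which matches the reported sign pattern
(P_alv < 0 at PI, > 0 at PE). End-inspiration reporting is available as
a config switch. Note that under the quasi-static model the lung
volume, and hence P_tp, is identical at T/4 and 3T/4; differences
between the phases come entirely from the flow direction.

## 1D pressure solver

Flow is apportioned to terminals (each lobe receives its TLC−FRC
air-volume-change share, split uniformly within the lobe) and summed up
the tree, so junction conservation holds by construction. Branch
pressure drop is `ΔP = γ · 128 μ L Q / (π D⁴)` in SI units with
μ = 1.81×10⁻⁵ Pa·s and ρ = 1.20 kg/m³; γ = 1 for the `poiseuille`
model, and for the default `pedley` model
`γ = max(1, (c/4√2)·√(Re·D/L))` with c = 1.85 and
`Re = 4ρ|Q|/(πμD)` — the entrance-effect correction that matters in the
central airways and reduces to Poiseuille in the low-Reynolds
periphery. Node pressures accumulate from the tracheal inlet (gauge
reference 0) along each unique path; `P_alv` is the arithmetic mean
over distal nodes of terminal branches.

Pleural decomposition uses a fixed global compliance
C = 0.2 L/cmH₂O (1 cmH₂O = 98.0665 Pa): `P_tp = V_lung/C`,
`P_pl = P_alv − P_tp`, so the identity `P_tp = P_alv − P_pl` holds to
machine precision by construction. The lung air volume is the
subject's FRC air volume plus the instantaneous tidal volume. Wall
compliance and parenchymal inertance are deliberately omitted — the
solve is quasi-static and resistive on moving geometry — because the
reported outputs are pressures at two phases under a fixed global
compliance; the interface leaves room for those terms. Workload is the
area of the P_pl–volume loop per cycle (Pa·L → J).

The cycle solver is vectorized internally (static topology; per-branch
subtended weights computed once; level-wise cumulative path sums), and
a test pins it to the scalar `distribute_flow`/`solve_timestep`
operations at machine precision.

## QCT metrics

The parametric response map uses the standard thresholds −950 HU
(inspiratory, emphysema) and −856 HU (expiratory, air trapping) as
documented defaults; both are config keys, and results are
threshold-sensitive. Classification order is emphysema first, then
air trapping, then normal. Lobe percentages are voxel counts; the
pooled "Total" row is voxel-count-weighted, not a mean of lobes.

Hydraulic diameter is 4A/P. `Dh*` normalizes by the subject's
predicted tracheal diameter; `WT*` by a reference wall thickness that
is pluggable (constant or callable of demographics) and defaults to
1.5 mm — the published reference equation for predicted tracheal wall
thickness is not available, and the choice only rescales `WT*`, never
group contrasts. The five s-prefixed regions average unweighted over
their constituent segments (sRUL: RB1–3; sRML: RB4–5; sRLL: RB6,
RB8–10; sLUL: LB1–5; sLLL: LB6, LB8–10).

## Statistics

Each variable is tested per group for normality (Shapiro–Wilk,
α = 0.05); only if both groups pass is Welch's unequal-variance t-test
used (group sizes 24 vs 12 make pooled variance fragile), otherwise a
two-sided Mann–Whitney U with the tie-corrected normal approximation
and no continuity correction (identical samples then give p = 1
exactly); exact enumeration is used below n = 12 per group when
tie-free. If every observation across both groups is tied the
comparison reports p = 1 rather than an undefined statistic. All
comparisons of a pipeline run — demographics, spirometry, QCT,
diameters, constriction and pressures (62 with the default variable
set) — form one Benjamini–Hochberg family whose membership is explicit
in the report, and adjusted values are reported as Q-values. Spearman
correlations (mid-rank ties, t-approximation p) link the six
spirometry variables to ten computational outputs.

## Synthetic cohort: what it emulates, and what it does not

Each subject consists of demographics, a CT-resolved tree at TLC and
FRC, lobar point clouds and air volumes, registered density pairs,
structural measurements for the 11 regions, and spirometry. Group
defaults carry the published group means/SDs: sizes 24/12, sex counts
4/20 vs 8/4, ages 62.6 (11.1) / 63.7 (13.1), BMI, the six spirometry
variables, lobar FRC `Dave*`, lobar Emph%/fSAD%, and central-region
`Dh*`/`WT*` per group. Heights are not published; defaults are
Normal(1.70, 0.06) m for males and Normal(1.57, 0.055) m for females.

Choices that require justification:

- **TLC constriction means.** Only FRC `Dave*` columns are available.
  TLC means are encoded as FRC means + 0.15, minus a 0.05 decrement for
  the FAO-like group. The offset puts healthy-side lobes near
  `Dave* ≈ 1` at TLC (the reference ratios derive from inspiratory CT)
  and guarantees, together with a per-branch standard-normal deviate
  shared between the two states, that every branch is strictly wider at
  TLC than at FRC; the decrement preserves the reported direction
  (lower TLC `Dave*` with FAO). These are assumptions, flagged as
  such, and configurable.
- **Lung air volumes.** FRC air volume defaults to Normal(1.28, 0.35) L
  without FAO and Normal(1.82, 0.45) L with FAO. The means are
  calibrated through `P_tp = V/C` to the published transpulmonary
  pressures (≈871 vs ≈1138 Pa at peak inspiration); the group gap
  represents air trapping and is what drives the pleural-pressure
  contrast under the shared global compliance.
- **Density mixture.** Voxel pairs are drawn from a three-component
  bivariate-normal HU mixture (emphysematous, air-trapped, normal
  tissue) whose weights are solved per lobe from a 3×3 linear system so
  the *expected* classified percentages equal the subject's targets
  exactly. Component parameters are chosen with small cross-threshold
  leakage so that the very small published emphysema targets
  (< 0.1%) remain reachable. Per-subject lobar targets are drawn from
  a moment-matched lognormal — the published SDs exceed the means, and
  a zero-truncated normal would inflate cohort means roughly twofold,
  while the lognormal preserves the published mean and SD exactly.
- **Resolved-tree scale.** The template carries the trachea, main
  bronchi, the six standard central regions, 19 labeled segments and
  two subsegmental children per segment (~66 resolved branches, ~13
  per lobe, comparable to the published per-subject airway counts of
  94–143). The subsegmental level is essential: with only 3–5
  resolved branches per lobe, per-subject estimates of the lobar
  `Dave*` SD are so noisy that occasional inflated estimates propagate
  into the unresolved tree and produce kilopascal-scale pressure-drop
  outliers.
- **Peripheral scale.** 768 seed points per lobe (~3,800 terminals)
  stand in for the ~30,000 terminal bronchioles of an adult lung. The
  simulated pressure drops are therefore a few hundred pascals instead
  of the published tens of pascals — a known, roughly 4× parallelization
  deficit — while every sign and group contrast is unaffected. Lobar
  point clouds are uniform fills of axis-aligned ellipsoids sized to
  the lobar air volumes; their shape affects branching geometry, not
  any solver contract.

What passing tests on this cohort demonstrate: that the pipeline's
operations are correct against closed forms and enumeration oracles,
that generator parameters are recovered within Monte-Carlo error, and
that the published qualitative group contrasts (higher fSAD%
everywhere, larger −P_pl and P_tp at both phases with FAO, alveolar
pressure negative at peak inspiration and positive at peak expiration,
no significant diameter difference) emerge from the stated group
parameterizations. What they cannot demonstrate: agreement with the
published cohort-level numbers, which depend on the 36 patients' CT
scans; scanner noise, registration error and real anatomical
variability are all outside the generator's scope. One synthetic
behavior worth noting mirrors a published caveat: the mostly-female
non-FAO group has smaller predicted tracheal diameters and therefore a
*larger* baseline airway pressure drop, which partially offsets the
constriction effect in `P_alv` — consistent with the published
non-significant alveolar-pressure difference and the sex-imbalance
limitation.

## Numerical choices and degenerate inputs

- Problem sizes: the default run is 36 subjects, 768 points/lobe and
  40 time steps (≈45 s on one CPU); unit tests use 5–9 subjects,
  16–64 points/lobe and 8–20 steps.
- Seeding: one master seed spawns independent per-subject generators
  (`numpy` SeedSequence), so cohorts are reproducible subject-by-subject
  and runs are bit-identical under a fixed config.
- Flow weights must sum to 1 within 1e-9; junction conservation is by
  construction and tested to 1e-9 relative.
- Zero flow yields exactly zero pressure everywhere; SD-zero
  constriction statistics yield deterministic diameters; λ outside
  [0, 1] and volumes outside [0, TLC−FRC] are errors, not clamps
  (except the final λ(T) knot, which is closed to λ(0) exactly).
- Trees are validated (single root, connectivity, parent-child node
  sharing, generation increments, positive geometry) after generation
  and again after completion; CSV round-trips use exact float parsing.

## Known limitations

- Quasi-static resistive solve: no wall compliance, inertance or gas
  compressibility; P_tp is symmetric between the two peak-flow phases
  by construction, so pressure hysteresis arises only from the flow
  term.
- Single global pleural decomposition; no regional compliance.
- The energy-balance closure is Poiseuille/Pedley; turbulence and
  bifurcation losses beyond the entrance correction are not modeled.
- The comparison family has 62 members with the default variable set;
  its membership is explicit in the report output, and analyses that
  need a different family should define it there rather than rely on a
  hard-coded count.
- Synthetic anatomy is schematic (fixed template + ellipsoid lobes);
  branch angles carry no anatomical meaning beyond centroid geometry.
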