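# pulmoflow

Asthma with **fixed airway obstruction** (FAO, post-bronchodilator
FEV₁/FVC < 0.7) carries worse lung function than asthma with reversible
obstruction, but spirometry alone says little about *where* and *how* the
obstruction loads the lung. Quantitative CT (QCT) plus a one-dimensional
airway-network flow model can: airway calibers and wall thickness measure
structural remodeling, registered inspiratory/expiratory densities
classify emphysema and functional small-airway disease, and a dynamic 1D
pressure solve over a breathing cycle turns the anatomy into alveolar,
pleural and transpulmonary pressures that can be contrasted between
groups.

`pulmoflow` implements that whole CT-to-computation chain for people who
want to study it without patient data: a **synthetic two-group cohort
generator** (parameterized by published group means/SDs) feeds every
downstream stage, so the complete pipeline — reference airway geometry,
stochastic completion of the tree beyond CT resolution, dynamic 1D
flow/pressure simulation, QCT metrics, and the group-comparison
statistics — runs end to end on a laptop. It is aimed at researchers in
computational respiratory physiology who want a testable, seedable
reimplementation of this class of analysis.

## The model in brief

**Healthy reference.** Predicted tracheal diameter (mm) from sex
(0 male / 1 female), height (m) and age (y):

    D_trachea,pred = 12.79 − 0.13·ln(age) − 5.82·ln(height)·sex + 3.01·ln(age)·ln(height)

A per-lobe, per-generation table of healthy diameter ratios `Daver` gives
`D_ave,pred = D_trachea,pred × Daver`, and the constriction/dilation index
is `Dave* = D_ave / D_ave,pred` (≈1 in health).

**Tree completion.** CT resolves airways to ~2 mm. Beyond that,
branches are grown into each lobe by recursive volume filling of a lobar
point cloud, ordered bottom-up (Horsfield: terminals 1, parent =
max(children)+1), given healthy diameters by a power law in order
anchored at the segmental prediction and a 0.6 mm terminal caliber, then
multiplied by per-branch draws from the lobe's Normal(mean, SD) of
`Dave*` — the measured constriction statistics propagate stochastically
into the unresolved periphery.

**Dynamics and pressures.** A sinusoidal tidal waveform (1 L, 4 s)
drives flow; geometry interpolates between the FRC and TLC states.
Branch pressure drops are Poiseuille with an optional Pedley
entrance-effect correction; node pressures accumulate from the tracheal
inlet (gauge 0). `P_alv` is the mean pressure at terminal distal nodes,
and with a fixed global compliance C = 0.2 L/cmH₂O,
`P_tp = V_lung/C` and `P_pl = P_alv − P_tp`. Pressures are reported at
peak inspiration (PI, t = T/4) and peak expiration (PE, t = 3T/4), plus
workload `|∮ P_pl dV|` and the pressure–volume hysteresis loop.

**QCT metrics.** The parametric response map classifies each registered
density pair: emphysema if inspiratory HU < −950, else fSAD if
expiratory HU < −856, else normal; Emph%/fSAD% are reported per lobe and
pooled. Hydraulic diameter (Dh = 4A/P) and wall thickness over 11
standard regions are normalized to `Dh*` and `WT*` by the predicted
tracheal diameter and a reference wall thickness.

**Statistics.** Per variable: Shapiro–Wilk gates between Welch's t-test
and Mann–Whitney U; all p-values form one Benjamini–Hochberg family
(Q-values); Spearman correlations link lung-function variables to the
computational outputs.

## Worked example

```python
from pulmoflow import Demographics, DaverTable, predict_trachea_diameter, \
    predict_generation_diameter

demo = Demographics(sex=0, height=1.70, age=60)
table = DaverTable.default()
print(f"predicted tracheal diameter: {predict_trachea_diameter(demo):.3f} mm")
print(f"predicted LUL generation-4 diameter: {predict_generation_diameter(demo, 'LUL', 4, table):.3f} mm")
```

    predicted tracheal diameter: 18.797 mm
    predicted LUL generation-4 diameter: 5.451 mm

A 60-year-old man of 1.70 m is predicted an 18.8 mm trachea; the
left-upper-lobe generation-4 average caliber is that times the 0.290
healthy ratio. Dividing a measured diameter by these predictions yields
`Dave*` per branch.

The full pipeline from the shell:

```bash
pulmoflow run --seed 1 --out demo_run
```

    included 36/36 subjects; 43/62 comparisons significant at Q < 0.05
    outputs written to demo_run

`demo_run/report_pressures.csv` then holds the simulated group contrast
(group A = without FAO, n = 24; group B = with FAO, n = 12):

    variable        mean_a    sd_a    mean_b    sd_b    test          p      Q
    P_alv_PI_Pa     -225.0    96.9    -158.9    64.5    mann_whitney  0.065  0.086
    neg_P_pl_PI_Pa  1135.3   159.7    1241.1   214.1    t_test        0.148  0.180
    neg_P_pl_PE_Pa   685.2   232.0     923.4   191.1    t_test        0.003  0.007
    P_tp_PI_Pa       910.3   173.9    1082.3   192.4    t_test        0.017  0.026

Alveolar pressure is negative at peak inspiration (a pressure drop
relative to the trachea) and positive at peak expiration; the FAO-like
group carries larger pleural-pressure magnitudes and transpulmonary
recoil at both phases, driven by its air trapping (larger FRC volume)
and airway constriction. Other subcommands: `pulmoflow cohort` (write a
synthetic cohort as CSV), `pulmoflow simulate` (one subject),
`pulmoflow report` (re-run statistics on an existing run directory).

## Layout

| module | contents |
| --- | --- |
| `reference_model` | tracheal regression, `Daver` table, `Dave*`, lobar statistics, multiplier sampling |
| `tree` / `tree_completion` | airway-tree container and I/O; volume filling, Horsfield orders, diameter assignment |
| `breathing` | tidal waveform, inflation fraction, FRC→TLC geometry interpolation |
| `flow_solver` | flow apportionment, branch resistance, pressure field, pleural decomposition, breath simulation |
| `qct` | parametric response map, hydraulic diameter, Dh*/WT* over the 11 regions |
| `stats` | normality-gated tests, BH adjustment, Spearman correlations, report assembly |
| `cohort` | synthetic two-group subject/cohort generator, QC filter |
| `pipeline` / `cli` | orchestration, config, outputs; `pulmoflow` console script |

See `docs/methods.md` for the modeling assumptions, parameter defaults
and known limitations.
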