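# cargoquant

Quantification of intracellular cargo transport for motor-protein cell
biology: how hard and how long dynein teams pull lipid-droplet cargo against
an optical trap, how much opposing motor teams deform lysosomes, how
organelles alternate directed runs and pauses, and where they sit between
the perinuclear region and the cell periphery.

## What it computes

**Escape-attempt analysis.** A cargo held in an optical trap of stiffness
*k* (pN/nm) makes successive *escape attempts*: excursions away from the
trap center that end either in escape (crossing the escape radius, nominally
200 nm) or in failure (detachment and high-velocity snapback to the center).
From a 2 kHz position trace the parser extracts, per attempt *i*: the peak
force `F_i = k · max|x|`, the persistence time (time with force above a
configurable fraction — default half — of that attempt's peak), and the
outcome. Cohorts are aggregated two-level (cargo means within experiment,
then mean ± s.e.m. across experiments) into an *adaptation profile*; the
escaped fraction *f* at each attempt carries the binomial error
`sqrt(f(1−f)/n)` over the *n* cargos that made the attempt.

**Lysosome deformation.** Each time-lapse frame is background-filtered,
Otsu-thresholded and labeled; each object contributes its equivalent-ellipse
eccentricity `e = sqrt(1 − (b/a)²)` (0 = circle, → 1 = elongated) once per
frame, gated to areas of 8–200 px². Pooled per-condition distributions are
compared with the two-sample Kolmogorov–Smirnov test.

**Run–pause motility.** 2-D tracks are projected on a motility axis and
parsed into runs (directed, roughly constant velocity) and pauses
(sub-threshold displacement), with direction-resolved run lengths, pause
durations, and the directional switching probability
`reversals / (reversals + same-direction resumptions)`.

**Perinuclear vs peripheral distribution.** The perinuclear region is the
20% of cytoplasm area nearest the nucleus (grown by Euclidean distance from
the nucleus boundary); the readout per cell is
`100 · (I_total − I_perinuclear) / I_total`.

A `synthetic` module generates ground-truthed stand-ins for every input —
trap traces with condition-dependent per-attempt trends, organelle stacks
with controllable high-eccentricity tails, run–pause tracks, and cell images
with a peripheral placement bias — so the whole pipeline is testable without
any experimental data. The shipped condition parameter sets are synthetic
choices, not measurements.

## Worked example

```sh
python examples/01_force_adaptation.py
```

simulates a wild-type-like and a kinase-knockdown-like cohort
(3 experiments × 15 cargos each), parses every trace, and prints the
adaptation profiles. Abbreviated output:

```
=== WT ===
               mean_peak_force  mean_persistence  escaped_fraction  n_cargos
attempt_index
1                        2.928             1.013             0.044        45
3                        4.022             1.860             0.000        41
5                        6.240             2.494             0.139        36
trend: +0.82 pN/attempt force, +0.35 s/attempt persistence

=== CDK5_KD ===
1                        2.685             1.303             0.000        45
3                        2.096             0.977             0.000        45
5                        1.384             0.466             0.000        44
trend: -0.33 pN/attempt force, -0.22 s/attempt persistence
```

Reading it: in the WT-like condition the motor team pulls harder
(2.9 → 6.2 pN) and persists longer (1.0 → 2.5 s) at each successive attempt,
and the escaped fraction rises — the force-adaptation signature. In the
knockdown-like condition both decline. `n_cargos` shrinks with attempt index
because cargos that escape stop contributing.

The other examples cover lysosome eccentricity + KS comparison
(`02_lysosome_shape.py`), run–pause parsing (`03_run_pause_motility.py`),
and the peripheral-fraction readout (`04_perinuclear_distribution.py`).

A thin CLI wraps the same stages:

```sh
cargoquant demo --seed 1 --out demo_out
cargoquant simulate --kind tracks --seed 3 --out sim
cargoquant analyze-tracks --tracks sim/tracks.csv --condition WT --out results
```

## Layout

- `src/cargoquant/trap.py` — escape-attempt parsing, adaptation profiles
- `src/cargoquant/morphology.py` — segmentation, eccentricity, KS comparison
- `src/cargoquant/tracks.py` — run–pause parsing, motility summaries
- `src/cargoquant/distribution.py` — perinuclear band, peripheral fraction
- `src/cargoquant/stats.py` — shared two-sided tests and star annotations
- `src/cargoquant/synthetic.py` — ground-truthed generators
- `src/cargoquant/io.py`, `cli.py` — CSV/TIFF/JSON schemas, reports, CLI
- `docs/methods.md` — models, conventions, parameter defaults, limitations
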