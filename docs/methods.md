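# Methods

This note documents the models, conventions and numerical choices behind
each stage, what the synthetic generators do and do not emulate, and the
known limitations.

## Trap force model and attempt parsing

Force is the linear trap restoring force `F = k·x`, with `x` the cargo
position relative to the trap center (minus-end excursions positive by
convention) sampled on a uniform grid (nominally 2 kHz; the parser rejects
grids non-uniform beyond 1 part in 10³). The parser:

1. smooths the position with a moving average (default 25 ms) — without it,
   the maximum of ~10 nm white position noise over a multi-second stall
   plateau would bias peak forces upward by several noise SDs;
2. marks an attempt wherever smoothed force exceeds the onset threshold
   (default 0.5 pN above the zero baseline), merging sub-threshold gaps
   shorter than 50 ms and discarding excursions shorter than 20 ms;
3. reports per attempt the peak force `k·max|x|`, the **persistence time**
   as the total time with force at or above `peak_fraction` (default 0.5) of
   that attempt's peak — a symmetric, noise-robust reading of "time over
   which force is maintained"; the fraction is a parameter because an
   absolute-threshold convention is equally defensible;
4. classifies the outcome: *escaped* if the excursion crosses the escape
   radius (default 200 nm) without returning below the onset threshold,
   otherwise *failed*. A high-velocity return (snapback faster than 5 µm/s
   sustained ≥ 5 ms, measured on a lightly smoothed derivative) is detected
   and available diagnostically, but a returned excursion is failed whether
   or not the return was fast.

Adaptation profiles aggregate in two levels — cargo-level values averaged
within each experiment, then mean ± s.e.m. across experiments — so that
experiments, not cargos, are the units of replication. Escaped fractions
pool cargos, with SE `sqrt(f(1−f)/n)`. Attempt-k-vs-attempt-1 comparisons
use two-sided Student t-tests on the per-experiment means (Welch available).
With a single experiment the profile is emitted with SEMs flagged
unavailable. Only attempt indices 1–5 are aggregated by default, matching
the five-attempt design of the measurements.

## Trap-trace generator

Per cargo, attempt `i` draws a latent peak force
`F_i = max(0.2 pN, F₁ + β_F(i−1) + ε)` and persistence
`τ_i = max(0.05 s, τ₁ + β_τ(i−1) + ε)` — linear-in-attempt with truncation,
the simplest model consistent with the observed monotone trends; escape is
Bernoulli with `p = logistic((F_i − midpoint)/steepness)`, a smooth
stand-in for an unmodeled outcome process. The trace is a piecewise-linear
skeleton plus white Gaussian position noise (default 10 nm): ramp at the
loading rate (default 4 pN/s) to the stall position `F_i/k`, hold for
`τ_i`, then either snap back to center (≥ 15 µm/s, within 10 ms) and rest
0.5 s, or — on escape — rise monotonically to
`max(1.15 × escape radius, 2.5 × stall position)` and terminate after a
30 ms recorded plateau. The 2.5 factor keeps the stall plateau safely away
from half of the escape peak; with a fixed exit target the plateau can land
exactly at the half-max persistence threshold, making the measured
persistence a knife-edge coin flip. Attempts whose stall force exceeds the
trap's maximum restoring force at the escape radius (`k × 200 nm`) are
escapes by construction.

Ground truth records the *realized* peak force and half-max persistence of
the noiseless skeleton — the estimands the parser targets — rather than the
latent draws. For failed attempts the realized persistence is
`τ_i + F_i/(2·loading rate)` plus a negligible snapback term; the constant
ramp term cancels in slope estimates, and per-attempt slope comparisons are
made against slopes fitted to the ground-truth records the same way.

Default condition parameter sets (`data/conditions.yaml`) are synthetic:
WT-like (β_F = +0.6 pN, β_τ = +0.35 s per attempt), CDK5-knockdown-like
(−0.3 pN, −0.15 s), and a flat cofactor-knockdown-like set. Forces sit in
the 2–7 pN range typical of small motor teams; only the signs and rough
magnitudes of the trends are meaningful. White position noise (no
Ornstein–Uhlenbeck bead dynamics, no corner-frequency structure) is
deliberate: it stresses the parser without modeling trap hydrodynamics.

## Organelle morphology

Segmentation is median filtering (disk radius 2 px by default; 0 disables)
followed by Otsu thresholding and 8-connected labeling; border-touching
objects are kept by default (a documented switch excludes them).
Eccentricity comes from the equivalent ellipse of second central moments
(`skimage.regionprops`), `e = sqrt(1 − (b/a)²)`. Detections are gated to
areas of 8–200 px² before pooling. Pooling takes the first `n_frames`
(default 100) of each per-cell stack and adds every per-frame per-object
value with **no** deduplication across frames: deformations are dynamic and
each frame is an instantaneous determination. Histograms use fixed 0.05-wide
bins on [0, 1]. Distributions are compared with the two-sample KS test on
the pooled values.

Numerical caveat: `e` has infinite slope in the axis ratio at `e = 0`, so
for near-circular objects half-pixel rasterization asymmetry alone reads as
`e ≈ 0.07–0.1`. The estimator is validated to ±0.03 on clearly elliptical
rasterized shapes (`e ∈ [0.5, 0.95]`, semi-major 10–25 px); a rasterized
disk is validated separately (reads ≤ 0.05, exactly 0 when rendered on an
integer center). For the same reason the synthetic renderer rasterizes
objects on integer pixel centers — sub-pixel placement would contaminate
shape ground truth with pixelation asymmetry. The generator draws each
object's eccentricity fresh every frame from a two-component mixture (a base
range plus a high tail above 0.9 whose weight is the condition knob), fixes
each object's area, random-walks centroids, and adds Poisson shot noise plus
Gaussian read noise over a constant background. It does not model a realistic
point-spread function, camera-specific noise, or object overlap/occlusion,
so passing tests validate the measurement definitions and statistics, not
robustness to dense or blurred real-world fields.

KS size and power are calibrated on generator eccentricity samples (the
pooled-values stage) at the study scale of ~2000 pooled values per
condition; segmentation accuracy is validated separately on rendered shapes.

## Run–pause parsing

The projection onto a per-cell motility axis (toward-nucleus = minus;
automatic axis inference is out of scope) is smoothed with a 3-frame rolling
mean. A frame is a **pause** iff some full window of the minimum pause
duration (default 0.5 s) covering it has a net displacement rate below the
pause threshold (default 50 nm/s). This covering-window rule is deliberate:
classifying each frame by its own local velocity fragments any pause shorter
than two windows — the middle frames see run motion on both sides — which
silently merges runs and inflates run lengths and switching probabilities.
Run frames take the sign of a centered displacement. Repairs then enforce
the conventions: pauses shorter than the minimum do not break a run
(co-directional neighbors merge; anti-directional neighbors split the
interruption at its midpoint), consecutive co-directional runs merge, and
runs with net displacement below the minimum run length are reclassified as
pauses. Segment distances are measured on the raw projection (smoothing
would clip displacement at track edges); segments tile the track exactly.

The default minimum run length is 50 nm — well above the 10 nm localization
noise (a 5σ net displacement) but small enough not to censor the short-run
mass of an exponential run-length distribution; at 250 nm, for example, 27%
of mean-800 nm runs would be discarded and cohort recovery drops below 90%.
Runs shorter than a frame interval appear as displacement jumps between
pauses and are still recovered as runs with the correct direction.

The track generator alternates exponential run lengths (traversed at
constant speed, direction reversing after each run with the switching
probability) with shifted-exponential pauses (floor 0.6 s, default mean
1.5 s): the floor keeps essentially all true pauses above the parser's
0.5 s design resolution, so ground truth stays within what any parser at
10 fps could in principle recover. Localization noise is isotropic Gaussian
(default 10 nm). Real tracks additionally contain diffusive pauses, curved
paths and heterogeneous speeds, which this generator does not emulate.

## Perinuclear band and peripheral fraction

The band is grown from the nucleus boundary by Euclidean distance: cytoplasm
pixels sorted by (distance, row, column) are added until the band area first
reaches the target fraction (default 20%) of the cytoplasm, so the split is
deterministic and exact to one pixel. The peripheral readout is
`100 × (I_total − I_perinuclear)/I_total` with `I_total` summed over the
whole cell mask — the literal reading of the subtraction definition, which
counts any nuclear-region signal toward the periphery; `include_nucleus=False`
restricts the total to the cytoplasm. Condition comparisons report both a
two-sample t-test on per-cell fractions and a two-proportion z-test (pooled
variance, continuity correction off by default) on effective counts — the
sum of per-cell fractions with n = number of cells; the t-test is the more
powerful of the two at typical cell counts. Masks are inputs; automated
cell/nucleus segmentation is provided only for synthetic images.

## Statistics layer

All tests are two-sided: Student's t (Welch optional), two-proportion z,
two-sample KS, and the Wilcoxon signed-rank test for paired samples. Star
annotations use strict thresholds *p* < 0.05 / 0.01 / 0.001 / 0.0001. No
multiple-testing correction is applied by default, matching per-comparison
reporting; a Benjamini–Hochberg helper is provided. Each test's type-I
error is checked to be within ±3% of the nominal 5% over 200 seeded null
replicates.

## Seeding and reproducibility

A single master seed drives every generator through fixed, documented
substreams (`trap=0`, `organelles=1`, `tracks=2`, `cell=3` spawn keys of the
master `SeedSequence`), so outputs are bit-reproducible and adding one stage
never perturbs another. Reports embed the seed, parameters and package
version, and re-running a configuration reproduces byte-identical tables.

## Problem sizes used in validation

Cohort-level checks run at the study's natural scale: 200 cargos for parser
parameter recovery; 50 replicates of 5 experiments × 30 cargos per condition
for the adaptation-trend pattern; ~2000 pooled eccentricity values per
condition (18 cells × ~100 frames worth) with 200 replicates for KS
size/power; 90 tracks × 100 s for motility recovery; all (escaped, n)
pairs with n ≤ 1000 for the binomial-error enumeration. Examples use
smaller cohorts for readability.

## Known limitations

- The trap model is kinematic: no bead relaxation dynamics, no trap
  anharmonicity, no double-trapping events (assumed handled upstream).
- Persistence for *escaped* attempts under the half-max convention reflects
  the exit transient, not the stall duration; cross-condition persistence
  trends are dominated by failed attempts.
- Segmentation equivalence with any particular legacy implementation is not
  claimed; only the stated definitions (median/Otsu, moments-based
  eccentricity, 8-connectivity, area gate) are implemented.
- The run–pause parser's thresholds are conventions, not inferred from the
  data; all are config-exposed and only synthetic ground-truth recovery is
  claimed.
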