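# Methods

`adiposeg` implements an automated pipeline for quantifying abdominal
adipose-tissue compartments — subcutaneous (SAT) and visceral (VAT) fat —
from T1-weighted-like MRI volumes, and for comparing a CNN segmentation
against an intensity-driven reference method at the cohort level.  Because
no patient MRI data are distributed with the package, every experiment runs
on synthetic phantoms with exact ground truth; this note describes the
models, the phantom, the numerical choices, and what the phantom results do
and do not show about real data.

## Image model and phantom cohort

On T1-weighted images fat is hyperintense, which is the physical basis of
both segmentation methods.  A phantom subject is an elliptical body
cross-section swept along z with a smooth "waist" profile:

* a SAT annulus of configurable thickness just inside the skin
  (intensity 200, arbitrary units),
* a mid-intensity organ interior (100),
* z-elongated, tilted VAT blobs inside the abdominal cavity (200), sized so
  that a target fraction of the cavity area is fat,
* optional bone confounders — spine and, on inferior slices, hip bones —
  drawn as a dark marrow core (40) with a bright, deliberately fat-like
  cortical rim (190), labelled *background* in the ground truth,
* a second-order polynomial multiplicative bias field (default relative
  amplitude 0.15), the standard low-order model of coil/field inhomogeneity,
* Rician noise (default σ = 4 % of the fat intensity), the magnitude-MRI
  noise model: `sqrt((I+n₁)² + n₂²)` with Gaussian `n₁, n₂`.

The ground-truth label map is noise-free by construction; SAT and VAT are
disjoint, and the SAT annulus never touches a VAT voxel.

The two-group cohort injects a VAT/SAT-ratio effect the way it appears in
wasting disease: patients draw a higher cavity fat fraction
(0.30 ± 0.07 vs 0.15 ± 0.05) and a thinner subcutaneous layer
(15 ± 2.5 mm vs 18 ± 3 mm).  On the desk geometry this yields ground-truth
VAT/SAT ratios of roughly 0.07 ± 0.03 (controls) vs 0.23 ± 0.07 (patients).
All subject parameters derive deterministically from
`(base_seed, group, index)`.

Two geometry presets exist:

| preset | grid | voxel (mm) | field of view |
|---|---|---|---|
| protocol | 384×384×36 per station | 1.25×1.25×6 | 480 mm |
| desk (default) | 64×64×12 | 3×3×6 | 192 mm |

The desk preset is the package's own scaled study condition: it preserves
slice thickness, body-to-field-of-view proportions, compartment contrast
and the confounders, at a resolution where the full pipeline (including CNN
training on one CPU) runs in minutes.  Tests and the acceptance script use
it throughout; the protocol preset remains available for full-scale runs.

What the phantom does **not** model: organ heterogeneity and partial-volume
mixtures, Dixon-type water–fat ambiguity, arms (deliberately absent — the
body-mask stage is instead exercised with synthetic lateral distractor
blobs), peristaltic/respiratory motion within a station, and anatomically
realistic bone shapes.  Passing phantom tests therefore demonstrates
correctness of the algorithms and the detectability of a group effect
through the full pipeline — not clinical-grade segmentation accuracy.

## Preprocessing

* **Station registration.**  Whole-body acquisitions arrive as 2+
  overlapping stations (1–3 shared slices).  Per junction, the displacement
  of the superior station is estimated by minimising the mean squared
  intensity difference over the overlap as a function of a 3-DOF
  translation — first an exhaustive integer-voxel grid search within the
  ±3-voxel bound (ties break toward the smaller displacement), then
  Nelder–Mead simplex refinement with two restarts from perturbed starts;
  trilinear interpolation handles fractional shifts.  Rotation and
  deformation are out of scope.  A genuine identifiability limit: a pure
  through-plane shift approaching the overlap extent is only recoverable
  because the phantom (like real anatomy) varies along z; on z-invariant
  content the cost surface is flat in dz and the tie-break returns 0.
* **Merging.**  The superior station, shifted back by its estimated
  displacement, overwrites the overlap (no blending) — deterministic and
  free of double-counting; averaging would be a one-line change.
* **Supersampling.**  Trilinear resampling to 1.2 mm isotropic voxels
  (36 slices × 6 mm → 180 slices); nearest-neighbour for label maps so
  classes stay in {0, 1, 2}.  Grid-aligned zoom makes the operation exact
  on constants and idempotent on already-isotropic volumes.
* **Median filtering.**  3×3×3 voxelwise median (reflection at edges), the
  smallest isotropic kernel; configurable.
* **Body mask.**  Quantile threshold (default 0.5), per-slice largest
  8-connected component, holes filled.  This is the automated surrogate for
  interactive arm removal: disconnected lateral structures are discarded.

## Reference segmentation (intensity + connectivity)

Semi-automatic reference protocols of this family select fat voxels by a
predefined intensity range and connectivity.  Here the
range is derived from the within-body histogram: 64 bins, Gaussian-smoothed
(σ = 1.5 bins), peaks found after zero-padding (so edge modes count); the
highest-intensity mode is fat, and the range is
`[mode − k·width, max]` with `k = 2` and `width` the half-height width of
that mode.  A unimodal histogram raises an error advising a manual range.
SAT is the set of in-range voxels inside a 30 mm subsurface band that are
26-connected to the body boundary; VAT is the in-range 26-connected
components of the remaining cavity, dropping components under 5 voxels.
The bright cortical rims of the bone confounders fall inside the fat range,
so this method systematically misassigns some bone voxels to VAT — the
failure mode the CNN comparison is designed to expose.

## CNN segmentation

The network is an encoder–decoder U-Net implemented directly on numpy
(explicit forward/backward passes, verified against finite differences):
three down-sampling steps, per level `convs_per_block = 2` 3×3
convolutions + ReLU then 2×2 max-pooling; feature widths 16/32/64
(bottleneck 128, continuing the doubling pattern); decoder with 2×2-stride
transposed convolutions and skip concatenations; dropout (rate 0.5) at the
bottleneck; 1×1 convolution and per-pixel softmax over 3 classes.  "Same"
padding keeps output resolution equal to input (default 384×384, any size
divisible by 8 works).  Training minimises categorical cross-entropy with
Adam (lr 1e-3, β 0.9/0.999), default 15 epochs at batch size 16, fully
seeded (init, shuffling, dropout).  Slices are min–max normalized per
volume to [0, 1].  No data augmentation and no early stopping.

`UNetSegmenter` follows the scikit-learn estimator protocol (`fit`,
`predict`, `predict_proba`, `get_params`/`set_params`, fitted attributes
`net_`, `history_`), so it plugs into sklearn model selection; the
intensity-based method is wrapped the same way (`ReferenceSegmenter`).

The **desk experiment** shrinks the net to 8/16/32 channels (bottleneck
64) on 64×64 slices, 10 epochs, and uses *weighted* cross-entropy with
class weights (1, 2, 10) for background/SAT/VAT.  Rationale: at desk scale
the training set is ~200 slices (vs tens of thousands at full scale) and
VAT occupies ~1.4 % of pixels; within 10 epochs the unweighted loss never
leaves the "predict no VAT" regime, while weighting by roughly the inverse
class-frequency order restores the compartment without hurting SAT.  The
weights were set once from the observed pixel frequencies
(≈ 0.84 / 0.14 / 0.014).

**Cohort splitting** is subject-level (never slice-level, to prevent
leakage): 50 % train / 6 % validation / 44 % test, stratified within
group × age-tertile × BMI-tertile cells by largest-remainder allocation
under the global quota; strata with fewer than 3 subjects trigger a
fallback to group-only stratification with a warning.

## Evaluation metrics

For reference mask R and prediction P, per class and per axial slice:

* Dice = 2|R∩P| / (|R| + |P|);
* pixel error (%) = 100·|RΔP| / (W·H), the fraction of image pixels on
  which the class masks disagree (Δ = symmetric difference).

Slices where both masks are empty for a class are *excluded* from that
class's averages by default (`empty_policy="exclude"`); scoring them as
Dice 1 is available (`"one"`) since the choice shifts means.  Group
summaries pool all slices of all examinations (mean ± population SD), in
the groups × compartments × metrics layout.  A whole-volume Dice is also
available as a secondary summary.

## Quantification and statistics

Compartment volume = voxel count × dx·dy·dz, reported in mL; the biomarker
is the VAT/SAT ratio (undefined, and an error, at zero SAT volume).  Group
comparison: classical two-tailed Student's (equal-variance) t-test,
α = 0.05; Welch's variant behind a flag.  Method agreement: Pearson
correlation of per-subject volumes, computed per group and compartment;
error bars use SEM = SD/√n.  In `cohort_report` a degenerate contrast
(zero pooled variance, e.g. an undertrained model predicting no VAT at
all) is reported as NaN with a warning rather than aborting the run.

## Problem sizes of the shipped experiments

* Segmentation experiment: 16 + 16 subjects (16 train / 2 val / 14 test
  after the 50/6/44 split), 64×64×12 voxels, 10 epochs — a few minutes on
  one CPU.
* Cohort contrast: the model above applied to fresh seeded 34 + 34
  cohorts; the training is amortised across seeds (the per-seed pipeline
  regenerates, segments, quantifies and tests each cohort).
* Registration checks: 2-station, 48×48×(39–41) noiseless and 5 %-noise
  phantoms with injected shifts up to 3 voxels.

## Known limitations

* The numpy CNN is CPU-bound and roughly an order of magnitude slower than
  a framework implementation; protocol-scale (384×384) training is
  supported but slow.
* The reference method is fully automatic; semi-automatic protocols of
  this family additionally allow interactive repair, which is not
  modelled here.
* Through-plane registration beyond the overlap extent is fundamentally
  under-determined (see above).
* Phantom realism limits (see above): results quantify algorithmic
  correctness and pipeline sensitivity, not clinical accuracy.
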