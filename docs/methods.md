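# Methods

## Problem setting

Zernike phase-contrast nano-tomography (Zernike-nanoCT) resolves the
lacuno-canalicular network (LCN) of bone — ellipsoidal osteocyte lacunae
(~5–20 µm) connected by sub-micrometre canaliculi — at ~100 nm effective
pixel sizes.  The price of the phase-contrast enhancement is two
reconstruction artifacts: a bright *halo* rim hugging material interfaces
and a dark *shade-off* gradient extending into the bone from its edges,
strongest at concave air interfaces and attenuated where the surface is
covered by mounting polymer.  Because these artifacts locally shift gray
values by more than the separation between tissue classes, no global
gray-value rule can segment such volumes; the package instead trains
convolutional networks on incrementally bootstrapped ground truth and
quantifies the segmented LCN in 3D.

`zernseg` implements the full workflow as a tested library: a synthetic
phantom generator reproducing the artifact pathology, two segmentation
architectures with a training protocol, a simulated-annotator bootstrap,
a threshold baseline, LCN morphometry, and the statistical comparisons.

## Phantom generator

The phantom is a bone rod aligned with the z (slice) axis.  Its outer
radius is modulated sinusoidally in angle and z (convexity) and carved by
one Gaussian groove along z (a parameterized concave region,
`concavity_depth_vox`).  A polymer coat covers an angular arc
(`polymer_arc_frac`) of the outer surface.  `n_lacunae` axis-aligned
ellipsoids with semi-axes drawn from `lacuna_radii_vox` are placed inside
the rod and connected by constant-radius tubes along a nearest-neighbour
graph of their centres, guaranteeing connected lacuna–canaliculi units for
the morphometry stage.  Ellipsoid semi-axes are scaled (with up to three
corrective re-rasterizations) so the carved LCN volume matches
`target_porosity_frac` of the rod volume; generation fails with a
configuration error when the requested porosity is unreachable for the
requested lacuna count.

Gray values start from per-class means (`class_means`) and receive:

* **halo** — a Gaussian bright band of width `halo_width_vox` centred on
  every solid/non-solid interface (outer surface and lacunae), amplitude
  `halo_amplitude`;
* **shade-off** — a ramp into the bone from air interfaces: it rises
  linearly across the halo rim (so the rim profile shows the
  characteristic bright maximum before the dark minimum), then decays
  exponentially with depth scale `shade_width_vox`.  The amplitude
  `shade_amplitude` is doubled at the concave groove and multiplied by
  `shade_polymer_attenuation` under the polymer arc;
* **noise** — additive Gaussian, `noise_sd`, clipped to [0, 1].

Labels are four classes (background 0, bone 1, shade_off 2, LCN 3); a
voxel is labelled shade-off when it is bone within `shade_width_vox` of an
air interface and its expected depression exceeds 0.04 gray units, so a
zero-amplitude shade yields a 3-class phantom.  One integer seed drives
all random draws; contrast parameters do not consume random numbers, so a
contrast-shifted phantom (`generate_domain_shifted`) shares its geometry
bit-for-bit with the unshifted one.

Default artifact amplitudes (halo 0.22, shade 0.22, noise 0.04 on class
means 0.12/0.62/0.48/0.28) were chosen once so that the generated
pathology matches the qualitative failure mode of threshold segmentation:
bone and shade-off gray histograms share support and the best
single-threshold bone-vs-rest accuracy stays below 0.98.  What the phantom
does *not* emulate: angle-dependent projection contrast, reconstruction
streaks, spatially correlated noise, and the irregular geometry of real
zebrafish spines.  Passing tests therefore demonstrate that the pipeline
recovers known geometry under artifact-laden contrast, not that any fixed
accuracy carries over to beamline data.

## Architectures and the CPU engine

No deep-learning framework is assumed: `zernseg._nn` is a compact
float32 engine (3×3 'same' convolutions computed as nine shifted GEMMs in
a channels-last layout, 2×2 max-pooling, 2×2 transposed convolutions,
softmax cross-entropy, Adadelta) with hand-written backpropagation,
gradient-checked against finite differences in the test-suite.

* `unet2d` — standard encoder–decoder with skip connections: two
  convolutions per level, channel doubling (`base_channels · 2^level`),
  max-pool down, transposed-conv up, 1×1 softmax head.
* `sensor3d` — a slice-context (2.5D) network: the same 2D encoder is
  applied with shared weights to each slice of an ordered window of
  `context_slices` neighbours; the per-slice bottleneck features are
  merged by a learned 1×1 slice-mixing convolution and decoded (with skip
  connections from the centre slice) into the centre-slice prediction.
  The slice mixer replaces a recurrent aggregation: it provides the same
  inter-slice information path with an exact, simple backward pass.

Defaults: depth 2, base 8 channels, patch 64, context 3.  Whole-volume
inference tiles each slice with 50 % overlap and blends probabilities
under a cosine window (floor 0.1) — deterministic and seam-free.  Edge
slices reflect-pad the context window in z.

## Training protocol

Ground-truth slices are split 80/20 (validation count `round(0.2 n)`,
floor 1).  Patches tile each training slice with 50 % overlap and are
reshuffled each epoch; augmentation applies random 90°-rotations and
flips identically to image and label (lossless for labels).  The
optimizer is Adadelta with the original settings (lr 1.0, ρ 0.95,
ε 1e-6); the loss is categorical cross-entropy.  Training stops at 100
epochs or once the monitored loss has failed to improve the running best
by more than 0.01 % (relative) for ten consecutive epochs.  The monitored
loss is the *validation* loss by default (configurable to training loss);
the 0.01 % rule is interpreted as a relative improvement of the
best-so-far value.  On stopping, the weights of the best monitored epoch
are restored (early stopping with checkpoint restore) and the reported
validation metrics refer to that epoch; this materially reduces
seed-to-seed variance at small scale.

For cross-size comparisons (the accuracy-versus-training-size trend) each
model is additionally scored on one fixed held-out slice cohort disjoint
from every training set, because at scaled-down slice counts a per-run
20 % validation split is a single slice and its Dice is too noisy to
order models by.

Class weighting: the LCN occupies well under 1 % of the voxels.  With the
small epoch budgets of CPU-scale runs, unweighted cross-entropy leaves the
LCN class entirely unlearned, so the pipeline runs (bootstrap, experiment
grid) default to inverse-frequency class weights computed from the
training labels and capped at 50; the reported/monitored losses remain
unweighted.  `class_weights=None` restores the plain protocol.

## Bootstrap and transfer learning

The staged ground-truth workflow trains on a small oracle-labelled cohort
(stage 1), segments the next (evenly z-spaced, superset) cohort with the
stage's slice-context model, passes the predictions through a simulated
corrector, and retrains on the enlarged set.  `oracle_full` restores the
true labels (an idealized annotator); `oracle_partial(p)` corrects each
mislabeled connected region independently with probability p.  Real-data
use replaces the corrector with externally edited label stacks.

Transfer learning re-dimensions the classification head for a merged
class set (shade-off → bone when the target domain lacks the shade
class), initializing merged head channels with the sum of their source
channels and every other layer with the source weights.  With zero
retraining epochs the transferred model reproduces the source model's
class-merged probabilities exactly (merged classes sum probabilities).

### Volume-fraction calibration

Segmentation-derived volume fractions inherit any shift in the model's
class prior, and class-weighted training deliberately shifts it toward
LCN recall.  After each bootstrap stage the pipeline therefore fits a
single additive LCN logit offset (by bisection, deterministic) so that
the predicted LCN voxel count on the labeled ground-truth cohort equals
the labeled count, and applies that offset at prediction time.  The
calibration uses only the slices an annotator would have labeled; the
remaining porosity error is the differential bias between the
ground-truth cohort and the rest of the stack.  `calibrate_lcn=False`
disables it.

## Threshold baseline

Fixed ranges use the published reference intervals (background exactly 0,
LCN 0.05–0.42, shade-off 0.43–0.53, bone 0.54–0.89) as closed intervals;
voxels in the gaps between printed bounds (or above the top bound) take
the class with the nearest interval midpoint, making the classifier
total.  Automatic mode uses multi-level Otsu (≤64-bin histogram,
between-class variance maximization, cross-checked against exhaustive
search in the tests) with bins assigned to classes by brightness order.
Note that between-class variance is mass-weighted: on volumes where the
LCN holds well under a percent of the voxels, multi-level Otsu splits the
heavy background/bone modes rather than isolating the LCN — one more
reason global thresholds fail on these data even before artifacts are
considered.

## Morphometry

1. *cleanup*: per-class 26-connected islands smaller than
   `island_min_vox` (default 27 ≈ a 3³ speck) are reassigned to the
   majority class of their dilated boundary; then per-class morphological
   closing with radius `closing_radius` (default 1).  Defaults were sized
   to remove the few-percent of stray mislabeled voxels CNN outputs show
   on phantoms.
2. *merge and crop*: shade-off is relabelled bone (it is bone material
   under an artifact) and the volume is cropped to the non-background
   bounding box.
3. *porosity*: `100 · V_lcn / (V_lcn + V_bone)` by default; the
   alternative convention `V_lcn / V_bone` is exposed
   (`denominator='bone'`) — at ~2 % porosity they differ by < 0.05
   points.
4. *local thickness*: per-voxel diameter of the largest inscribed sphere
   containing the voxel.  The sphere radius at a candidate centre is the
   Euclidean distance transform minus half a voxel (the surface runs
   halfway between voxel centres), so a single voxel has thickness 1 and
   a digital ball `{|x| ≤ 5}` has maximum thickness 9.2 voxels.  The
   implementation (descending-radius sphere painting) is verified against
   brute-force sphere fitting on ≥20 random ≤20³ masks.
5. *connected units*: 26-connected components of the LCN mask; units
   smaller than `component_min_vox` (default 100) voxels are discarded;
   volumes are `count · (voxel_size_nm/1000)³` µm³.

## Statistics

Wilcoxon signed-rank (two-sided, zero differences dropped) compares the
two architectures' metric columns paired over grid cells; Spearman rank
correlation relates training-data size (and batch size) to validation
metrics.  Exact null distributions are used at small n (full sign
enumeration for n ≤ 12; full permutation for n ≤ 8), normal/t
approximations above; ties receive average ranks; α = 0.05.  No
multiple-testing correction is applied.

## Problem sizes for bundled runs

The test-suite and the acceptance script exercise the pipeline at sizes
chosen for single-CPU runs with the numpy engine:

* parameter recovery: 64×128×128 phantom (8 lacunae, target porosity
  2.1 %), bootstrap stages 8/20/28 slices (the staged 5 %/12 %/16 %
  fractions of a 420-slice stack scaled to 64 slices), slice-context
  model with patch 64, base 8, ≤20 epochs per stage;
* size-vs-accuracy trend: 32×64×64 phantom, training sizes scaled from
  {10, 20, 30, 50, 70} to {5, 7, 9, 12, 16} slices, batch 32, three
  seeds, scored by Spearman correlation of the per-size median held-out
  Dice (within-size seed variability exceeds the between-size increments
  at this scale, so the medians are not expected to be pointwise
  monotone);
* transfer: 32×64×64 phantoms, a contrast-shifted 3-class target domain,
  ≤40 epochs, three seeds.

Full-scale 420×512×512 phantoms are supported by the same code paths.

## Known limitations

* The engine is CPU-bound; large grids at full patch size are slow by
  design of the environment it targets.
* Lacunae are axis-aligned ellipsoids; no orientation distribution or
  surface roughness is modelled.
* The simulated corrector sees oracle labels; real annotator noise is
  only approximated by `oracle_partial`.
* Early stopping monitors a small validation set at small scale, so
  epoch counts carry substantial seed-to-seed variance.
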