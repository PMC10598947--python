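# Methods

`m3mc` implements a cascaded, distance-aware analysis of two adjacent
mandibular structures in CBCT-like volumes: the third molar (M3, label 1)
and the mandibular canal (MC, label 2). The cascade is

1. slice-wise multiclass **segmentation** of both structures (S-Net),
2. a **signed distance map** (SDM) computed from the segmentation,
3. **localization** of the closest M3–MC approach and assembly of a
   fixed-size multichannel crop,
4. a 3-D convolutional **classifier** (C-Net) of the binary buccal/lingual
   course of the canal relative to the molar root,
5. **evaluation** (overlap metrics, per-slice profiles, PR/AP over IoU
   thresholds, ROC/AUC) and **Grad-CAM** explanation of the classifier.

Because clinical CBCT data cannot ship with the package, a parametric
phantom generator provides volumes with known geometry and labels; every
stage is validated against independent oracles on those phantoms.

## Coordinate and label conventions

Grids are indexed `(x, y, z)`, 0-based: `x` is the in-plane left–right
(buccolingual) axis, `y` the second in-plane (mesiodistal) axis, and `z`
the axial slice index increasing inferior → superior. Right-side volumes
are mirrored along `x` onto the left-side convention before analysis
(`flip_right_to_left`, an involution on the data grid), so "buccal" is a
consistent grid direction (+x) relative to the tooth axis. Masks use
0 = background, 1 = M3, 2 = MC. NIfTI I/O goes through nibabel; reading
fails loudly if the header lacks positive voxel spacing rather than
silently assuming one.

## Signed distance map

For a binary mask `B` (by default the union of the M3 and MC labels), the
distance transform `SDT(M)` assigns each foreground voxel of `M` the
Euclidean distance to its nearest background voxel (0 elsewhere). The
signed map is the voxelwise combination

    SDM = (1 − B) · SDT(1 − B) − B · (SDT(B) − 1)

so background voxels carry the positive distance to the nearest structure,
foreground voxels with a background face-neighbour are exactly 0, and
deeper interior voxels are negative. The literal "−1" keeps one-voxel-deep
shells at 0. Between two disjoint structures the positive field forms a
ridge of locally constant value — the geometric cue the classifier learns
from. Two readings of "distance to the boundary" differ by at most one
voxel for interior points; the distance-to-complement reading (distance
from a foreground voxel to the nearest background voxel center) is used
throughout, with no half-voxel offset. Units default to voxel lengths (the
intended data are isotropic); `units="mm"` scales by the voxel spacing and
replaces the literal 1 by one minimal voxel length. The fast path uses
`scipy.ndimage.distance_transform_edt`; `sdm_bruteforce` recomputes the
identical contract by exhaustive all-pairs search (guarded to 10⁴ voxels)
and is the independent oracle in the tests, which require voxelwise
agreement to 1e-9.

## Phantom generator

Each phantom is a 64×64×32 grid at 0.2×0.2×0.2 mm (a desk-scale crop of
the mandible region at clinical voxel size) containing:

* a tooth (label 1): ellipsoidal crown (default semi-axes 7×8×6 voxels,
  center z=22) with two constant-radius root cylinders (radius 2.5 voxels)
  descending to the canal level;
* a canal (label 2): a tube of radius 2.5 voxels running mesiodistally at
  z=9 whose centerline passes at a lateral offset
  `±(root_radius + canal_radius + clearance)` from the tooth axis —
  buccal (+x) or lingual (−x) — and curves away from the tooth
  quadratically toward the volume ends (amplitude 4 voxels). A cortical
  rim (1.5 voxels, bright) surrounds the lumen as intensity only;
* piecewise-constant intensities on a 16-bit-like scale
  (bone 700, tooth 1600, canal lumen 150, rim 1100) plus additive Gaussian
  noise, σ = 200 by default. That noise level (canal/bone contrast-to-noise
  ≈ 2.8, tooth/bone ≈ 4.5) sits at the noisy end of realistic small-voxel
  CBCT and is deliberate: with near-noiseless intensities the raw image
  channel alone would trivially reveal the relationship, which real CBCT
  does not.

`clearance` is the exact lateral surface gap at closest approach
(anchoring structure centers on integer voxel coordinates keeps it exact
under voxelization); `clearance ≤ 0` produces contact. The mask geometry
is a deterministic function of the geometric parameters; the seed drives
only intensity noise and, in `generate_dataset`, per-case jitter of sizes,
curvature, clearance (uniform 0.5–2.5 voxels) and canal level. Class
counts are exact (`round(n · class_balance)`, default 0.5).

The ground-truth rule `relation_oracle` codifies the clinical annotation
geometrically: find the closest M3–MC voxel pair, then test on which side
of the plane spanned by the tooth's principal axis and the mesiodistal
direction the canal point lies (normal oriented toward +x = buccal).
Generator and oracle agree on 100/100 clean phantoms across seeds, and
mirroring a phantom across `x` flips the oracle's answer.

What the phantoms do **not** emulate: beam hardening, streak/ring
artifacts, anatomical context (adjacent teeth, cortical plates, soft
tissue), root morphologies that wrap the canal, and ambiguous borderline
cases that a radiologist would exclude. Passing tests therefore
demonstrate that the pipeline machinery is correct and that the distance
channel carries the relationship signal under controlled conditions — not
clinical performance.

## Networks

No deep-learning framework is part of the dependency set; the networks run
on `m3mc.nn`, a compact numpy engine (reverse-mode autograd, 2-D/3-D
convolution via sliding-window unfolding + matmul, max-pooling with stored
indices, nearest-neighbour upsampling, batch norm, Adam, plateau/step
learning-rate schedules). Every primitive's gradient is checked against
central finite differences in the test suite. All arithmetic is float64 on
CPU.

**S-Net** is a family of 2-D U-shaped slice segmenters with a shared
decoder contract (per level: 2×2 upsampling or index unpooling, optional
skip, two blocks of 3×3 conv + batch norm + ReLU; 1×1 head + softmax over
3 classes):

* `plain_unet` — standard encoder/decoder with skip concatenation;
* `attention_unet` — additive attention gates on the skips;
* `dense_unet` — densely connected encoder blocks with 1×1 transitions
  (random initialization only; no pretrained encoder weights are bundled,
  and requesting them raises);
* `segnet` — no skip concatenation; decoding by max-pooling-index
  unpooling preceded by a 1×1 channel match.

Families are faithful to their topologies at configurable depth/width
rather than to the originals' layer counts, so they train on CPU. Training
uses the soft Dice loss (ε = 1e-6, averaged over the 3 classes including
background; a class empty in both prediction and target scores 1, so
perfect predictions have loss ≈ 0 on structure-free slices) with Adam.
Clinical-recipe defaults: learning rate 2.5e-4, plateau factor 0.5,
patience 25, up to 300 epochs, batch 8. The desk-scale benchmark preset
(used in tests and the acceptance script) is a depth-3, 8-filter plain
U-Net on 64×64 slices, 20 epochs at 1e-3 (the point where the validation loss plateaus) — enough for held-out DSC > 0.9
on phantoms.

**C-Net** stacks levels of 3×3×3 conv + batch norm + ReLU + 2×2×2
max-pooling, then global average pooling → dense → softmax over
(buccal, lingual). Default desk scale: 3 levels, base 8 filters (doubling
per level), 32×32×16 crops; `ClsModelConfig.clinical_scale()` restores the
clinical five-level preset on 256×256×32 crops, where the depth axis
reaches extent 1 before the last pooling — pooling is clamped to 1 on such
axes and logged. Training: cross-entropy of the two-class softmax with
Adam at 1e-3, plateau 0.5/25, up to 100 epochs; batch size 1 is the
clinical default (batch-norm then relies on running statistics at
evaluation), but the benchmarks train batched (4).

## Localization and channel assembly

The classifier crop is centered at the floor midpoint of the closest M3–MC
voxel pair (Euclidean in mm; ties broken lexicographically by `(z, y, x)`
of the M3 then MC point, making the result deterministic). Channels are
stacked in the fixed order (image, mask, sdm): the image min-max
normalized per volume, the mask the binary M3 ∪ MC union, the SDM passed
through unscaled in voxel units. Outside the source grid, image and mask
pad with 0; the SDM pads with the maximum in-crop value, since 0 would
mean "on a boundary" under the sign convention. If a predicted
segmentation lacks a structure, classification is refused with a
diagnostic rather than guessing a center.

## Evaluation conventions

Overlap metrics are computed from voxel counts at volume level: precision
TP/(TP+FP), recall TP/(TP+FN), DSC 2TP/(2TP+FP+FN), IoU TP/(TP+FP+FN),
VOE 1 − |∩|/|∪|, RVD |V_gt − V_pred|/V_gt. Degenerate cases are explicit:
0/0 ratios are defined as 0 and logged; RVD with empty ground truth and
Hausdorff with an empty set are NaN ("flagged missing"). Per-slice
profiles walk axial slices inferior → superior, omitting slices empty in
both masks. Hausdorff is the symmetric max over directed distances between
voxel centers in mm (no percentile variant).

The PR curve over IoU thresholds treats each evaluated case as one
detection of one object: at threshold t the case is a TP iff its IoU ≥ t,
otherwise simultaneously an FP and an FN, so precision and recall coincide
with the fraction of cases passing t; AP is the mean precision over the
distinct achieved recall values. This case-level reading is one of several
possible constructions and is fixed here with the threshold grid
(0.05 steps) configurable. Pooling across case×structure is the default
for "both structures together"; per-structure averaging is available.
ROC/AUC sweeps the class-probability threshold with trapezoidal
integration; tests assert equality with the pairwise concordance statistic
P(s⁺ > s⁻) + ½P(tie).

## Sample size

`required_sample_size` returns the smallest total N (equal groups) whose
exact noncentral-t power for the two-sided two-sample t-test reaches the
target: d = 0.50, α = 0.05, power 0.80 → 64 per group, N = 128. The
closed-form normal approximation (⌈2(z₀.₉₇₅+z₀.₈₀)²/d²⌉ = 63 per group,
126 total) is exposed as the approximation the exact computation refines.
The sentence motivating this computation describes comparing networks on
the same subjects — a paired design — yet the printed N corresponds to the
independent-samples convention of standard power software; the independent
mode is therefore primary and a paired mode (34 pairs at the same
parameters) is available.

## Grad-CAM

Explanations use the gradient of the target-class logit with respect to a
convolutional level's activations (default: the last level before the
pooling head, the usual choice when unspecified): channelwise globally
averaged gradients weight the activation channels, the weighted sum is
rectified, trilinearly upsampled to the crop extent, and max-normalized to
[0, 1] (all-zero rectified maps are returned as zeros). Overlays alpha-blend
a colormapped heatmap over the grayscale slice.

## Desk-scale benchmark conditions

Chosen once as the package's standard CPU-scale experiment and used by the
test suite, the acceptance script, and the examples:

* segmentation: 8 training / 2 held-out phantoms, depth-3 plain U-Net,
  20 epochs — bar: per-structure held-out DSC ≥ 0.8;
* classification: 60 training / 40 held-out phantoms, ground-truth-mask
  crops (isolating the input configuration from segmentation error),
  3-level C-Net, 25 epochs, channel sets {image, sdm} and {image}, plus a
  label-shuffle negative control — bars: {image, sdm} accuracy ≥ 0.9,
  shuffle ≈ chance.

The shuffle control uses a *class-balanced* permutation (exactly half of
each true class receives the opposite label). On a deterministically
separable binary task an unconstrained shuffle lets the learner adopt
whichever label polarity the random assignment happens to favor, making
held-out accuracy bimodal near 0 or 1 instead of chance; balancing nets
the polarity signal to zero, so the control concentrates at 0.5 as a
negative control must.

## Known limitations

* On the desk-scale phantom benchmark the classifier's Grad-CAM mass does
  **not** concentrate on the structures themselves: with an SDM channel the
  far-field distance gradient already encodes the side, and the tiny
  network attends to that background field (region-mean attention inside a
  dilated M3∪MC region is lower than outside). Attention maps on clinical
  models should not be expected to transfer from phantoms.
* The phantom's image channel, being a geometric rendering, is more
  informative than clinical CBCT: even at the default noise the image-only
  classifier can solve the phantom task, so the phantom benchmark
  demonstrates that the SDM channel is sufficient, not that the image
  alone is insufficient (on clinical data it is reported not to be).
* The numpy engine is single-threaded apart from BLAS matmuls; clinical-
  scale training (five-level networks on 256×256 slices, hundreds of
  epochs) is out of reach — the clinical presets validate wiring, not
  speed.
* No DICOM ingestion, reconstruction, registration, sub-voxel surface
  distances, multi-tooth batch localization, or significance testing
  between model variants.
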