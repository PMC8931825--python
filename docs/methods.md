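# Methods

## Problem and approach

Quantitative FDG-PET analysis of mouse brains needs two segmentation products
per animal: a brain-parenchyma mask (skull-stripping) and a set of anatomical
volumes of interest (VOIs) for regional uptake statistics.  The classical
route runs spatial normalization (SN): each brain is registered onto a
template, and template-space VOIs are applied, or carried back through the
inverse deformation (inverse spatial normalization, iSN) into the animal's
native space.  SN is the fragile, semi-automatic step.  The approach
implemented here removes it from deployment: a CNN is trained to *predict*
the iSN-projected template VOIs (iVOIs) directly from the native-space MR,
alongside a second CNN for skull-stripping.  At deployment the pipeline is
mask CNN → skull-strip → iVOI CNN → PET quantification, with no registration.

Five VOIs are used: cortex, hippocampus, striatum, thalamus, and cerebellum;
the cerebellum serves as the SUVR reference region (assumed plaque-free in
the APP/PS1 amyloid model).

## Synthetic cohort

Real paired-scan datasets of this kind are rarely public, so the package
ships a first-class phantom generator whose outputs carry exact ground truth.
It emulates a study of `n_mice` animals (default 18), each imaged at baseline
(BL) and follow-up (FU).

**Anatomy.** A coarse geometric mouse brain: a brain ellipsoid inside a
larger soft-tissue "head" ellipsoid (so skull-stripping has a real
foreground/background decision), a caudal cap (axial fraction ≥ 0.72) for the
cerebellum, a dorsal outer shell for the cortex, and three interior
ellipsoids for hippocampus, striatum, and thalamus.  Regions are checked for
pairwise disjointness at template construction; overlap raises an error
naming the colliding regions.

**Per-mouse deformation.** Each mouse's anatomy is the template carried
through a random smooth forward displacement field (template → individual):
per-axis Gaussian white noise smoothed at `deform_smoothness_mm` (default
2 mm) and scaled to `deform_amplitude_vox` peak displacement (default 2.5
voxels; 1.8 on the CPU preset).  A sampled field is accepted only if the
Jacobian determinant of `x + u(x)` is positive at every voxel; failures are
resampled with 20% smaller amplitude (at most 5 attempts).  BL and FU of one
mouse share the field, matching repeated imaging of the same animal.

**MR.** Warped template intensities (linear interpolation), multiplied by a
low-order random quadratic bias field (`bias_amplitude`, default 0.2) and
degraded with additive Gaussian noise (`noise_sigma_mr`, default 4 intensity
units against tissue values of 60–140).

**PET.** Piecewise-constant uptake per tissue (kBq/mL; cortex 180,
hippocampus 170, striatum 190, thalamus 175, cerebellum 150, non-VOI
parenchyma 120, extracranial tissue 40), multiplied at FU by the per-region
treatment effect (defaults: cortex +10%, hippocampus +8%, thalamus +8%,
striatum −10%, cerebellum unchanged), warped with nearest-neighbour sampling
(so noiseless region means are exact), blurred with a Gaussian PSF
(`psf_fwhm_mm`, default 0.8 mm) and degraded with Gaussian noise
(`noise_sigma_pet`, default 5 kBq/mL).  Gaussian noise is used for both
modalities instead of Rician/Poisson — adequate at these SNRs and much
simpler to reason about in tests.

**Dosimetry.** Injected dose ~N(5550, 300²) kBq (≈0.15 mCi) and body weight
~N(25, 2²) g per scan, for SUV computation with the 1 g ≡ 1 mL density
convention.

**Grids.** Default 70×128×128 voxels at (0.8, 0.15625, 0.15625) mm — a 20 mm
in-plane field of view at half the acquisition matrix, so mm-valued surface
distances are meaningful.  The CPU preset uses 40×64×64 at (0.8, 0.3125,
0.3125) mm, same field of view.

**What the phantom does not model:** MR physics (no Rician floor, no
susceptibility), PET reconstruction artifacts, attenuation/scatter, motion,
anatomical variability beyond smooth diffeomorphisms, and pathology-driven
contrast change.  Passing end-to-end tests therefore demonstrates that the
pipeline machinery is correct and learnable on clean, well-posed data — not
that the segmentation accuracies transfer to real T2 MR.

## Displacement fields

Fields are dense voxel-unit displacement volumes, axis order (z, y, x),
0-based, with a direction tag (`forward` = template → individual).  All
resampling uses the pull convention `out(x) = vol(x + u(x))`; out-of-grid
samples read background 0 (consistent for intensities and labels, where 0 is
the background code).  Label volumes are always resampled nearest-neighbour
(plain rounded lookup on the sample coordinate).

Inversion uses the fixed-point iteration `v_{k+1}(x) = −u(x + v_k(x))`,
`v_0 = 0`, with defaults `max_iter=50`, `tol_vox=0.05`; convergence is
declared when the composition residual `|u(x + v(x)) + v(x)|` on the
margin-trimmed interior falls below tolerance, and non-convergence raises an
error carrying the residual.  This scheme is accurate for small smooth
fields (the phantom's regime) and fails loudly for folding deformations; no
fidelity to any specific registration package's numerics is claimed.

## Network

A standard U-Net operating on quasi-3D inputs: each axial slice is predicted
from a 3-channel stack of slices (z−1, z, z+1), border slices replicating
their neighbour.  This yields as many training samples as a 2D approach with
local through-plane context; a 1-channel configuration is available as the
plain-2D ablation.  The contraction path applies two 3×3 convolutions (leaky
ReLU, slope 0.01) then 2×2 max pooling per level; the expansion path applies
2×2 transposed convolutions and concatenates the matching encoder features
before two further 3×3 convolutions.  Heads: 1-channel sigmoid (mask),
6-channel softmax (background + 5 VOIs).

Training minimizes soft-Dice loss, `1 − (2Σpg + ε)/(Σp + Σg + ε)` with
ε = 1.0 (stabilizes empty maps); the overlap sums pool over the whole batch
and, for the iVOI model, the loss averages over the five foreground classes.
Batch pooling matters: a per-slice loss lets slices where a class is absent
drive that class's probabilities to zero (gradient ~1/ε per pixel there),
which collapses multi-class training to all-background.  The optimizer is
Adam.  Inputs are
z-scored per volume.  Hidden layers use He initialization; the output head
starts at exactly zero so the network begins uncommitted (p = 0.5 / uniform)
and the early gradient flows through the head first.  The iVOI model trains only on
slices whose skull-stripped input is non-empty — slices outside the brain
carry no signal after stripping, and the criterion depends only on the input,
so deployment (which predicts every slice) is consistent.  Augmentation
applies one random affine (shift, rotation, shear) per sample to image and
target jointly (bilinear / nearest).  Everything — initialization, shuffling,
augmentation draws — is driven by one seed, so training is bit-reproducible.

The layers themselves are NumPy: convolutions are evaluated as shifted
matrix products against BLAS, and the backward pass is verified against
numerical directional derivatives in the test suite.

### Scale presets

| setting | full scale | CPU preset |
|---|---|---|
| grid | 70×128×128 | 40×64×64 |
| levels / base channels | 4 / 32 | 3 / 8 |
| input size | 128 | 64 |
| batch size | 25 | 25 |
| learning rate | 1e-5 | 1e-3 |
| epochs | caller-set | 16 |
| augmentation | shift 5%, rot 10°, shear 5° | off |

The full-scale learning rate (1e-5) assumes a GPU-scale step budget (≥10⁴
optimizer steps).  Adam's update magnitude is
bounded by the learning rate, so a preset that runs ~10³ steps on one CPU
core must scale the step size along with depth, width, and grid; the CPU
preset uses 1e-3, the conventional Adam default, and disables augmentation to
keep the per-step cost down.  The cosine schedule decays the rate to 1% of
its initial value over the run so the final weights settle rather than
bouncing around the optimum.

## Postprocessing

Raw probability maps are regularized by: threshold at 0.5 (inclusive) →
morphological opening (erosion + dilation, full 3×3×3 box element, radius 1)
→ kill-islands (keep the largest 6-connected 3D component; ties go to the
component containing the lexicographically smallest voxel) → fill-holes
(6-connected background components not touching the volume border become
foreground).  After the chain a mask has exactly one component and no
interior holes, which is property-tested on random smoothed-noise inputs.
Multi-class maps are argmaxed first (ties to the lowest code) and the chain
runs per foreground class; voxels a class loses become background, and a
voxel is never claimed by two classes.  The box element is used for the
opening because it preserves large solid shapes exactly (a cross-shaped
element would shave corners off rectangular solids); components and holes
use face connectivity.

## Metrics

DSC `2|P∩G|/(|P|+|G|)`; voxelwise sensitivity, specificity, and PPV from
whole-grid confusion counts; ASSD as the symmetric mean over both boundary
sets of nearest-boundary Euclidean distances (mm, voxel centre to voxel
centre, via exact distance transforms with anisotropic sampling).  Boundary
voxels are mask voxels with a face-adjacent background neighbour; the volume
border counts as background, so a single voxel is its own boundary.
Convention choices: both-empty DSC is 1.0 (perfect agreement on absence,
reported with a warning); zero-denominator ratios are reported as missing
rather than 0.  Method agreement uses Lin's concordance correlation
coefficient (population moments), which is bounded by |Pearson r|.

## Quantification

`SUV = C/(ID/BW)` with density 1 g/mL; `SUVR = SUV_target/SUV_reference`,
which algebraically reduces to the ratio of region mean counts (the package
asserts the two routes agree).  Treatment effect is summarized as
`100·(SUVR_FU − SUVR_BL)/SUVR_BL` per mouse, region, and VOI route.  Three
routes are compared: `DL` (predicted iVOIs on native PET), `iGT`
(ground-truth iVOIs on native PET), and `GT` (template VOIs on PET warped
into template space — the conventional SN route; the space is configurable).
Between routes the package reports CCC and Pearson r of mean counts and
SUVRs, paired t-tests on matched per-mouse % changes, and Welch t-tests on
the full unpaired samples (the unequal-variance form is the robust default;
the pooled form would need a variance-homogeneity assumption nothing here
guarantees).  Zero-variance comparisons are reported as undefined (NaN), not
as 0 or 1.

## Cross-validation

Folds split mice, not scans: a seeded shuffle of mouse ids is chunked into k
near-equal test sets (sizes differ by ≤1), and both scans of a mouse stay on
one side of every split.  With 18 mice and k = 6 each fold trains on 30
scans and tests on 6.  Within a fold the iVOI model trains on
ground-truth-stripped MR but is deployed on MR stripped by the *predicted*
postprocessed mask (`--strip-source` can switch to ground-truth stripping
for ablation).  A failing fold is logged and skipped; remaining folds
proceed.

## Problem sizes used in the shipped tests and acceptance script

The acceptance script and the end-to-end tests run the CPU preset: an
18-mouse cohort on the 40×64×64 grid, training on one fold (15 mice, 1200
slice stacks, 48 optimizer steps/epoch, 30 epochs) and evaluating on the 3
held-out mice.  Unit and property tests use 8–32-voxel grids and 2-mouse
cohorts.  The treatment-effect analysis evaluates the ground-truth-label
routes (iGT, GT) on all 18 mice and the DL route on the held-out fold of the
shared trained models — the DL route is never evaluated on mice that trained
it.

## Known limitations

* The phantom's clean contrast makes skull-stripping easier than on real T2
  MR; reported phantom scores are upper bounds, not transferable accuracies.
* The phantom applies an identical treatment effect to every mouse.  With no
  between-mouse effect heterogeneity, the per-mouse variance of SUVR %
  change is tiny, and paired tests comparing VOI routes become powered
  enough to flag sub-0.1-percentage-point systematic differences (such as
  the interpolation bias of the template-space route) as highly significant.
  In a real cohort, biological variance absorbs differences of that size;
  interpret route-comparison p-values on the phantom accordingly.
* The fixed-point field inversion assumes small smooth deformations; strong
  or folding fields raise rather than silently degrade.
* Gaussian noise models ignore the Rician magnitude floor (MR) and Poisson
  counting statistics (PET).
* The NumPy network is single-core; full-scale (128-grid, levels-4) training
  is possible but slow, and no GPU path is provided.
* PET is simulated directly in MR space; co-registration error between
  modalities is not modelled.
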