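# Methods

`prorad` is an in-silico testbed for proton-radiography (PR) based treatment
verification in adaptive proton therapy: it simulates PR images through
synthetic head-and-neck CT volumes, injects controlled treatment deviations,
reduces each impaired/reference image pair to a two-dimensional range-shift
map (RSM), and trains a compact convolutional classifier that names the
deviation source. This note records the models, the parameters that matter,
the numerical choices, and the limits of what the synthetic experiments can
show.

## Synthetic phantoms

Real head-and-neck planning CTs are not distributable, so the cohort is a
parametric stand-in: an ellipsoidal head on an elliptic-cylinder neck with a
bony spine (periodic vertebral bulges), a cranial vault shell, an optional
mandible arc, a central airway, and distributed fat — a subcutaneous layer
(base 6 mm) thickened posteriorly into a nape fat pad (default +8 mm at the
posterior pole) plus a few deep ellipsoidal fat compartments. Distributed
fat matters: a fat-density calibration error is detectable only through the
water-equivalent path length of fat actually traversed, and a shell-only fat
model would make the FAT deviation category physically near-invisible
(≤0.6 mm WET change), which no classifier could recover. With the default
geometry the fat fraction of the body is ≈20–25 % and bone ≈12–14 %, in the
range of clinical neck CTs.

Tissues are piecewise-constant in Hounsfield units (air −1000, fat −100,
soft 30, bone 700 by default) with seeded Gaussian texture (σ = 15 HU)
inside the body so range-shift maps are not artificially flat. Every
structure size and position is jittered per seed (±10 % by default) to give
a cohort inter-patient variability. The grid default is 128×128×160 voxels
at 2 mm isotropic spacing; axes are (x, y, z) = (left–right,
anterior–posterior, inferior–superior), with rays travelling along +x
(90° gantry).

## Calibration curve and tissue perturbations

The Hounsfield-to-relative-stopping-power (RSP) curve is piecewise linear
through six control points anchored at air (−1000 HU → 0.00) and water
(0 HU → 1.00), clamped outside the control range. Calibration-curve errors
multiply the RSP of the control points in a tissue band by (1 + p) — fat and
soft tissue at |p| ∈ {3, 4, 5} %, bone at {7, 9, 11} %, signs random. Tissue
bands are half-open HU intervals (air < −200 ≤ fat < −20 ≤ soft < 120 ≤
bone). The perturbed curve is applied during the impaired PR simulation
rather than by rewriting CT numbers; the two are equivalent for
water-equivalent thickness (WET, the only quantity that feeds the range
analysis) and avoiding HU re-quantisation keeps the perturbation exact, as
the round-trip identity test (perturb by p, then by −p/(1+p)) verifies to
1e−12.

## Proton radiography model

Energy loss is modelled purely as residual-range shift. A spot whose ray
accumulates WET `w` measures the pristine Bragg curve displaced proximally
by `w`; there is no depth straggling or nuclear halo. The pristine integral
depth dose (IDD) is an analytic stand-in — gently rising plateau, Gaussian
peak at the 210 MeV water range (r0 = 279 mm, configurable), erfc distal
falloff over a few mm, peak-normalised — chosen because the downstream
analysis only relies on a smooth, strictly unimodal shape; the
shift-recovery oracle tests are the evidence that this suffices.

WET is a Siddon-style exact voxel traversal (`compute_wet`), oracle-tested
against 0.01 mm Riemann quadrature. For the axis-aligned PR geometry the
traversal degenerates to the RSP line integral of one voxel column, which
the simulator precomputes for the whole volume (a projection image) and
looks up per ray; a test pins the fast path to the generic traversal.

Lateral heterogeneity ("range mixing") is modelled by the stated Gaussian
kernel (σ = 3.5 mm, truncated at 3σ): each spot's IDD is the kernel-weighted
mixture of the shifted curves of a fine lateral WET grid. The fine pitch
defaults to max(in-plane voxel spacing, 1 mm) — finer pitches would only
resample identical voxel columns. The mixture is evaluated exactly: because
a shifted piecewise-linear curve is reproduced exactly by linear binning of
its shift onto the depth grid, the per-spot mixture reduces to a
(spots × shift-bins) histogram times a (shift-bins × depth) matrix of
integer-shifted pristine curves, which is a single BLAS call per image.

Setup errors translate every ray entry point rigidly in the
anterior–posterior / inferior–superior plane while spot labels stay fixed,
so reference and impaired spots pair by index.

## Anatomy deformation

Neck expansion/contraction (weight change surrogate) is an analytic radial
surface displacement, not deformable registration. Per axial slice inside
the neck region the body contour radius R(θ) (estimated from the slice mask
around its centroid) moves to R + a(z); a(z) ramps with a cosine from zero
at the region's axial edges. The radial map is the identity inside a
protected core (R − max(15 mm, |a|+3 mm)) so the airway and almost all of
the spine stay put, and only the outer tissue layer stretches or
compresses; newly created tissue on expansion therefore takes the
subcutaneous fat/soft values. Under the strongest contractions the
outermost few mm of a posterior vertebral bulge can be compressed — the
price of guaranteeing a collapse-free mapping; the contour-displacement
contract (equivalent radius moves by a ± one voxel) is what the tests pin.
Contractions that would push the contour into the protected core raise an
error.

## Range-shift maps

The per-spot range shift is the offset s minimising the mean squared
difference between the impaired IDD and the reference IDD shifted by s,
with the mean taken over the overlapping depth samples (overlap
normalisation prevents window-edge bias). The scalar reference
implementation scans ±30 mm at 0.5 mm and refines with a three-point
parabola; it matches a 0.01 mm brute-force argmin within 0.05 mm on noisy
pairs. `compute_rsm` uses an algebraically equivalent vectorised search
(per-spot depth windows centred on the reference peak, integer-step scan,
half-step interpolation, parabolic refinement) that is tested against the
scalar path. Sign convention, fixed project-wide: positive = WET increased
= range pulled back. Export clips to the fixed −10..10 mm display window;
stored values are never clipped.

The RP-QC emulation compares paired IDD sets on the sparse 81-spot grid
(40×40 mm², 5 mm spacing) and reports the relative range error
RRE = 100·s/r0 per spot with a mean ± 1.5 SD summary against the ±3 %
clinical margin. The reference range in the denominator is the beam's
water range r0; the physics-validation workflow builds the
pseudo-measurement by adding iid depth noise (1 % of peak) to the
simulation.

## Deviation taxonomy and sampling

Eight categories (AP, BONE, CONT, EXP, FAT, IS, NONREL, SOFT); classes are
the 8 singles plus all 20 unordered pairs that exclude NONREL and the
mutually exclusive CONT&EXP — 28 classes, alphabetically canonical. Setup
magnitudes are |N(0, 1.5 mm)| truncated to [2, 4] mm with random sign;
deformations are uniform over the even integers ±{2,…,12} mm; tissue
perturbations are drawn from the discrete levels above. Background
nuisances (uniform |setup| ≤ 1 mm per axis, |p| ≤ 2 % per tissue) are
always added — but only on components the sampled class does not already
use, so that ground-truth labelling by the relevance thresholds (1 mm
setup, 2 % calibration, 1 mm deformation) recovers the sampled class for
every seed. The deformation threshold is this package's choice; the other
two mirror the stated background bounds.

## Dataset, classifier, and training

The desk-scale study: 8 phantoms (5/1/2 phantom-level train/val/test split,
the 22:3:7 proportions at cohort size 8), 28 classes × 12 draws per phantom
= 2688 RSMs, desk field 128×128 mm at 4 mm spot spacing (33×33 spots)
resampled bilinearly to 32×32 classifier inputs with mm values preserved.
Class-aware augmentation oversamples each training class to 100 samples
with label-preserving sub-pixel translations (≤2 spots) and mild additive
noise (σ ≤ 0.15 mm); flips are excluded because they would swap the
anterior/posterior and inferior/superior semantics of the labels.
Validation and test splits are never augmented, and phantom-level split
disjointness is asserted at construction and at evaluation.

Inputs are channel-normalised with train-split mean/std (not per-image
z-scores: the mm magnitude scale *is* the feature that separates
background-level from clinically relevant deviations, and per-image
standardisation would erase it). The per-image z-score operation is still
provided (`znormalize`) for pipelines that want it.

The compact classifier is three Conv–BatchNorm–ReLU–pool blocks
(16/32/64 channels), a 256-unit dense layer with dropout, and a
**structured head**: a 7-unit dense layer produces independent category
logits z, and the 28 class logits are the exact subset log-odds
`logit p_S`, `p_S = Π_{m∈S} σ(z_m) · Π_{m∉S} (1−σ(z_m))` (NONREL is the
empty subset). The head bakes the taxonomy's compositional algebra into
the network, so only seven category detectors have to generalise across
phantoms; downstream sigmoid outputs remain exactly the 28 class
probabilities the evaluation contract expects. Training uses binary
cross-entropy on the 28 outputs (positive weight 2) plus two auxiliary
losses on shared features: category-level BCE on z, and mean-squared
regression of the six ground-truth deviation magnitudes (scaled to unit
range). The magnitude regression is a training-time signal only — it
forces the trunk to behave as an amplitude estimator, which is what
distinguishing a 3 % perturbation from a 2 % background requires — and no
severity output is exposed. Optimisation is AdamW (lr 3e−3, decoupled
weight decay 1e−4, batch 128) with a 3-epoch linear warmup, plateau-halved
learning rate, early stopping on validation loss (patience 30, max 130
epochs), and best-weights restoration. Everything is NumPy; one master seed fans out to
phantom, deviation, augmentation and weight-init streams.

Evaluation is micro-averaged precision/recall/F1/F2 over the flattened
28-column binary matrix at threshold 0.5, per-class ROC AUCs (classes
absent from a split are reported as undefined and excluded from
summaries), and the micro-averaged ROC over all (sample, class) pairs.

## What the synthetic experiments do and do not show

The generator reproduces the *mechanisms* that make deviations visible in
range-shift maps — contour displacement, tissue-band density errors, rigid
field shifts — under controlled ground truth, which is what the
classification experiment needs. It does not reproduce real anatomical
diversity (organs, sinus cavities, dental artifacts), CT noise spectra,
detector effects, or deformable-registration residuals; passing the
synthetic study shows the pipeline is self-consistent and that the
deviation signatures are learnable at desk scale, not that the trained
weights transfer to patients. Desk-scale results are also not expected to
match a full-scale study: 8 phantoms give the classifier five training
anatomies (the full study's split had 22), the 4 mm desk spot grid is four
times coarser than the 1 mm clinical field, and the compact CNN is orders
of magnitude smaller than a production backbone. The hardest residual
decision at desk scale is the FAT category — a 3 % fat-density error
against a ≤2 % background on a phantom whose fat geometry the model has
never seen — and it dominates the remaining error budget of the held-out
metrics.

## Problem sizes and determinism

Default problem sizes (desk preset): 128³-ish voxel phantoms at 2 mm, 33×33
spot PR images with a 2 mm fine mixing grid, 341-point depth grid at 1 mm,
2688-sample dataset, ≤130 training epochs. The full pipeline is
deterministic for a fixed master seed on a fixed platform; floating-point
reductions can differ across BLAS builds, so bit-identity is only promised
within a platform. The clinical-scale preset (260×260 mm field at 1 mm
spacing, 1 mm CT grids, 32 phantoms) is provided behind an explicit
`allow_large` guard.
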