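# Methods

## The problem and the model

PET radiomics needs a 3D tumor mask, but voxel labels are expensive.
`petcam` obtains the mask from *weak* supervision only: a per-patient
cancer-type label (esophageal = 0, lung = 1) and one prior point p at
the tumor center. The pipeline has four stages.

**1. Preprocessing.** Volumes are resampled to isotropic spacing with
cubic splines (masks nearest-neighbor, to preserve binarity), SUV
intensities are clipped to [0, 30] and scaled to [0, 1], and two
maximum intensity projections are computed. Axis convention: arrays are
indexed (x, y, z); the coronal MIP collapses y into a (z, x) image, the
sagittal MIP collapses x into (z, y). A sagittal projection looks along
the left-right axis, so it cannot retain x; this fixes the axis
bookkeeping everywhere downstream. Normalizing before or after
projection is equivalent because a monotone map commutes with the max;
we normalize the volume first. `normalize_suv` flags its output, so the
operation is idempotent.

**2. Classifier and class activation maps.** A shared CNN classifies
each MIP. The default architecture is eight 3x3 conv/ReLU layers with
channels (16, 16, 32, 32, 64, 64, 128, 128) and five stride-2
downsamplings, so a 416 x 160 input ends in D = 128 feature maps of
13 x 5; the dense head is 128 -> 64 -> 1 (ELU, dropout 0.5, sigmoid).
The conv details are choices of this package — only the 13 x 5 / 128
contract and the head are fixed by design. The heat map for class C
averages each feature map's influence on the class response,
w_i = mean over positions of dy^C/df_i, combines maps as
sum_i w_i f_i, applies a ReLU, and is upsampled with corner-aligned
bilinear interpolation (a separable linear operator, so its transpose
is the exact training gradient). Inference heat maps are scaled to
[0, 1] by their maximum.

**3. Multitask training.** The objective is
`loss_glob = L_class + alpha * L_distance` with alpha = 1. `L_class` is
the binary cross entropy (probabilities clamped at 1e-7 for the loss
value). `L_distance` penalizes class activation far from the prior
point. The public `distance_loss` operation is the activation-weighted
mean pixel distance sum_i h(q_i) d(q_i, p) / sum_i h(q_i) (an all-zero
map scores 0 by convention). A literal unweighted sum of distances over
the heat-map grid would be constant in the network parameters and could
not train anything, which is why the loss is activation-weighted.

Inside the training graph the distance term needs care; three numerical
choices matter and are deliberate:

* **Score-based influence.** The in-graph CAM weights are seeded with
  the class-score (logit) gradient, +/-1, instead of dy_hat/df. The two
  differ only by the positive scalar sigma'(logit), so the normalized
  heat map is identical, but the probability form vanishes once the
  classifier saturates, silently switching the constraint off.
* **Softmax attention weighting.** The in-graph loss is the expected
  distance under a softmax attention distribution over the (per-sample
  scale-normalized) pre-heat map, with temperature 0.2. This is a
  smooth surrogate of the ReLU-weighted ratio: strictly positive
  weights mean the map can neither die (a dead ReLU map receives no
  gradient and can never be revived at the prior point) nor produce the
  1/mass gradient blow-up of the raw ratio. The read-out CAM remains
  the ReLU map.
* **Diagonal-normalized distances.** In-graph distances are measured as
  a fraction of the MIP diagonal. This makes alpha = 1 genuinely
  balanced: in pixel units the distance gradient exceeds the
  classification gradient by more than two orders of magnitude at
  initialization and the classifier never learns.

The CAM weights w_i are treated as constants during the distance
backward pass (stop-gradient): back-propagating through them would
require second-order derivatives; the first-order form is standard for
trainable-attention losses and is sufficient here. The full
second-order path is not implemented.

Training uses Adam (library default lr 1e-4, 100 epochs; the benchmark
configuration below overrides both), mini-batches of eight patients
(sixteen MIPs — both views of a patient travel together), optional
step decay of the learning rate, and early stopping that restores the
best-validation-epoch parameters. With alpha = 0 every CAM-related
branch is skipped, so that run is bit-for-bit a plain classifier
training — the no-prior ablation arm. An optional left-right flip
augmentation of the coronal view exists but is off by default (it did
not help on phantoms). `train_cam_ensemble` trains several members
from independent initializations and averages their max-normalized
heat maps; consensus suppresses activations only one run believes in.

**4. Reconstruction and outcome.** Each heat map is thresholded at 40%
of its maximum (mirroring the clinical convention the ground truth
itself uses), the largest connected component is kept, and the two
masks are back-projected: voxel (x, y, z) is tumor iff coronal(z, x)
and sagittal(z, y). The intersection prism is exact for axis-aligned
cuboids and a superset for convex shapes. `refine_by_suv` optionally
re-thresholds inside the prism at 40% of the maximum intensity it
contains — the same protocol that defines the ground truth, now applied
to the predicted region; it is off by default in `segment_patient` and
on in the benchmark pipeline, where the prism is deliberately generous
(coarse CAM cells) and the refinement carves the metabolic volume out
of it. The outcome network is conv(32)-pool-conv(64)-pool-dense(128)-
dense(1, sigmoid) on a 48^3 crop centered on the mask centroid
(crop unmasked by default; masking is a flag).

## The phantom generator

Defaults: 64 x 64 x 128 voxels at 2 mm (so MIPs are 128 x 64), 20
patients, class balance 0.5, background 2 SUV inside an elliptical body
envelope, Gaussian-profile decoys at fixed anatomical-analogue
positions (brain, bladder, heart) with intensity U(6, 14), one
anisotropic Gaussian tumor (amplitude U(8, 20), sigma U(3, 5.5) voxels)
truncated at its 3-sigma bounding cuboid, additive Gaussian noise
(sigma 0.5 SUV, clipped at zero), ground truth = 40%-of-max threshold
of the noise-free tumor component inside the cuboid, prior point = the
rounded tumor center. Esophageal tumors sit on the posterior midline,
lung tumors in an anterior lateral lobe (side random), so classes are
separable by tumor x-position by construction, with a secondary y cue
that makes the sagittal view informative too. The decoy intensity range
overlaps the tumor's — decoys may outshine the lesion, which is the
confusability the distance constraint exists to resolve. Outcome labels
follow `volume-median` (1 iff metabolic volume above the cohort median)
with a 10% label-flip probability by default.

What the phantom does *not* emulate: scanner physics (PSF, attenuation,
reconstruction artifacts), multi-lesion disease, inter-patient anatomy
variation, or realistic outcome biology. Passing tests therefore show
that the mechanism works when its assumptions hold — a single focal
lesion whose position encodes the class — not that it transfers to
clinical data.

## The benchmark configuration

`petcam.benchmark.run_synthetic_benchmark` is the package's end-to-end
study, used by both the acceptance tests and `scripts/acceptance.py`:
60 phantom patients (outcome flips disabled so the outcome ceiling is
set by the data, not injected noise), a stratified ~36/12/12
train/validation/test split (first fold of the five-fold protocol),
and for each arm (alpha = 1 and alpha = 0) a two-member ensemble of the
reduced classifier — channels (8, 16, 16, 32, 32, 32, 32, 32), three
downsamplings, 16 x 8 feature maps of depth 32 on the 128 x 64 MIPs —
trained 200 epochs at lr 1e-3 with step decay at epochs 120/170.
Segmentation uses threshold 0.4 plus SUV refinement; the outcome net is
a reduced conv(8)-conv(16)-dense(64) on 24^3 *masked* crops (the
volume-median label is a property of the mask, so zeroing the
background puts the labeled quantity directly in view), 80 epochs at
lr 3e-3. These
problem sizes keep the whole study at roughly ten minutes on one CPU
while preserving the study's structure; they are the package's own
desk-scale choices, not the defaults a clinical-scale run would use.

## Numerical choices and degenerate inputs

* All network arithmetic is float64; every layer's backward pass is
  finite-difference-tested.
* Bilinear upsampling is corner-aligned; `J = 1` rows degenerate to
  constant interpolation.
* An all-zero heat map binarizes to an empty mask with a warning;
  `refine_by_suv` returns an empty mask unchanged with a warning;
  `crop_tumor` refuses an empty mask (the caller should fall back to
  another mask source).
* Dice and IoU define empty-vs-empty as 1 and empty-vs-nonempty as 0.
  `iou = dice / (2 - dice)` holds identically.
* AUC is the rank-based Mann-Whitney statistic with half-credit ties.
* `sens_spec_acc` raises a named error on a zero denominator rather
  than propagating NaN.
* Stratified folds spread each class's remainder over different folds,
  so at n = 195, k = 5 every test fold has 39-40 patients; within each
  fold the non-test portion is split ~74/26 into train/validation,
  mimicking a 115/40/40 protocol.
* Cross-validated AUC is computed per fold and then averaged (with its
  standard deviation), not pooled.

## Known limitations

* The heat-map-to-mask threshold (0.4) and the SUV refinement are
  exposed as configuration; there is no principled way to choose them
  from weak labels alone.
* Reconstruction from two orthogonal views cannot represent concavities
  along the collapsed axes and assumes a single lesion; multi-lesion
  volumes would need per-component matching across views.
* The distance constraint assumes the prior point is inside the lesion;
  a grossly misplaced point drags the map with it.
* Second-order training through the CAM weights is not implemented.
* Wrong-lateralization failures (the lung CAM locking onto the
  contralateral lobe of a held-out patient) dominate the residual
  segmentation error at phantom scale; ensembling reduces but does not
  eliminate them.
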