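# Methods

This note documents the models and procedures implemented in `fissnet`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic phantoms do and do not establish about behaviour on real MRI.

## Problem setting

The input is a bias-corrected T1-weighted brain MRI registered to a 1 mm
isotropic stereotaxic template, together with a binary cerebellar mask
produced by an external tool. The outputs are three binary masks on the
cropped cerebellar grid: the fissures (dark CSF clefts between folia), the
tissue with fissures carved out, and the whole cerebellar envelope. One
network is trained per output; the three differ only in their training
labels. Upstream steps (N4 bias-field correction, registration, the initial
cerebellar mask, and any manual mask correction) are outside the package; the
pipeline documents hooks for them and the phantom generator supplies
already-"registered" inputs for testing.

## Label construction

Training labels are derived, not hand-drawn:

1. **Contrast enhancement.** z-scoring `i ← (i − mean i)/std i`, linear
   rescale to [1, 255], global histogram equalization. The z-score uses the
   population SD (divide by N); on volumes of ≥ 10⁴ voxels the difference
   from the sample SD is far below any threshold sensitivity. Equalization
   uses 256 bins on the rescaled range and is applied globally; equalizing
   within a brain mask would be a reasonable variant but the global form is
   the implemented one.
2. **Binarization.** The Otsu threshold is computed over a 256-bin histogram
   by maximizing between-class variance, with the exact per-bin intensity
   mass (not bin centers) so that the result coincides with an exhaustive
   partition search whenever distinct values occupy distinct bins. Ties are
   broken toward the lowest maximizing threshold, and voxels *strictly above*
   the threshold count as tissue.
3. **Mask smoothing.** The cerebellar mask is regularized with morphological
   Chan–Vese active contours (scikit-image), initialized at the mask and run
   on the mask itself as a piecewise-constant image — the intensity image is
   not needed for border regularization. Defaults: 10 iterations, smoothing 1.
   The algorithm family is fixed but these two numbers were an open choice;
   they keep the smoothed mask within Dice ≈ 0.99 of its input on
   ellipsoidal phantoms, and a configurable Dice floor (default 0.9) triggers
   a warning if the contour drifts.
4. **Mask algebra.** `fissures = whole ∧ ¬binary` and
   `tissue = whole ∖ fissures`. Two interpretation points are deliberate:
   a *global* XOR of the binarized head image with the cerebellar mask would
   label every bright extra-cerebellar voxel a "fissure", so the operation is
   restricted to the mask support (fissures are dark voxels *inside* the
   cerebellum); and the tissue map is defined as the set difference
   `whole ∖ fissures`, the only direction that is non-empty and that makes
   the triplet identities `fissures ∪ tissue = whole`,
   `fissures ∩ tissue = ∅` hold by construction. Both identities are asserted
   voxelwise throughout the test suite.

Visual inspection of the binary maps — needed on real data where high
contrast can erode tissue — is replaced here by a QC report of voxel counts
and the fissure fraction; no GUI is provided.

## Architecture

A U-Net whose blocks are inception modules. Each module runs four parallel
branches over the same input — convolutions of width 1, 3 and 5, and a
stride-1 max-pool of width 3 followed by a width-1 convolution — each
emitting `f` feature maps, ReLU after every convolution, concatenated to
`4f` maps. Branch widths follow the canonical inception layout; the sources
fixing this architecture specify four convolutions and one pooling operation
per module, and 1/3/5/pool is the standard realization. The encoder has four
stages (module → instance norm → 2× max-pool), the bottleneck chains two
modules, and the decoder mirrors the encoder with transposed-convolution
upsampling (kernel 2, stride 2, channels halved) and concatenation of the
matching encoder stage's normalized output. Ten inception modules in total;
filter parameters 16, 16, 32, 64 (encoder), 128, 128 (bottleneck),
64, 32, 16, 16 (decoder). A single dropout layer (rate 0.3) sits before the
final single-filter convolution with sigmoid output. Down/up-sampling
operators, the exact branch wiring, and the placement of the one dropout
layer were open details; the choices above are conventional and recorded
here as this package's interpretation.

Inputs must have spatial dimensions divisible by 2⁴ = 16; the error message
names `preprocess.pad_to_multiple` as the remedy, and the pipeline pads
cropped samples automatically (edge replication for images, zeros for
labels).

### The numerical engine

The network runs on `fissnet.nn`, a compact reverse-mode automatic
differentiation engine over numpy float32 arrays: N-dimensional "same"
convolution implemented as one GEMM per kernel offset, stride-2 transposed
convolution, max pooling (stride-2 and stride-1 "same"), instance
normalization, dropout, channel concatenation, soft-Dice and cross-entropy
losses, and Adam. Tensors carry no batch axis — one volume is processed per
optimizer step. Every backward pass is verified against central finite
differences in `tests/test_nn.py`. The engine is sized for desk-scale
volumes; it is exact but not fast, which motivates the reduced protocol
below.

## Training protocol

* **Loss: soft Dice**, `1 − 2Σpg/(Σp² + Σg²)`, evaluated on sigmoid
  probabilities; on binary inputs the ratio reduces to `2TP/(2TP+FP+FN)`.
  Dice is the headline evaluation metric, which is why it is also the
  default loss; binary cross-entropy is selectable (`loss="bce"`).
* **Optimizer:** Adam with its standard defaults (lr 10⁻³, β₁ 0.9, β₂ 0.999).
* **Epochs:** 120 by default.
* **Augmentation:** for every training/validation image, 40 rigidly
  transformed copies — per-axis rotations drawn uniformly from [−10°, 10°]
  and integer shifts from [−10, 10] voxels applied on a random subset of
  axes. Images are interpolated linearly, labels with nearest neighbour and
  re-binarized at 0.5; containment (`fissures ⊆ whole`) is re-imposed after
  interpolation and the tissue map is rebuilt as `whole ∖ fissures`, so the
  triplet identities survive augmentation exactly.
* **Split:** the reference cohort proportions 17/2/5 (train/val/test of 24)
  are the default fractions; phantom experiments use explicit counts.
* **Model selection:** the checkpoint with the best validation Dice is kept
  alongside the final weights; no early stopping.
* **Determinism:** all randomness (initialization, shuffling, augmentation,
  dropout) flows from the configured seed; two runs with the same seed and
  data produce identical losses.

Batch size appears in the configuration for interface completeness, but the
engine processes one volume per step (a 3D-memory-driven choice).

## Inference and postprocessing

Volumes are z-scored per volume (the same normalization as training inputs),
probabilities thresholded at 0.5. For the `tissue` and `whole` targets only
the largest 26-connected component is kept (ties broken by the first label
in scan order — deterministic); the fissure target gets no postprocessing,
since fissures legitimately form many small components. Probability cut,
connectivity and tie-break were open numerical choices and are configurable.
Deriving fissures as the difference of the two cerebellum models is exposed
as `inference.combine_tissue_models` but is an unvalidated utility, not a
supported path.

## Evaluation metrics

DSC (squared-sum form), overlap coefficient `Σpg / min(Σp, Σg)`, specificity
`TN/(FP+TN)`, sensitivity `TP/(TP+FN)`, and `AUC = 1 − ½(FPR + FNR)`. The
last is implemented exactly as this closed form — balanced accuracy of one
hard classification, equal to `(SN+SP)/2` — not a threshold-sweep ROC
integral. Degenerate cases: Dice of two empty masks is defined as 1 with a
logged warning; OC, SP, SN and AUC raise on inputs that leave them undefined
(empty mask, absent class). All five measures are tested to 1e-12 against an
exhaustive voxel-loop oracle.

## The phantom generator

Phantoms emulate the contrast structure of a cropped, registered T1
cerebellum: a bright filled ellipsoid (tissue, 180 a.u.) carved by dark thin
sheets (fissures, 30 a.u.) on a darker background (10 a.u.), 64³ voxels at
1 mm with semi-axes (26, 22, 18), four fissures of width 2. Fissures are
level-set slabs of planes with sinusoidal warp (amplitude ≤ 3 voxels),
clipped to the ellipsoid — simple, countable geometry that reproduces the
dark-sheet topology of real fissures. Corruptions: a smooth multiplicative
bias field (Gaussian-blurred white noise rescaled to [1−a, 1+a], default
a = 0.1) standing in for scanner inhomogeneity, and additive Gaussian noise
(default SD 8, i.e. tissue SNR ≈ 22). Intensities are arbitrary units; the
preprocessing rescale removes absolute scale.

What the phantoms do **not** model: anatomically realistic folia/lobule
shapes, partial-volume effects, Rician noise statistics (Gaussian is adequate
for exercising thresholding and training but underweights the background
noise floor), registration misalignment, and inter-rater variability in the
initial mask. Passing phantom tests therefore establishes the correctness of
the machinery — mask algebra, shapes, training dynamics, metric values — not
clinical-grade accuracy on patient MRI.

## Reduced desk-scale protocol

The full protocol (default filter schedule on ~200³ crops, 120 epochs, 40×
augmentation) is a GPU-scale workload. The package's standard reduced
experiment (`fissnet.presets`) uses 32³ phantoms with proportionally scaled
geometry (semi-axes 13, 11, 9, two fissures), the quarter-width schedule
4, 4, 8, 16, 32 / 32, 16, 8, 4, 4, 20 epochs, and no offline augmentation —
at this cohort size the un-augmented run already drives validation Dice for
the whole-cerebellum target above 0.99, so augmentation is reserved for its
own dedicated tests. The reduced network satisfies every structural
invariant of the full one (10 modules, 4× rule, four stages), and the
reduced experiment — train on 8 phantoms, validate on 2 — is the package's
stand-in for cohort-level evaluation: the acceptance suite requires held-out
validation Dice ≥ 0.8 there.

## Known limitations

* The numpy engine makes full-scale (default-architecture, full-resolution)
  training impractical; the default `ArchitectureSpec` is exercised
  structurally and via forward passes, while training claims are established
  at reduced scale.
* Label construction degrades with noise: global histogram equalization
  spreads the background mode, and the Otsu threshold can then misclassify
  fissure voxels. On real data this is exactly where the recommended visual
  inspection/correction enters; the package only quantifies it via the QC
  report. Noiseless phantoms recover ground-truth labels exactly (Dice 1.0).
* Masks are treated as isotropic voxel grids; all mask algebra ignores world
  coordinates beyond carrying the affine through I/O unchanged.
* The morphological-snake step assumes the input mask is a single compact
  region; wildly fragmented masks may be over-smoothed (the Dice-floor
  warning fires).
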