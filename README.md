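# fissnet

Segmentation of **cerebellar fissures** from T1-weighted brain MRI with an
inception-U-Net, plus the semi-automatic label-construction procedure that
makes training such models practical without full manual annotation.

Cerebellar atrophy — e.g. in spinocerebellar ataxia type 2 (SCA2) — widens the
CSF-filled fissures between cerebellar folia. Standard cerebellum
segmentation/parcellation tools tend to label these dark clefts as tissue,
inflating volume estimates precisely in the patients where atrophy matters.
`fissnet` targets three binary masks per scan, each learned by its own model
from the same architecture:

| target     | mask                                          |
|------------|-----------------------------------------------|
| `fissures` | cerebellar fissures only (M1)                 |
| `tissue`   | cerebellar tissue with fissures carved out (M2) |
| `whole`    | the whole cerebellar envelope (M3)            |

The package is aimed at neuroimaging researchers who have bias-corrected,
template-registered T1 volumes and an external cerebellar mask (e.g. from
ACAPULCO or CERES), and at method developers who want a fully testable,
dependency-light reference implementation: every stage runs on synthetic
cerebellum phantoms with exact ground truth, so nothing requires a data
download.

## What is inside

* **Label construction** (`fissnet.maskgen`) — from a contrast-enhanced image
  and a cerebellar mask: Otsu binarization (keep voxels *strictly above* the
  threshold), morphological-snake smoothing of the mask borders, then mask
  algebra: `fissures = whole ∧ ¬binary` (the XOR restricted to the mask
  support) and `tissue = whole ∖ fissures`, so that
  `fissures ∪ tissue = whole` and `fissures ∩ tissue = ∅` hold exactly.
* **Preprocessing** (`fissnet.preprocess`) — intensity z-scoring
  `i ← (i − mean i)/std i`, linear rescale to [1, 255], global histogram
  equalization, and cropping to the mask bounding box (with recorded crop box
  for uncropping predictions).
* **Architecture** (`fissnet.architecture`) — a U-Net of **10 inception
  modules** (four down-/up-sampling stages + a two-module bottleneck) with
  instance normalization after every module, ReLU after every convolution,
  dropout 0.3 before the final single-filter sigmoid convolution. Each
  inception module has four branches (1-, 3-, 5-wide convolutions and
  max-pool → 1-wide convolution) and emits **4× its filter parameter** feature
  maps; the default schedule is 16, 16, 32, 64, 128 (contracting) /
  128, 64, 32, 16, 16 (expanding). The network runs on a small numpy
  reverse-mode autodiff engine shipped in `fissnet.nn`, with
  gradient-checked layers and Adam.
* **Training** (`fissnet.training`) — per-target training with soft-Dice loss
  (Dice = 2Σpg / (Σp² + Σg²)), Adam with default hyper-parameters, 120 epochs
  by default, and offline rigid augmentation: 40 copies per train/validation
  image with rotations in [−10°, 10°] and integer shifts in [−10, 10] voxels
  on random axes.
* **Inference** (`fissnet.inference`) — sigmoid probabilities thresholded at
  0.5; largest-connected-component filtering (26-connectivity) for the
  `tissue`/`whole` targets, no postprocessing for `fissures`.
* **Metrics** (`fissnet.metrics`) — DSC, overlap coefficient
  OC = Σpg / min(Σp, Σg), specificity, sensitivity, and balanced-accuracy
  AUC = 1 − ½(FPR + FNR).
* **Phantoms** (`fissnet.phantom`) — synthetic cropped cerebellum volumes:
  a bright ellipsoid with dark warped-slab fissures on a dark background,
  optional smooth multiplicative bias field and Gaussian noise, with exact
  ground-truth mask triplets.

## Worked example

```python
from fissnet import FissureSegmentationModel
from fissnet.presets import REDUCED_ARCH, reduced_phantom_params, reduced_training_config

model = FissureSegmentationModel.from_phantoms(
    10, target="whole",
    params=reduced_phantom_params(),
    arch=REDUCED_ARCH,
    config=reduced_training_config(target="whole", epochs=8,
                                   split_fractions=(0.7, 0.1, 0.2)),
    seed=0)
res = model.fit()
print(res.summary())
print(res.evaluate().round(3))
```

prints

```
Fissure segmentation fit
====================================================
target:            whole
parameters:        1,572,657
inception modules: 10
train/val volumes: 7/1 (+0 augmentations each)
epochs:            8 (best validation at 8)
final train loss:  0.1502
final val DSC:     0.9117
best val DSC:      0.9117

          DSC     OC     SP     SN   AUC
volume
1       0.916  0.995  0.965  0.995  0.98
2       0.913  0.996  0.964  0.996  0.98
```

i.e. after eight epochs on seven 32³ phantoms the reduced quarter-width
network segments the two held-out phantoms' whole-cerebellum masks with Dice
≈ 0.91; OC ≈ 0.995 says the true mask is almost entirely contained in the
prediction, and SP/SN read the voxelwise error rates per class. Longer
training pushes validation Dice above 0.99 (see `tests/test_acceptance.py`).

The same workflow is available from the shell:

```bash
fissnet phantom -o ph --seed 1            # synthetic volume + ground truth
fissnet preprocess ph.nii.gz --mask ph_whole.nii.gz -o enh.nii.gz
fissnet build-dataset ph.nii.gz --mask ph_whole.nii.gz -o labels
fissnet demo -o demo_run --epochs 5       # end-to-end pipeline
fissnet evaluate labels_fissures.nii.gz ph_fissures.nii.gz
```

## Scope

Bias-field correction (N4), registration to the ICBM/MNI template, and the
initial cerebellar mask are deliberately out of scope: the pipeline consumes
already-corrected, already-registered volumes plus an external mask, and the
phantom generator supplies equivalents for testing. See `docs/methods.md`
for the model assumptions, parameter choices, and known limitations.
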