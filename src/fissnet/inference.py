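"""Applying a trained model to a preprocessed volume, plus postprocessing.

The volume is z-scored (as during training) and pushed through the network;
the sigmoid output is binarized at 0.5.  For the tissue and whole-cerebellum
targets, only the largest 3D connected component (26-connectivity) is kept;
the fissure model's output is left untouched, since fissures legitimately
form many components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .architecture import InceptionUNet, ShapeError
from .grids import BinaryMask3D, CropBox, IntensityVolume
from .preprocess import uncrop

__all__ = ["Prediction", "segment", "largest_component", "combine_tissue_models"]

logger = logging.getLogger(__name__)

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class Prediction:
    """Voxelwise probabilities with the thresholded mask and crop context."""

    probabilities: np.ndarray
    mask: BinaryMask3D
    threshold: float = 0.5
    crop_box: CropBox | None = None

    def uncropped_mask(self, full_shape) -> BinaryMask3D:
        """Embed the mask back into the original (uncropped) grid."""
        if self.crop_box is None:
            raise ValueError("prediction carries no crop box")
        return self.mask.with_data(uncrop(self.mask.data, self.crop_box, full_shape))


def segment(model: InceptionUNet, volume: IntensityVolume, threshold: float = 0.5,
            crop_box: CropBox | None = None, postprocess: bool = False,
            connectivity: int = 26) -> Prediction:
    """Segment a preprocessed (enhanced, cropped) volume.

    The same per-volume z-scoring used during training is applied here, so
    any contrast-enhanced crop is a valid input.  Set ``postprocess=True``
    for the tissue / whole-cerebellum targets to keep only the largest
    connected component.
    """
    data = np.asarray(volume.data, dtype=np.float32)
    k = model.spec.downsample_factor
    if any(s % k for s in data.shape):
        raise ShapeError(
            f"input shape {data.shape} not divisible by {k}; pad first, e.g. "
            f"preprocess.pad_to_multiple(volume, {k})")
    sd = data.std()
    if sd > 0:
        data = (data - data.mean()) / sd
    probs = model.predict(data)
    mask = BinaryMask3D(probs >= threshold, volume.spacing, volume.affine)
    if postprocess:
        mask = largest_component(mask, connectivity=connectivity)
    return Prediction(probabilities=probs, mask=mask, threshold=threshold,
                      crop_box=crop_box)


def largest_component(mask: BinaryMask3D, connectivity: int = 26) -> BinaryMask3D:
    """Keep only the largest connected component (ties -> lowest label in
    scan order); an empty mask is returned unchanged with a warning."""
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    if mask.is_empty():
        logger.warning("largest_component called on an empty mask")
        return mask.with_data(mask.data.copy())
    labels, n = ndimage.label(mask.data, structure=_STRUCTURES[connectivity])
    sizes = np.bincount(labels.ravel())[1:]  # skip background
    keep = int(np.argmax(sizes)) + 1         # argmax -> first max -> lowest label
    return mask.with_data(labels == keep)


def combine_tissue_models(with_fissures: BinaryMask3D,
                          without_fissures: BinaryMask3D) -> BinaryMask3D:
    """Fissures as the set difference of the two tissue models (M2 minus M3).

    Utility only: deriving fissures from the two cerebellum models is an
    unvalidated alternative to the dedicated fissure model.
    """
    with_fissures.require_congruent(without_fissures, "model outputs")
    return with_fissures.with_data(with_fissures.bool & ~without_fissures.bool)
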