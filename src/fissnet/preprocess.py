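"""Contrast enhancement and cropping of bias-corrected, registered volumes.

The network input is a contrast-enhanced image built in three steps:
z-scoring (i := (i - mean(i)) / std(i), population SD), linear rescale to
[1, 255], and histogram equalization (256 bins).  Volumes are then cropped
to the cerebellar mask's bounding box (with a small margin) to cut the
computational cost; the crop box is recorded so predictions can be embedded
back into the original grid.

Bias-field correction and registration to a stereotaxic template are
upstream of this package: inputs are assumed already corrected and
registered (the phantom generator produces such volumes directly).
"""

from __future__ import annotations

import numpy as np
from skimage import exposure

from .grids import BinaryMask3D, CropBox, DegenerateInputError, GridError, IntensityVolume

__all__ = [
    "normalize_intensity",
    "rescale_range",
    "equalize_histogram",
    "enhance_contrast",
    "crop_to_mask",
    "crop_mask",
    "uncrop",
    "pad_to_multiple",
]


def normalize_intensity(volume: IntensityVolume) -> IntensityVolume:
    """Z-score the volume: (i - mean(i)) / std(i), population SD."""
    data = volume.data.astype(np.float64)
    sd = data.std()
    if sd == 0:
        raise DegenerateInputError("cannot normalize a constant volume (std = 0)")
    return volume.with_data((data - data.mean()) / sd)


def rescale_range(volume: IntensityVolume, lo: float = 1.0, hi: float = 255.0) -> IntensityVolume:
    """Linear map sending the volume minimum to ``lo`` and maximum to ``hi``."""
    data = volume.data.astype(np.float64)
    vmin, vmax = data.min(), data.max()
    if vmax == vmin:
        raise DegenerateInputError("cannot rescale a constant volume")
    return volume.with_data(lo + (data - vmin) * (hi - lo) / (vmax - vmin))


def equalize_histogram(volume: IntensityVolume, n_bins: int = 256) -> IntensityVolume:
    """Remap intensities by the cumulative histogram (global equalization).

    The mapping is monotone non-decreasing in the input intensities; output
    spans the same [min, max] range as the input.
    """
    data = volume.data.astype(np.float64)
    vmin, vmax = data.min(), data.max()
    if vmax == vmin:
        raise DegenerateInputError("cannot equalize a constant volume")
    eq = exposure.equalize_hist(data, nbins=n_bins)  # in [0, 1]
    return volume.with_data(vmin + eq * (vmax - vmin))


def enhance_contrast(volume: IntensityVolume, n_bins: int = 256,
                     equalize: bool = True) -> IntensityVolume:
    """normalize -> rescale to [1, 255] -> histogram equalization.

    This enhanced image is the common input of the three segmentation models
    and of the label-construction thresholding.
    """
    out = rescale_range(normalize_intensity(volume))
    if equalize:
        out = equalize_histogram(out, n_bins=n_bins)
    return out


def _bounding_box(mask: BinaryMask3D, margin: int):
    idx = np.argwhere(mask.data)
    if idx.size == 0:
        raise DegenerateInputError("cannot crop to an empty mask")
    lower = np.maximum(idx.min(axis=0) - margin, 0)
    upper = np.minimum(idx.max(axis=0) + 1 + margin, mask.shape)
    return CropBox(tuple(lower), tuple(upper), margin)


def crop_to_mask(volume: IntensityVolume, mask: BinaryMask3D, margin: int = 4):
    """Crop to the mask's bounding box dilated by ``margin`` (clipped).

    Returns ``(cropped_volume, crop_box)``; the box is half-open in voxel
    indices and contains every mask voxel.
    """
    volume.require_congruent(mask, "volume/mask")
    box = _bounding_box(mask, margin)
    return volume.with_data(volume.data[box.slices].copy()), box


def crop_mask(mask: BinaryMask3D, box: CropBox) -> BinaryMask3D:
    """Apply an existing crop box to a congruent mask."""
    return mask.with_data(mask.data[box.slices].copy())


def uncrop(data: np.ndarray, box: CropBox, full_shape, fill=0.0) -> np.ndarray:
    """Embed cropped voxel data back at its crop box in the original grid."""
    if tuple(data.shape) != box.shape:
        raise GridError(f"data shape {data.shape} does not match crop box {box.shape}")
    out = np.full(full_shape, fill, dtype=data.dtype)
    out[box.slices] = data
    return out


def pad_to_multiple(volume: IntensityVolume, multiple: int = 16, mode: str = "edge"):
    """Pad spatial dims up to the next multiple (e.g. of 2^4 for four halvings).

    Returns ``(padded_volume, crop_box)`` where the box locates the original
    voxels inside the padded grid, so ``uncrop`` semantics can be reused via
    its ``slices``.
    """
    shape = volume.shape
    target = tuple(int(np.ceil(s / multiple) * multiple) for s in shape)
    pads = [(0, t - s) for s, t in zip(shape, target)]
    padded = np.pad(volume.data, pads, mode=mode)
    box = CropBox((0, 0, 0), shape, margin=0)
    return volume.with_data(padded), box
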