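"""Semi-automatic construction of the three training labels.

Given the contrast-enhanced image and an externally produced cerebellar
mask, the label triplet is derived by mask algebra:

1. Otsu-threshold the enhanced image and keep voxels *strictly above* the
   threshold (bright tissue), giving a binary tissue map of the whole head.
2. Smooth the cerebellar mask with morphological active contours
   (morphological Chan-Vese), regularizing borders drawn by different
   raters; this smoothed mask is the *whole cerebellum* label.
3. Fissures are the dark voxels inside the cerebellum: ``whole & ~binary``.
   (A literal global XOR of the binarized head with the cerebellar mask
   would also label bright extra-cerebellar voxels; the operation is
   restricted to the mask support on purpose.)
4. Tissue is the cerebellum with the fissures carved out:
   ``whole & ~fissures``, so that fissures ∪ tissue = whole and
   fissures ∩ tissue = ∅ hold by construction.

The Otsu threshold is computed over a 256-bin histogram by exhaustively
maximizing between-class variance; ties are broken toward the lowest
maximizing threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.segmentation import morphological_chan_vese

from .grids import BinaryMask3D, DegenerateInputError, GridError, IntensityVolume, MaskTriplet

__all__ = [
    "MaskGenConfig",
    "otsu_threshold",
    "binarize",
    "smooth_mask",
    "derive_fissure_mask",
    "derive_tissue_mask",
    "build_label_triplet",
    "qc_report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MaskGenConfig:
    """Knobs of the label-construction pipeline."""

    use_snakes: bool = True
    snake_iterations: int = 10
    snake_smoothing: int = 1
    otsu_bins: int = 256
    smooth_dsc_floor: float = 0.9


def otsu_threshold(volume: IntensityVolume | np.ndarray, n_bins: int = 256) -> float:
    """Between-class-variance-maximizing threshold over an ``n_bins`` histogram.

    Returns the lowest maximizing candidate (a bin edge); thresholding is
    meant to be applied strictly (``intensity > threshold``).
    """
    data = volume.data if isinstance(volume, IntensityVolume) else np.asarray(volume)
    data = data.astype(np.float64).ravel()
    if data.min() == data.max():
        raise DegenerateInputError("Otsu threshold undefined for a constant volume")
    hist, edges = np.histogram(data, bins=n_bins)
    sums, _ = np.histogram(data, bins=edges, weights=data)
    p = hist.astype(np.float64) / hist.sum()
    omega0 = np.cumsum(p)             # class-0 weight for split after bin k
    mu = np.cumsum(sums) / data.size  # exact cumulative intensity mass per bin
    mu_t = mu[-1]
    # between-class variance for every split; guard empty classes
    valid = (omega0 > 0) & (omega0 < 1)
    sigma_b = np.zeros(n_bins)
    sigma_b[valid] = (mu_t * omega0[valid] - mu[valid]) ** 2 / (
        omega0[valid] * (1.0 - omega0[valid]))
    k = int(np.argmax(sigma_b))  # argmax takes the first (lowest) maximizer
    return float(edges[k + 1])


def binarize(volume: IntensityVolume, threshold: float) -> BinaryMask3D:
    """Voxel = 1 iff intensity is strictly higher than the threshold."""
    return BinaryMask3D(volume.data > threshold, volume.spacing, volume.affine)


def smooth_mask(mask: BinaryMask3D, iterations: int = 10, smoothing: int = 1,
                dsc_floor: float = 0.9) -> BinaryMask3D:
    """Border smoothing by morphological active contours (Chan-Vese).

    The evolution is initialized at the mask and run on the mask itself as a
    piecewise-constant image, so it regularizes the border without needing
    the intensity image.  ``iterations=0`` is the identity.  A warning is
    logged if the smoothed mask drifts below ``dsc_floor`` Dice overlap with
    the input.
    """
    if mask.is_empty():
        raise DegenerateInputError("cannot smooth an empty mask")
    if iterations == 0:
        return mask.with_data(mask.data.copy())
    level = morphological_chan_vese(mask.data.astype(float), num_iter=iterations,
                                    init_level_set=mask.data.astype(np.int8),
                                    smoothing=smoothing)
    out = mask.with_data(level.astype(np.uint8))
    inter = int((out.bool & mask.bool).sum())
    dsc = 2.0 * inter / max(out.count() + mask.count(), 1)
    if dsc < dsc_floor:
        logger.warning("smooth_mask drifted from its input (DSC %.3f < %.2f floor)",
                       dsc, dsc_floor)
    return out


def derive_fissure_mask(binary: BinaryMask3D, whole: BinaryMask3D) -> BinaryMask3D:
    """Fissures = dark voxels inside the cerebellum: ``whole & ~binary``.

    This is the XOR of the binarized image with the cerebellar mask,
    restricted to the mask support (bright voxels outside the cerebellum are
    not fissures); the result is contained in ``whole`` by construction.
    """
    if binary.shape != whole.shape:
        raise GridError(f"incongruent grids: {binary.shape} vs {whole.shape}")
    return whole.with_data(whole.bool & ~binary.bool)


def derive_tissue_mask(whole: BinaryMask3D, fissures: BinaryMask3D) -> BinaryMask3D:
    """Tissue = cerebellum with fissures carved out: ``whole & ~fissures``."""
    if whole.shape != fissures.shape:
        raise GridError(f"incongruent grids: {whole.shape} vs {fissures.shape}")
    if np.any(fissures.bool & ~whole.bool):
        raise GridError("fissure mask is not contained in the whole-cerebellum mask")
    return whole.with_data(whole.bool & ~fissures.bool)


def build_label_triplet(enhanced: IntensityVolume, cereb_mask: BinaryMask3D,
                        config: MaskGenConfig | None = None) -> MaskTriplet:
    """Run the full label construction on an enhanced image + cerebellar mask."""
    config = config or MaskGenConfig()
    enhanced.require_congruent(cereb_mask, "volume/mask")
    if cereb_mask.is_empty():
        raise DegenerateInputError("cerebellar mask is empty")
    if config.use_snakes:
        whole = smooth_mask(cereb_mask, config.snake_iterations,
                            config.snake_smoothing, config.smooth_dsc_floor)
    else:
        whole = cereb_mask.with_data(cereb_mask.data.copy())
    threshold = otsu_threshold(enhanced, n_bins=config.otsu_bins)
    binary = binarize(enhanced, threshold)
    fissures = derive_fissure_mask(binary, whole)
    tissue = derive_tissue_mask(whole, fissures)
    return MaskTriplet(fissures=fissures, tissue=tissue, whole=whole)


def qc_report(triplet: MaskTriplet) -> dict:
    """Voxel-count summary standing in for the visual inspection of the
    binary maps (counts and fissure fraction of the cerebellum)."""
    n_whole = triplet.whole.count()
    return {
        "whole_voxels": n_whole,
        "fissure_voxels": triplet.fissures.count(),
        "tissue_voxels": triplet.tissue.count(),
        "fissure_fraction": triplet.fissures.count() / max(n_whole, 1),
    }
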