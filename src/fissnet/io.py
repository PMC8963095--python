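"""NIfTI reading and writing (plain or gzipped), with mask validation."""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np

from .grids import BinaryMask3D, GridError, IntensityVolume

__all__ = ["read_volume", "read_mask", "write_volume"]


def _spacing_from(img) -> tuple:
    return tuple(float(z) for z in img.header.get_zooms()[:3])


def read_volume(path) -> IntensityVolume:
    """Load a NIfTI-1/2 scalar volume (``.nii`` or ``.nii.gz``)."""
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # nibabel wraps many format errors
        raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    return IntensityVolume(data, spacing=_spacing_from(img), affine=img.affine)


def read_mask(path) -> BinaryMask3D:
    """Load a NIfTI as a binary mask; values other than {0,1} are rejected."""
    vol = read_volume(path)
    vals = np.unique(vol.data)
    if not np.isin(vals, (0, 1)).all():
        raise GridError(f"{path} is not a binary mask (values {vals[:10]})")
    return BinaryMask3D(vol.data.astype(np.uint8), vol.spacing, vol.affine)


def write_volume(obj, path, force: bool = False):
    """Write a volume (float32) or mask (uint8) as NIfTI, preserving the affine.

    Refuses to overwrite an existing file unless ``force=True``.
    """
    path = str(path)
    if os.path.exists(path) and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    if isinstance(obj, BinaryMask3D):
        data = obj.data.astype(np.uint8)
    elif isinstance(obj, IntensityVolume):
        data = obj.data.astype(np.float32)
    else:
        raise TypeError(f"expected IntensityVolume or BinaryMask3D, got {type(obj)}")
    img = nib.Nifti1Image(data, affine=obj.affine)
    img.header.set_zooms(obj.spacing)
    nib.save(img, path)
    return path
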