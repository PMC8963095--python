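"""Core voxel-grid containers shared by every pipeline stage.

An :class:`IntensityVolume` is a 3D scalar grid (a cropped T1-weighted MRI in
practice) together with its voxel spacing and NIfTI affine.  A
:class:`BinaryMask3D` is a congruent {0,1} grid.  A :class:`MaskTriplet`
bundles the three training labels used throughout: the fissure mask, the
tissue mask (cerebellum with the fissures carved out), and the whole
cerebellum, which must satisfy ``fissures | tissue == whole`` and
``fissures & tissue == 0`` voxelwise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IntensityVolume",
    "BinaryMask3D",
    "MaskTriplet",
    "CropBox",
    "default_affine",
    "GridError",
    "DegenerateInputError",
]


class GridError(ValueError):
    """Raised when grids are incongruent or a mask violates its contract."""


class DegenerateInputError(ValueError):
    """Raised for degenerate inputs such as constant or empty volumes."""


def default_affine(spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Diagonal RAS affine for a volume with the given voxel spacing in mm."""
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class IntensityVolume:
    """3D scalar image with voxel spacing (mm) and a 4x4 NIfTI affine."""

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise GridError(f"expected a 3D grid, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise GridError("volume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise GridError(f"voxel spacing must be positive, got {self.spacing}")
        if self.affine is None:
            self.affine = default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise GridError("affine must be 4x4")

    @property
    def shape(self):
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "IntensityVolume":
        """New volume with the same header but different voxel data."""
        return IntensityVolume(np.asarray(data), self.spacing, self.affine.copy())

    def congruent(self, other) -> bool:
        return self.shape == other.shape

    def require_congruent(self, other, what="grids"):
        if not self.congruent(other):
            raise GridError(f"incongruent {what}: {self.shape} vs {other.shape}")


@dataclass
class BinaryMask3D:
    """3D {0,1} label grid congruent with its source volume."""

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise GridError(f"expected a 3D mask, got ndim={arr.ndim}")
        if arr.dtype == bool:
            arr = arr.astype(np.uint8)
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise GridError(f"mask values must be in {{0,1}}, found {vals[:10]}")
        self.data = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.affine is None:
            self.affine = default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self):
        return self.data.shape

    @property
    def bool(self) -> np.ndarray:
        return self.data.astype(bool)

    def count(self) -> int:
        """Number of foreground voxels."""
        return int(self.data.sum())

    def is_empty(self) -> bool:
        return self.count() == 0

    def with_data(self, data) -> "BinaryMask3D":
        return BinaryMask3D(np.asarray(data), self.spacing, self.affine.copy())

    def congruent(self, other) -> bool:
        return self.shape == other.shape

    def require_congruent(self, other, what="grids"):
        if not self.congruent(other):
            raise GridError(f"incongruent {what}: {self.shape} vs {other.shape}")


@dataclass
class MaskTriplet:
    """The three training labels: fissures, tissue, and whole cerebellum.

    Invariants (checked on construction): the fissure and tissue masks are
    disjoint, their union is the whole-cerebellum mask, and the fissure mask
    is contained in the whole mask.
    """

    fissures: BinaryMask3D
    tissue: BinaryMask3D
    whole: BinaryMask3D

    def __post_init__(self):
        self.whole.require_congruent(self.fissures, "triplet grids")
        self.whole.require_congruent(self.tissue, "triplet grids")
        f, t, w = self.fissures.bool, self.tissue.bool, self.whole.bool
        if np.any(f & t):
            raise GridError("fissure and tissue masks overlap")
        if not np.array_equal(f | t, w):
            raise GridError("fissures ∪ tissue != whole")

    def select(self, target: str) -> BinaryMask3D:
        """Label map for a model target: 'fissures' (M1), 'tissue' (M2), 'whole' (M3).

        Naming note: 'tissue' here is the cerebellum *with* its fissures
        carved out; 'whole' is the full cerebellar envelope.
        """
        try:
            return {"fissures": self.fissures, "tissue": self.tissue, "whole": self.whole}[target]
        except KeyError:
            raise ValueError(f"unknown target {target!r}; expected fissures/tissue/whole") from None


@dataclass
class CropBox:
    """Half-open voxel bounding box ``[lower, upper)`` with its dilation margin.

    Recorded when cropping so that predictions on the cropped grid can be
    embedded back into the original volume.
    """

    lower: tuple
    upper: tuple
    margin: int = 0

    def __post_init__(self):
        self.lower = tuple(int(v) for v in self.lower)
        self.upper = tuple(int(v) for v in self.upper)
        if len(self.lower) != 3 or len(self.upper) != 3:
            raise GridError("CropBox corners must be voxel triples")
        if not all(lo < hi for lo, hi in zip(self.lower, self.upper)):
            raise GridError(f"CropBox requires lower < upper, got {self.lower} vs {self.upper}")

    @property
    def slices(self):
        return tuple(slice(lo, hi) for lo, hi in zip(self.lower, self.upper))

    @property
    def shape(self):
        return tuple(hi - lo for lo, hi in zip(self.lower, self.upper))

    def to_json(self) -> str:
        return json.dumps({"lower": self.lower, "upper": self.upper, "margin": self.margin})

    @classmethod
    def from_json(cls, text: str) -> "CropBox":
        d = json.loads(text)
        return cls(tuple(d["lower"]), tuple(d["upper"]), int(d.get("margin", 0)))
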