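"""Synthetic cerebellum phantoms with ground-truth label triplets.

Real cropped T1 volumes of the cerebellum show bright tissue traversed by
dark CSF-filled fissures on a dark background.  The phantom reproduces that
contrast structure with countable geometry: the whole "cerebellum" is a
filled ellipsoid, and each fissure is a thin slab (a level set of a plane,
optionally warped sinusoidally) clipped to the ellipsoid.  Optional
corruptions emulate acquisition artefacts: a smooth multiplicative bias
field (the inhomogeneity N4 correction removes on real data) and additive
Gaussian noise.  Every sample carries its exact ground-truth
:class:`~fissnet.grids.MaskTriplet`, so each downstream stage is testable
without any data download.

The geometry is deliberately simple rather than anatomically realistic:
lobule shapes, Rician noise statistics, and registration misalignment are
not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .grids import BinaryMask3D, IntensityVolume, MaskTriplet

__all__ = [
    "PhantomParams",
    "PhantomSample",
    "generate_phantom",
    "apply_bias_field",
    "add_noise",
    "ellipsoid_mask",
    "slab_mask",
]


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, contrast, and corruption settings for one phantom.

    Intensities are in arbitrary units (the preprocessing rescale makes the
    absolute scale irrelevant); defaults mimic a T1 contrast with bright
    tissue (180), dark CSF fissures (30), darker background (10), mild
    multiplicative inhomogeneity (±10%) and additive noise (SD 8).
    """

    grid_shape: tuple = (64, 64, 64)
    ellipsoid_semi_axes: tuple = (26.0, 22.0, 18.0)
    tissue_intensity: float = 180.0
    fissure_intensity: float = 30.0
    background_intensity: float = 10.0
    n_fissures: int = 4
    fissure_width: float = 2.0
    bias_field_amplitude: float = 0.1
    noise_sigma: float = 8.0
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "grid_shape", tuple(int(s) for s in self.grid_shape))
        object.__setattr__(self, "ellipsoid_semi_axes",
                           tuple(float(a) for a in self.ellipsoid_semi_axes))
        if len(self.grid_shape) != 3 or len(self.ellipsoid_semi_axes) != 3:
            raise ValueError("grid_shape and ellipsoid_semi_axes must be triples")
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape entries must be positive")
        if not (self.fissure_intensity < self.tissue_intensity
                and self.background_intensity < self.tissue_intensity):
            raise ValueError("fissure and background intensities must be below tissue intensity")
        if self.n_fissures < 0:
            raise ValueError("n_fissures must be >= 0")
        if self.fissure_width < 1:
            raise ValueError("fissure_width must be >= 1 voxel")
        if any(2 * a >= s for a, s in zip(self.ellipsoid_semi_axes, self.grid_shape)):
            raise ValueError("ellipsoid semi-axes must fit inside the grid")
        if self.bias_field_amplitude < 0:
            raise ValueError("bias_field_amplitude must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class PhantomSample:
    """A simulated volume with its exact ground-truth mask triplet."""

    volume: IntensityVolume
    truth: MaskTriplet
    params: PhantomParams


def ellipsoid_mask(grid_shape, semi_axes, center=None) -> np.ndarray:
    """Boolean mask of the filled ellipsoid Σ ((x_i - c_i)/a_i)² <= 1."""
    if center is None:
        center = tuple((s - 1) / 2.0 for s in grid_shape)
    coords = np.indices(grid_shape, dtype=float)
    q = sum(((coords[i] - center[i]) / semi_axes[i]) ** 2 for i in range(3))
    return q <= 1.0


def slab_mask(grid_shape, normal, center=None, width=2.0,
              warp_amplitude=0.0, warp_frequency=0.15, warp_axis=None) -> np.ndarray:
    """Boolean mask of a thin sheet: |n·(x-c) + a·sin(f·t·(x-c))| < width/2.

    ``normal`` is the (unnormalized) sheet normal; the optional sinusoidal
    warp bends the sheet along a direction ``warp_axis`` orthogonal to it,
    mimicking the curved geometry of real fissures.
    """
    if center is None:
        center = tuple((s - 1) / 2.0 for s in grid_shape)
    n = np.asarray(normal, dtype=float)
    n /= np.linalg.norm(n)
    coords = np.indices(grid_shape, dtype=float)
    rel = [coords[i] - center[i] for i in range(3)]
    dist = sum(n[i] * rel[i] for i in range(3))
    if warp_amplitude:
        if warp_axis is None:
            # any direction orthogonal to the normal
            ref = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
            warp_axis = np.cross(n, ref)
        t = np.asarray(warp_axis, dtype=float)
        t /= np.linalg.norm(t)
        phase = sum(t[i] * rel[i] for i in range(3))
        dist = dist + warp_amplitude * np.sin(warp_frequency * phase)
    return np.abs(dist) < width / 2.0


def _smooth_unit_field(shape, rng, sigma_frac=0.25) -> np.ndarray:
    """Smooth random field rescaled to [-1, 1]."""
    noise = rng.normal(size=shape)
    sigma = max(1.0, sigma_frac * min(shape))
    f = gaussian_filter(noise, sigma=sigma)
    lo, hi = f.min(), f.max()
    if hi - lo < 1e-12:  # pathological: blur collapsed to a constant
        return np.zeros(shape)
    return 2.0 * (f - lo) / (hi - lo) - 1.0


def apply_bias_field(volume: IntensityVolume, amplitude: float, seed: int) -> IntensityVolume:
    """Multiply by a smooth field in [1 - amplitude, 1 + amplitude]."""
    if amplitude < 0:
        raise ValueError("bias amplitude must be >= 0")
    if amplitude == 0:
        return volume.with_data(volume.data.copy())
    rng = np.random.default_rng(seed)
    field = 1.0 + amplitude * _smooth_unit_field(volume.shape, rng)
    return volume.with_data(volume.data * field)


def add_noise(volume: IntensityVolume, sigma: float, seed: int) -> IntensityVolume:
    """Add zero-mean Gaussian noise with standard deviation ``sigma``."""
    if sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    if sigma == 0:
        return volume.with_data(volume.data.copy())
    rng = np.random.default_rng(seed)
    return volume.with_data(volume.data + rng.normal(0.0, sigma, size=volume.shape))


def generate_phantom(params: PhantomParams) -> PhantomSample:
    """Build one phantom volume with its exact ground-truth triplet.

    Deterministic for a fixed ``params.seed``: fissure orientations, warp
    parameters, the bias field, and the noise are all drawn from one seeded
    generator chain.
    """
    rng = np.random.default_rng(params.seed)
    shape = params.grid_shape
    whole = ellipsoid_mask(shape, params.ellipsoid_semi_axes)

    fissures = np.zeros(shape, dtype=bool)
    for _ in range(params.n_fissures):
        normal = rng.normal(size=3)
        while np.linalg.norm(normal) < 1e-6:  # pragma: no cover - astronomically rare
            normal = rng.normal(size=3)
        warp_amp = rng.uniform(0.0, 3.0)
        warp_freq = rng.uniform(0.08, 0.25)
        # keep sheets near the center so they actually cross the ellipsoid
        offset = rng.uniform(-0.3, 0.3, size=3) * np.asarray(params.ellipsoid_semi_axes)
        center = tuple((s - 1) / 2.0 + o for s, o in zip(shape, offset))
        sheet = slab_mask(shape, normal, center=center, width=params.fissure_width,
                          warp_amplitude=warp_amp, warp_frequency=warp_freq)
        fissures |= sheet
    fissures &= whole
    tissue = whole & ~fissures

    data = np.full(shape, params.background_intensity, dtype=np.float64)
    data[tissue] = params.tissue_intensity
    data[fissures] = params.fissure_intensity
    vol = IntensityVolume(data)

    # independent sub-seeds so bias/noise are reproducible in isolation too
    bias_seed, noise_seed = (int(s) for s in rng.integers(0, 2 ** 31 - 1, size=2))
    vol = apply_bias_field(vol, params.bias_field_amplitude, bias_seed)
    vol = add_noise(vol, params.noise_sigma, noise_seed)

    truth = MaskTriplet(
        fissures=BinaryMask3D(fissures, vol.spacing, vol.affine),
        tissue=BinaryMask3D(tissue, vol.spacing, vol.affine),
        whole=BinaryMask3D(whole, vol.spacing, vol.affine),
    )
    return PhantomSample(volume=vol, truth=truth, params=params)


def generate_cohort(n: int, params: PhantomParams | None = None, seed: int = 0) -> list:
    """n phantoms with distinct sub-seeds derived from ``seed``."""
    base = params or PhantomParams()
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=n)
    return [generate_phantom(replace(base, seed=int(s))) for s in seeds]
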