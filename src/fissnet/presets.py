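"""Reduced desk-scale presets.

The full protocol (default architecture, 120 epochs, 40 augmentations per
image on ~256³ registered volumes) is a GPU-scale workload.  For CPU-scale
experiments, demos, and the test suite the package ships one reduced
protocol: 32³ phantoms with proportionally scaled geometry, a quarter-width
filter schedule, 20 epochs, and no offline augmentation.  The reduced
network obeys the same structural invariants (ten inception modules, 4x
feature-map rule, four down/up-sampling stages) as the default one.
"""

from __future__ import annotations

from dataclasses import replace

from .architecture import ArchitectureSpec
from .phantom import PhantomParams
from .training import TrainingConfig

__all__ = ["REDUCED_ARCH", "reduced_phantom_params", "reduced_training_config"]

REDUCED_ARCH = ArchitectureSpec(encoder_filters=(4, 4, 8, 16, 32),
                                decoder_filters=(32, 16, 8, 4, 4))


def reduced_phantom_params(seed: int = 0, **overrides) -> PhantomParams:
    """32³ phantom with the ellipsoid and fissure count scaled to the grid."""
    base = PhantomParams(grid_shape=(32, 32, 32), ellipsoid_semi_axes=(13.0, 11.0, 9.0),
                         n_fissures=2, seed=seed)
    return replace(base, **overrides) if overrides else base


def reduced_training_config(target: str = "whole", epochs: int = 20,
                            seed: int = 0, **overrides) -> TrainingConfig:
    """20-epoch protocol without offline augmentation."""
    base = TrainingConfig(target=target, epochs=epochs, augment_per_image=0, seed=seed)
    return replace(base, **overrides) if overrides else base
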