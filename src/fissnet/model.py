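"""High-level Model/Results interface over the segmentation pipeline.

``FissureSegmentationModel`` is built from data — a list of
``(IntensityVolume, MaskTriplet)`` pairs plus the target label and
architecture/training configuration — and ``fit()`` returns a
``SegmentationFitResults`` carrying the trained network, the training
curves, per-volume evaluation metrics, and a printable ``summary()``.

    >>> model = FissureSegmentationModel.from_phantoms(10, target="whole")
    >>> res = model.fit()
    >>> print(res.summary())
    >>> pred = res.predict(volume)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .architecture import ArchitectureSpec, InceptionUNet
from .grids import IntensityVolume
from .inference import Prediction, segment
from .metrics import METRIC_COLUMNS, evaluate
from .phantom import PhantomParams, generate_cohort
from .training import TrainingConfig, TrainingHistory, split_samples, train_model

__all__ = ["FissureSegmentationModel", "SegmentationFitResults"]


class FissureSegmentationModel:
    """One segmentation task (target label + architecture + protocol) bound
    to a dataset of labelled volumes."""

    def __init__(self, samples, target: str = "fissures",
                 arch: ArchitectureSpec | None = None,
                 config: TrainingConfig | None = None,
                 split_seed: int = 0):
        if config is None:
            config = TrainingConfig(target=target)
        elif config.target != target:
            raise ValueError(f"config.target={config.target!r} disagrees with target={target!r}")
        self.samples = list(samples)
        self.target = target
        self.arch = arch or ArchitectureSpec()
        self.config = config
        self.train_set, self.val_set, self.test_set = split_samples(
            self.samples, config.split_fractions, seed=split_seed)

    @classmethod
    def from_phantoms(cls, n: int, target: str = "fissures",
                      params: PhantomParams | None = None,
                      arch: ArchitectureSpec | None = None,
                      config: TrainingConfig | None = None,
                      seed: int = 0) -> "FissureSegmentationModel":
        """Build the model on a synthetic phantom cohort (ground-truth labels)."""
        cohort = generate_cohort(n, params=params, seed=seed)
        samples = [(s.volume, s.truth) for s in cohort]
        return cls(samples, target=target, arch=arch, config=config, split_seed=seed)

    def fit(self) -> "SegmentationFitResults":
        result = train_model(self.arch, self.train_set, self.val_set, self.config)
        return SegmentationFitResults(model=self, network=result.model,
                                      history=result.history,
                                      best_epoch=result.best_epoch,
                                      final_state=result.final_state)


@dataclass
class SegmentationFitResults:
    """Fitted network with its training curves and evaluation helpers."""

    model: FissureSegmentationModel
    network: InceptionUNet
    history: TrainingHistory
    best_epoch: int
    final_state: dict = field(repr=False, default=None)  # type: ignore[assignment]

    # -- inference ----------------------------------------------------------
    def predict(self, volume: IntensityVolume, postprocess: bool | None = None,
                **kwargs) -> Prediction:
        """Segment one preprocessed volume; postprocessing defaults to the
        target's convention (largest component except for fissures)."""
        if postprocess is None:
            postprocess = self.model.target != "fissures"
        return segment(self.network, volume, postprocess=postprocess, **kwargs)

    def evaluate(self, samples=None) -> pd.DataFrame:
        """Per-volume metric table (DSC, OC, SP, SN, AUC) on held-out data."""
        samples = self.model.test_set if samples is None else samples
        rows = []
        for i, (vol, labels) in enumerate(samples):
            pred = self.predict(vol)
            rep = evaluate(pred.mask, labels.select(self.model.target))
            rows.append({"volume": i + 1, **dict(zip(METRIC_COLUMNS, rep.row()))})
        return pd.DataFrame(rows).set_index("volume")

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        h = self.history
        lines = [
            "Fissure segmentation fit",
            "=" * 52,
            f"target:            {self.model.target}",
            f"parameters:        {self.network.num_parameters():,}",
            f"inception modules: {self.network.graph.n_inception_modules}",
            f"train/val volumes: {len(self.model.train_set)}/{len(self.model.val_set)}"
            f" (+{self.model.config.augment_per_image} augmentations each)",
            f"epochs:            {len(h)} (best validation at {self.best_epoch})",
            f"final train loss:  {h.train_loss[-1]:.4f}",
            f"final val DSC:     {h.val_dsc[-1]:.4f}",
            f"best val DSC:      {max(h.val_dsc):.4f}",
        ]
        return "\n".join(lines)

    def plot_history(self, ax=None):
        """Loss / validation-Dice curves on a matplotlib axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        epochs = np.arange(1, len(self.history) + 1)
        ax.plot(epochs, self.history.train_loss, label="train loss")
        ax.plot(epochs, self.history.val_loss, label="val loss")
        ax.plot(epochs, self.history.val_dsc, label="val DSC")
        ax.set_xlabel("epoch")
        ax.legend()
        return ax
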