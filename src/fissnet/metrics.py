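"""Volumetric overlap metrics for binary segmentations.

Five measures are reported per prediction/ground-truth pair:

* Dice score        DSC = 2 Σ p·g / (Σ p² + Σ g²)   (= 2TP/(2TP+FP+FN) on binary masks)
* overlap coeff.    OC  = Σ p·g / min(Σ p, Σ g)
* specificity       SP  = TN / (FP + TN)
* sensitivity       SN  = TP / (TP + FN)
* balanced accuracy AUC = 1 - ((FPR + FNR) / 2)      (= (SN + SP) / 2)

The last is the closed-form "area under the curve" of a single hard
classification, i.e. balanced accuracy, not a threshold-sweep ROC integral.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grids import BinaryMask3D, GridError

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "dice",
    "overlap_coefficient",
    "specificity",
    "sensitivity",
    "auc_balanced",
    "evaluate",
]

logger = logging.getLogger(__name__)

METRIC_COLUMNS = ("DSC", "OC", "SP", "SN", "AUC")


def _as_bool(mask) -> np.ndarray:
    if isinstance(mask, BinaryMask3D):
        return mask.bool
    arr = np.asarray(mask)
    if not np.isin(np.unique(arr), (0, 1)).all():
        raise GridError("metric inputs must be binary {0,1} grids")
    return arr.astype(bool)


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxelwise 2x2 contingency counts."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """The five overlap measures plus the underlying counts."""

    dsc: float
    oc: float
    sp: float
    sn: float
    auc: float
    counts: ConfusionCounts

    def to_dict(self) -> dict:
        return {"DSC": self.dsc, "OC": self.oc, "SP": self.sp, "SN": self.sn,
                "AUC": self.auc,
                "TP": self.counts.tp, "TN": self.counts.tn,
                "FP": self.counts.fp, "FN": self.counts.fn}

    def row(self) -> list:
        """Values in the (DSC, OC, SP, SN, AUC) column layout."""
        return [self.dsc, self.oc, self.sp, self.sn, self.auc]


def confusion_counts(prediction, truth) -> ConfusionCounts:
    p, g = _as_bool(prediction), _as_bool(truth)
    if p.shape != g.shape:
        raise GridError(f"incongruent grids: {p.shape} vs {g.shape}")
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def dice(prediction, truth) -> float:
    """Dice with the squared-sum denominator; defined as 1 when both masks
    are empty (perfect agreement; a warning is logged)."""
    p, g = _as_bool(prediction), _as_bool(truth)
    if p.shape != g.shape:
        raise GridError(f"incongruent grids: {p.shape} vs {g.shape}")
    num = 2.0 * np.count_nonzero(p & g)
    den = float(np.count_nonzero(p) + np.count_nonzero(g))
    if den == 0:
        logger.warning("Dice of two empty masks defined as 1.0")
        return 1.0
    return num / den


def overlap_coefficient(prediction, truth) -> float:
    """Intersection over the smaller mask; requires both masks nonempty."""
    p, g = _as_bool(prediction), _as_bool(truth)
    if p.shape != g.shape:
        raise GridError(f"incongruent grids: {p.shape} vs {g.shape}")
    np_, ng = np.count_nonzero(p), np.count_nonzero(g)
    if np_ == 0 or ng == 0:
        raise ValueError("overlap coefficient requires two nonempty masks")
    return np.count_nonzero(p & g) / min(np_, ng)


def specificity(counts: ConfusionCounts) -> float:
    """True-negative rate TN / (FP + TN)."""
    if counts.fp + counts.tn == 0:
        raise ValueError("specificity undefined: no negative voxels")
    return counts.tn / (counts.fp + counts.tn)


def sensitivity(counts: ConfusionCounts) -> float:
    """True-positive rate TP / (TP + FN)."""
    if counts.tp + counts.fn == 0:
        raise ValueError("sensitivity undefined: empty ground truth")
    return counts.tp / (counts.tp + counts.fn)


def auc_balanced(counts: ConfusionCounts) -> float:
    """1 - (FPR + FNR)/2; algebraically equal to (SN + SP)/2."""
    if counts.fp + counts.tn == 0 or counts.tp + counts.fn == 0:
        raise ValueError("balanced accuracy requires both classes present")
    fpr = counts.fp / (counts.fp + counts.tn)
    fnr = counts.fn / (counts.fn + counts.tp)
    return 1.0 - 0.5 * (fpr + fnr)


def evaluate(prediction, truth) -> MetricsReport:
    """All five measures plus counts for one prediction/truth pair."""
    counts = confusion_counts(prediction, truth)
    return MetricsReport(
        dsc=dice(prediction, truth),
        oc=overlap_coefficient(prediction, truth),
        sp=specificity(counts),
        sn=sensitivity(counts),
        auc=auc_balanced(counts),
        counts=counts,
    )
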