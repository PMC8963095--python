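"""Augmentation and training protocol for the three model variants.

One network is trained per target label (M1 fissures, M2 tissue-with-
fissures, M3 whole cerebellum).  Training/validation images are augmented
offline with random rigid transforms — rotations in [-10°, 10°] about each
axis and integer shifts in [-10, 10] voxels on a random subset of axes, 40
augmented copies per image by default.  Images are interpolated linearly,
labels with nearest neighbour and re-binarized, and the triplet invariants
are re-imposed after the transform.  The optimizer is Adam with its default
hyper-parameters; the loss is soft Dice (binary cross-entropy selectable);
volumes are z-scored before entering the network and processed one per step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .architecture import ArchitectureSpec, InceptionUNet, build_unet
from .grids import BinaryMask3D, GridError, IntensityVolume, MaskTriplet
from .nn import Adam
from .nn import functional as F

__all__ = [
    "TrainingConfig",
    "TrainingHistory",
    "TrainResult",
    "random_rigid_params",
    "apply_rigid",
    "augment_image",
    "soft_dice_loss",
    "train_model",
]

logger = logging.getLogger(__name__)

TARGETS = ("fissures", "tissue", "whole")

# train/validation/test proportions of the reference cohort (17/2/5 of 24)
DEFAULT_SPLIT = (17 / 24, 2 / 24, 5 / 24)


@dataclass(frozen=True)
class TrainingConfig:
    """Protocol knobs; defaults follow the reference protocol."""

    target: str = "fissures"
    epochs: int = 120
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    loss: str = "dice"  # or "bce"
    batch_size: int = 1
    augment_per_image: int = 40
    rotation_range: float = 10.0   # degrees, symmetric [-r, r]
    shift_range: int = 10          # voxels, symmetric [-s, s]
    split_fractions: tuple = DEFAULT_SPLIT
    seed: int = 0

    def __post_init__(self):
        if self.target not in TARGETS:
            raise ValueError(f"target must be one of {TARGETS}, got {self.target!r}")
        if self.epochs <= 0:
            raise ValueError("epochs must be positive")
        if self.augment_per_image < 0:
            raise ValueError("augment_per_image must be >= 0")
        if self.rotation_range < 0 or self.shift_range < 0:
            raise ValueError("rotation/shift ranges must be non-negative")
        if self.loss not in ("dice", "bce"):
            raise ValueError("loss must be 'dice' or 'bce'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["split_fractions"] = list(self.split_fractions)
        return d


@dataclass
class TrainingHistory:
    """Per-epoch curves (lengths equal the number of epochs)."""

    train_loss: list = field(default_factory=list)
    train_dsc: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_dsc: list = field(default_factory=list)

    def __len__(self):
        return len(self.train_loss)

    def to_rows(self):
        for i in range(len(self)):
            yield {"epoch": i + 1, "train_loss": self.train_loss[i],
                   "train_dsc": self.train_dsc[i], "val_loss": self.val_loss[i],
                   "val_dsc": self.val_dsc[i]}


@dataclass
class TrainResult:
    """Trained network plus history and both weight sets.

    ``model`` holds the best-validation weights; ``final_state`` the weights
    after the last epoch.
    """

    model: InceptionUNet
    history: TrainingHistory
    best_state: dict
    final_state: dict
    best_epoch: int
    config: TrainingConfig


# ---------------------------------------------------------------------------
# rigid augmentation
# ---------------------------------------------------------------------------

def random_rigid_params(config: TrainingConfig, rng: np.random.Generator):
    """One random rigid draw: per-axis rotation angles (degrees), integer
    shifts, and the random subset of axes the shifts act on."""
    angles = rng.uniform(-config.rotation_range, config.rotation_range, size=3)
    axes = tuple(int(a) for a in np.flatnonzero(rng.random(3) < 0.5))
    shifts = np.zeros(3, dtype=int)
    if axes:
        shifts[list(axes)] = rng.integers(-config.shift_range, config.shift_range + 1,
                                          size=len(axes))
    return tuple(angles), tuple(int(s) for s in shifts), axes


_ROT_PLANES = ((1, 2), (0, 2), (0, 1))  # rotation plane about each axis


def apply_rigid(data: np.ndarray, angles, shifts, order: int) -> np.ndarray:
    """Rotate about the three axes then shift; constant (0) boundary fill."""
    out = data.astype(np.float32)
    for axis, angle in enumerate(angles):
        if angle != 0.0:
            out = ndimage.rotate(out, angle, axes=_ROT_PLANES[axis], reshape=False,
                                 order=order, mode="constant", cval=0.0)
    if any(shifts):
        out = ndimage.shift(out, shifts, order=order, mode="constant", cval=0.0)
    return out


def _transform_pair(volume: IntensityVolume, labels: MaskTriplet, angles, shifts):
    img = apply_rigid(volume.data, angles, shifts, order=1)
    whole = apply_rigid(labels.whole.data, angles, shifts, order=0) > 0.5
    fiss = apply_rigid(labels.fissures.data, angles, shifts, order=0) > 0.5
    fiss &= whole  # re-impose containment after independent interpolation
    triplet = MaskTriplet(
        fissures=labels.fissures.with_data(fiss),
        tissue=labels.tissue.with_data(whole & ~fiss),
        whole=labels.whole.with_data(whole),
    )
    return volume.with_data(img), triplet


def augment_image(volume: IntensityVolume, labels: MaskTriplet,
                  config: TrainingConfig, seed: int) -> list:
    """``config.augment_per_image`` rigidly transformed (volume, triplet) pairs.

    The same transform is applied to the image and all three labels; labels
    use nearest-neighbour interpolation and are re-binarized, and the triplet
    invariants are restored by construction afterwards.
    """
    volume.require_congruent(labels.whole, "volume/labels")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(config.augment_per_image):
        angles, shifts, _ = random_rigid_params(config, rng)
        out.append(_transform_pair(volume, labels, angles, shifts))
    return out


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def soft_dice_loss(prediction: np.ndarray, truth) -> float:
    """1 - Dice with the squared-sum denominator, evaluated on soft values."""
    p = np.asarray(prediction, dtype=np.float64)
    g = np.asarray(truth.data if isinstance(truth, BinaryMask3D) else truth,
                   dtype=np.float64)
    if p.shape != g.shape:
        raise GridError(f"prediction/truth shape mismatch: {p.shape} vs {g.shape}")
    den = (p ** 2).sum() + (g ** 2).sum()
    if den == 0:
        return 0.0
    return float(1.0 - 2.0 * (p * g).sum() / den)


def _hard_dice(prob: np.ndarray, g: np.ndarray, cut: float = 0.5) -> float:
    p = prob >= cut
    gb = g > 0.5
    den = p.sum() + gb.sum()
    if den == 0:
        return 1.0
    return float(2.0 * (p & gb).sum() / den)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _zscore(arr: np.ndarray) -> np.ndarray:
    sd = arr.std()
    if sd == 0:
        raise GridError("cannot train on a constant volume")
    return ((arr - arr.mean()) / sd).astype(np.float32)


def _prepare(samples, target: str):
    """(z-scored image, float target mask) arrays with a channel axis."""
    out = []
    for vol, labels in samples:
        x = _zscore(np.asarray(vol.data, dtype=np.float32))[None]
        y = labels.select(target).data.astype(np.float32)[None]
        out.append((x, y))
    return out


def train_model(spec: ArchitectureSpec, train_samples, val_samples,
                config: TrainingConfig) -> TrainResult:
    """Train one model variant on (volume, triplet) pairs.

    Augmentation (``config.augment_per_image`` rigid copies per image) is
    applied to both the training and validation partitions before training.
    Keeps the best-validation-Dice checkpoint alongside the final weights.
    """
    if not train_samples or not val_samples:
        raise ValueError("training requires nonempty train and validation partitions")
    rng = np.random.default_rng(config.seed)

    def expanded(samples):
        full = list(samples)
        if config.augment_per_image > 0:
            for vol, labels in samples:
                full.extend(augment_image(vol, labels, config,
                                          seed=int(rng.integers(2 ** 31 - 1))))
        return full

    train_data = _prepare(expanded(train_samples), config.target)
    val_data = _prepare(expanded(val_samples), config.target)
    logger.info("training target=%s on %d volumes (%d validation)",
                config.target, len(train_data), len(val_data))

    model = build_unet(spec, seed=config.seed)
    model.reseed_dropout(config.seed + 1)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    loss_fn = F.soft_dice_loss_t if config.loss == "dice" else F.bce_loss_t

    history = TrainingHistory()
    best = {"dsc": -1.0, "state": model.state_dict(), "epoch": 0}
    order = np.arange(len(train_data))
    for epoch in range(config.epochs):
        rng.shuffle(order)
        ep_loss, ep_dsc = [], []
        for i in order:
            x, y = train_data[i]
            out = model.forward(x, training=True)
            loss = loss_fn(out, y)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch + 1} (sample {i}); "
                    "try a lower learning rate")
            model.zero_grad()
            loss.backward()
            opt.step()
            ep_loss.append(float(loss.data))
            ep_dsc.append(_hard_dice(out.data, y))
        vl, vd = [], []
        for x, y in val_data:
            out = model.forward(x, training=False)
            vl.append(float(loss_fn(out, y).data))
            vd.append(_hard_dice(out.data, y))
        history.train_loss.append(float(np.mean(ep_loss)))
        history.train_dsc.append(float(np.mean(ep_dsc)))
        history.val_loss.append(float(np.mean(vl)))
        history.val_dsc.append(float(np.mean(vd)))
        if history.val_dsc[-1] > best["dsc"]:
            best = {"dsc": history.val_dsc[-1], "state": model.state_dict(),
                    "epoch": epoch + 1}
        logger.info("epoch %d/%d loss %.4f val DSC %.4f", epoch + 1, config.epochs,
                    history.train_loss[-1], history.val_dsc[-1])

    final_state = model.state_dict()
    model.load_state_dict(best["state"])
    return TrainResult(model=model, history=history, best_state=best["state"],
                       final_state=final_state, best_epoch=best["epoch"], config=config)


def split_samples(samples, fractions=DEFAULT_SPLIT, seed: int = 0):
    """Shuffle and split into train/validation/test partitions by fractions."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    idx = np.random.default_rng(seed).permutation(len(samples))
    n = len(samples)
    n_train = max(1, round(fractions[0] * n))
    n_val = max(1, round(fractions[1] * n))
    train = [samples[i] for i in idx[:n_train]]
    val = [samples[i] for i in idx[n_train:n_train + n_val]]
    test = [samples[i] for i in idx[n_train + n_val:]]
    return train, val, test
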