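"""End-to-end pipeline configuration and runner.

``run_pipeline`` chains phantom generation, contrast enhancement, label
construction, training, segmentation of held-out volumes, and evaluation,
writing NIfTI artifacts, a training-history CSV, and a metrics CSV to an
output directory.  The whole run is reproducible from the configured seed.
"""

from __future__ import annotations

import json
import logging
import pickle
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .architecture import ArchitectureSpec
from .grids import MaskTriplet
from .inference import segment
from .io import write_volume
from .maskgen import MaskGenConfig, build_label_triplet, qc_report
from .metrics import METRIC_COLUMNS, evaluate
from .phantom import PhantomParams, generate_cohort
from .preprocess import crop_mask, crop_to_mask, enhance_contrast
from .training import TrainingConfig, train_model

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Serializable bundle of every stage's settings."""

    n_phantoms: int = 10
    phantom: PhantomParams = field(default_factory=PhantomParams)
    arch: ArchitectureSpec = field(default_factory=ArchitectureSpec)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    maskgen: MaskGenConfig = field(default_factory=MaskGenConfig)
    crop_margin: int = 4
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "n_phantoms": self.n_phantoms,
            "phantom": asdict(self.phantom),
            "arch": self.arch.to_dict(),
            "training": self.training.to_dict(),
            "maskgen": asdict(self.maskgen),
            "crop_margin": self.crop_margin,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = dict(d)
        if "phantom" in kwargs:
            p = dict(kwargs["phantom"])
            for key in ("grid_shape", "ellipsoid_semi_axes"):
                if key in p:
                    p[key] = tuple(p[key])
            kwargs["phantom"] = PhantomParams(**p)
        if "arch" in kwargs:
            kwargs["arch"] = ArchitectureSpec.from_dict(kwargs["arch"])
        if "training" in kwargs:
            t = dict(kwargs["training"])
            if "split_fractions" in t:
                t["split_fractions"] = tuple(t["split_fractions"])
            kwargs["training"] = TrainingConfig(**t)
        if "maskgen" in kwargs:
            kwargs["maskgen"] = MaskGenConfig(**kwargs["maskgen"])
        return cls(**kwargs)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(data)


def _stage(name):
    logger.info("stage: %s", name)
    return time.time()


def _pad_sample(volume, triplet: MaskTriplet, multiple: int):
    """Pad a cropped sample so its dims divide the network's downsampling
    factor: edge replication for the image, zeros for the labels."""
    shape = volume.shape
    target = tuple(int(np.ceil(s / multiple) * multiple) for s in shape)
    if target == shape:
        return volume, triplet
    pads = [(0, t - s) for s, t in zip(shape, target)]

    def pad_mask(m):
        return m.with_data(np.pad(m.data, pads))

    padded = volume.with_data(np.pad(volume.data, pads, mode="edge"))
    return padded, MaskTriplet(fissures=pad_mask(triplet.fissures),
                               tissue=pad_mask(triplet.tissue),
                               whole=pad_mask(triplet.whole))


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run phantom -> preprocess -> label construction -> train -> segment ->
    evaluate; returns a small dict of artifact paths and summary numbers."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings = {}

    t0 = _stage("phantom")
    cohort = generate_cohort(config.n_phantoms, params=config.phantom, seed=config.seed)
    timings["phantom"] = time.time() - t0

    # preprocess + derive labels from the phantom's "external" cerebellar mask
    t0 = _stage("preprocess+maskgen")
    k = config.arch.downsample_factor
    samples, qc = [], []
    for i, s in enumerate(cohort):
        enhanced = enhance_contrast(s.volume)
        cropped, box = crop_to_mask(enhanced, s.truth.whole, margin=config.crop_margin)
        triplet = build_label_triplet(cropped, crop_mask(s.truth.whole, box),
                                      config.maskgen)
        cropped, triplet = _pad_sample(cropped, triplet, k)
        samples.append((cropped, triplet))
        qc.append({"phantom": i + 1, **qc_report(triplet)})
    pd.DataFrame(qc).to_csv(outdir / "label_qc.csv", index=False)
    timings["preprocess"] = time.time() - t0

    t0 = _stage("train")
    n = len(samples)
    n_train = max(1, round(config.training.split_fractions[0] * n))
    n_val = max(1, round(config.training.split_fractions[1] * n))
    train, val = samples[:n_train], samples[n_train:n_train + n_val]
    test = samples[n_train + n_val:] or val
    result = train_model(config.arch, train, val, config.training)
    pd.DataFrame(result.history.to_rows()).to_csv(outdir / "history.csv", index=False)
    for tag, state in (("best", result.best_state), ("final", result.final_state)):
        with open(outdir / f"weights_{tag}.pkl", "wb") as fh:
            pickle.dump({"arch": config.arch.to_dict(), "state": state,
                         "target": config.training.target}, fh)
    timings["train"] = time.time() - t0

    t0 = _stage("segment+evaluate")
    rows = []
    postprocess = config.training.target != "fissures"
    for i, (vol, labels) in enumerate(test):
        pred = segment(result.model, vol, postprocess=postprocess)
        write_volume(pred.mask, outdir / f"test{i + 1:02d}_{config.training.target}_mask.nii.gz",
                     force=True)
        rep = evaluate(pred.mask, labels.select(config.training.target))
        rows.append({"volume": i + 1, **dict(zip(METRIC_COLUMNS, rep.row()))})
    table = pd.DataFrame(rows)
    table.to_csv(outdir / "metrics.csv", index=False)
    timings["evaluate"] = time.time() - t0

    summary = {
        "outdir": str(outdir),
        "mean_dsc": float(table["DSC"].mean()),
        "timings_s": {k: round(v, 2) for k, v in timings.items()},
        "best_epoch": result.best_epoch,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    logger.info("pipeline done: mean DSC %.3f", summary["mean_dsc"])
    return summary
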