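"""Inception-U-Net architecture for binary cerebellar segmentation.

The network is a U-Net whose convolutional blocks are inception modules:
four parallel branches (1-, 3- and 5-wide convolutions plus a stride-1
max-pool followed by a 1-wide convolution), each emitting ``filter_param``
feature maps, concatenated to ``4 * filter_param`` maps.  Every convolution
is followed by a ReLU, every inception module by an instance-normalization
layer.  The encoder has four down-sampling stages, the bottleneck chains two
inception modules, and the decoder mirrors the encoder with skip
concatenations — ten inception modules in total with the default filter
schedule 16, 16, 32, 64, 128 (contracting) / 128, 64, 32, 16, 16 (expanding).
A dropout layer sits before the final single-filter convolution, whose
sigmoid output is the voxelwise foreground probability.

The same class supports a 2D mode (``spatial_rank=2``) for cheap tests and a
reduced filter schedule for desk-scale experiments; the structural
invariants (4x rule, module count, shape preservation) are identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import nn
from .nn import functional as F
from .nn.autodiff import Tensor

__all__ = [
    "ArchitectureSpec",
    "InceptionModule",
    "InceptionUNet",
    "ModuleGraph",
    "ShapeError",
    "build_inception_module",
    "build_unet",
    "count_feature_maps",
]

DEFAULT_ENCODER = (16, 16, 32, 64, 128)
DEFAULT_DECODER = (128, 64, 32, 16, 16)


class ShapeError(ValueError):
    """Raised when an input shape is incompatible with the down-sampling depth."""


@dataclass(frozen=True)
class ArchitectureSpec:
    """Hyper-parameters defining one inception-U-Net.

    ``encoder_filters`` lists the filter parameter of the four contracting
    stages plus the first bottleneck module; ``decoder_filters`` lists the
    second bottleneck module plus the four expanding stages.  Each inception
    module outputs four times its filter parameter.
    """

    encoder_filters: tuple = DEFAULT_ENCODER
    decoder_filters: tuple = DEFAULT_DECODER
    dropout_rate: float = 0.3
    spatial_rank: int = 3
    input_channels: int = 1
    output_channels: int = 1

    def __post_init__(self):
        object.__setattr__(self, "encoder_filters", tuple(int(f) for f in self.encoder_filters))
        object.__setattr__(self, "decoder_filters", tuple(int(f) for f in self.decoder_filters))
        if len(self.encoder_filters) != len(self.decoder_filters):
            raise ValueError("encoder and decoder filter sequences must have equal length")
        if len(self.encoder_filters) != 5:
            raise ValueError("expected 5 filter counts (4 stages + bottleneck half)")
        if any(f <= 0 for f in self.encoder_filters + self.decoder_filters):
            raise ValueError("filter counts must be positive")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0,1)")
        if self.spatial_rank not in (2, 3):
            raise ValueError("spatial_rank must be 2 or 3")
        if self.input_channels <= 0 or self.output_channels <= 0:
            raise ValueError("channel counts must be positive")

    @property
    def n_stages(self) -> int:
        return len(self.encoder_filters) - 1

    @property
    def downsample_factor(self) -> int:
        """Input spatial dims must be divisible by this (2^stages)."""
        return 2 ** self.n_stages

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["encoder_filters"] = list(self.encoder_filters)
        d["decoder_filters"] = list(self.decoder_filters)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ArchitectureSpec":
        return cls.from_dict(yaml.safe_load(text))

    @classmethod
    def from_file(cls, path) -> "ArchitectureSpec":
        text = open(path).read()
        if str(path).endswith(".json"):
            return cls.from_dict(json.loads(text))
        return cls.from_yaml(text)


@dataclass
class BlockRecord:
    """One entry of a :class:`ModuleGraph`."""

    name: str
    kind: str  # inception | norm | pool | upconv | dropout | final_conv
    filter_param: int | None
    in_channels: int
    out_channels: int
    scale: float  # spatial scale relative to the input (1, 1/2, ...)


@dataclass
class ModuleGraph:
    """Ordered structural description of a built network."""

    blocks: list = field(default_factory=list)

    def add(self, *args, **kwargs):
        self.blocks.append(BlockRecord(*args, **kwargs))

    @property
    def inception_blocks(self):
        return [b for b in self.blocks if b.kind == "inception"]

    @property
    def n_inception_modules(self) -> int:
        return len(self.inception_blocks)

    def summary(self) -> str:
        lines = [f"{'block':<22}{'kind':<12}{'filter':>7}{'in':>6}{'out':>6}{'scale':>8}"]
        for b in self.blocks:
            f = "" if b.filter_param is None else str(b.filter_param)
            lines.append(f"{b.name:<22}{b.kind:<12}{f:>7}{b.in_channels:>6}{b.out_channels:>6}{b.scale:>8.3g}")
        lines.append(f"inception modules: {self.n_inception_modules}")
        return "\n".join(lines)


class InceptionModule(nn.Module):
    """Four-branch inception block preserving spatial shape.

    Branches: 1-conv, 3-conv, 5-conv, and max-pool(3, stride 1) -> 1-conv,
    each followed by ReLU and emitting ``filter_param`` maps; the channel
    concatenation therefore carries ``4 * filter_param`` maps.
    """

    def __init__(self, in_channels: int, filter_param: int, rank: int, rng):
        if filter_param <= 0:
            raise ValueError(f"filter_param must be positive, got {filter_param}")
        self.branch1 = nn.ConvNd(in_channels, filter_param, 1, rank, rng)
        self.branch3 = nn.ConvNd(in_channels, filter_param, 3, rank, rng)
        self.branch5 = nn.ConvNd(in_channels, filter_param, 5, rank, rng)
        self.branch_pool = nn.ConvNd(in_channels, filter_param, 1, rank, rng)
        self.filter_param = filter_param
        self.in_channels = in_channels
        self.out_channels = 4 * filter_param

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        return F.concat([
            F.relu(self.branch1(x)),
            F.relu(self.branch3(x)),
            F.relu(self.branch5(x)),
            F.relu(self.branch_pool(F.maxpool_same(x, 3))),
        ])


class InceptionUNet(nn.Module):
    """The full encoder/bottleneck/decoder network (see module docstring)."""

    def __init__(self, spec: ArchitectureSpec, seed: int = 0):
        rng = np.random.default_rng(seed)
        r = spec.spatial_rank
        self.spec = spec
        graph = ModuleGraph()
        enc_f = spec.encoder_filters
        dec_f = spec.decoder_filters
        n_stages = spec.n_stages

        # encoder stages: inception -> instance norm -> (skip) -> maxpool/2
        self.enc_modules, self.enc_norms = [], []
        c = spec.input_channels
        scale = 1.0
        for i in range(n_stages):
            m = InceptionModule(c, enc_f[i], r, rng)
            self.enc_modules.append(m)
            self.enc_norms.append(nn.InstanceNorm(m.out_channels))
            graph.add(f"enc{i + 1}", "inception", enc_f[i], c, m.out_channels, scale)
            graph.add(f"enc{i + 1}_norm", "norm", None, m.out_channels, m.out_channels, scale)
            graph.add(f"pool{i + 1}", "pool", None, m.out_channels, m.out_channels, scale / 2)
            c = m.out_channels
            scale /= 2

        # bottleneck: two chained inception modules
        self.bottleneck1 = InceptionModule(c, enc_f[-1], r, rng)
        self.bn_norm1 = nn.InstanceNorm(self.bottleneck1.out_channels)
        graph.add("bottleneck1", "inception", enc_f[-1], c, self.bottleneck1.out_channels, scale)
        graph.add("bottleneck1_norm", "norm", None, self.bottleneck1.out_channels,
                  self.bottleneck1.out_channels, scale)
        c = self.bottleneck1.out_channels
        self.bottleneck2 = InceptionModule(c, dec_f[0], r, rng)
        self.bn_norm2 = nn.InstanceNorm(self.bottleneck2.out_channels)
        graph.add("bottleneck2", "inception", dec_f[0], c, self.bottleneck2.out_channels, scale)
        graph.add("bottleneck2_norm", "norm", None, self.bottleneck2.out_channels,
                  self.bottleneck2.out_channels, scale)
        c = self.bottleneck2.out_channels

        # decoder stages: upconv/2 -> concat skip -> inception -> norm
        self.upconvs, self.dec_modules, self.dec_norms = [], [], []
        for j in range(n_stages):
            up_out = max(c // 2, 1)
            up = nn.ConvTransposeNd(c, up_out, r, rng)
            self.upconvs.append(up)
            scale *= 2
            graph.add(f"up{j + 1}", "upconv", None, c, up_out, scale)
            skip_ch = self.enc_modules[n_stages - 1 - j].out_channels
            m = InceptionModule(up_out + skip_ch, dec_f[j + 1], r, rng)
            self.dec_modules.append(m)
            self.dec_norms.append(nn.InstanceNorm(m.out_channels))
            graph.add(f"dec{j + 1}", "inception", dec_f[j + 1], up_out + skip_ch,
                      m.out_channels, scale)
            graph.add(f"dec{j + 1}_norm", "norm", None, m.out_channels, m.out_channels, scale)
            c = m.out_channels

        self.dropout = nn.Dropout(spec.dropout_rate)
        graph.add("dropout", "dropout", None, c, c, scale)
        self.final_conv = nn.ConvNd(c, spec.output_channels, 1, r, rng)
        graph.add("final_conv", "final_conv", None, c, spec.output_channels, scale)

        self.graph = graph
        self._dropout_rng = np.random.default_rng(seed + 1)

    # -- forward ------------------------------------------------------------
    def check_input_shape(self, shape):
        spatial = shape[1:]
        if len(spatial) != self.spec.spatial_rank:
            raise ShapeError(
                f"expected (channels, {'x'.join(['S'] * self.spec.spatial_rank)}) input, got {shape}")
        k = self.spec.downsample_factor
        if any(s % k for s in spatial):
            raise ShapeError(
                f"spatial shape {spatial} not divisible by {k} "
                f"({self.spec.n_stages} down-sampling halvings); pad the input, e.g. with "
                f"preprocess.pad_to_multiple(volume, {k})")
        if shape[0] != self.spec.input_channels:
            raise ShapeError(f"expected {self.spec.input_channels} input channels, got {shape[0]}")

    def forward(self, x, training: bool = False) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        self.check_input_shape(x.shape)
        skips = []
        for mod, norm in zip(self.enc_modules, self.enc_norms):
            x = norm(mod(x))
            skips.append(x)
            x = F.maxpool_down(x)
        x = self.bn_norm1(self.bottleneck1(x))
        x = self.bn_norm2(self.bottleneck2(x))
        for up, mod, norm, skip in zip(self.upconvs, self.dec_modules, self.dec_norms,
                                       reversed(skips)):
            x = F.relu(up(x))
            x = F.concat([x, skip])
            x = norm(mod(x))
        x = self.dropout(x, self._dropout_rng, training)
        return F.sigmoid(self.final_conv(x))

    def predict(self, volume: np.ndarray) -> np.ndarray:
        """Foreground probabilities for a raw ``(*spatial)`` array (eval mode)."""
        arr = np.asarray(volume, dtype=np.float32)
        if arr.ndim == self.spec.spatial_rank:
            arr = arr[None]
        return self.forward(Tensor(arr), training=False).data[0]

    def reseed_dropout(self, seed: int):
        self._dropout_rng = np.random.default_rng(seed)

    def summary(self) -> str:
        head = (f"InceptionUNet(rank={self.spec.spatial_rank}, "
                f"params={self.num_parameters():,})")
        return head + "\n" + self.graph.summary()


# ---------------------------------------------------------------------------
# functional constructors / reports
# ---------------------------------------------------------------------------

def build_inception_module(filter_param: int, spatial_rank: int = 3,
                           in_channels: int = 1, seed: int = 0) -> InceptionModule:
    """Standalone inception module (its output carries 4*filter_param maps)."""
    return InceptionModule(in_channels, filter_param, spatial_rank, np.random.default_rng(seed))


def build_unet(spec: ArchitectureSpec | None = None, seed: int = 0) -> InceptionUNet:
    """Construct the network; its ``.graph`` attribute is the ModuleGraph."""
    return InceptionUNet(spec or ArchitectureSpec(), seed=seed)


def count_feature_maps(obj) -> list:
    """Output feature-map count (4x the filter parameter) of each inception
    module, in network order."""
    graph = obj.graph if isinstance(obj, InceptionUNet) else obj
    return [b.out_channels for b in graph.inception_blocks]
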