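"""Layer/module system over the autodiff tensors.

Mirrors the familiar Module/Parameter idiom: a :class:`Module` owns
:class:`~fissnet.nn.autodiff.Parameter` leaves and sub-modules, exposes
``parameters()`` and a copyable ``state_dict()``.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as F
from .autodiff import Parameter, Tensor

__all__ = ["Module", "ConvNd", "ConvTransposeNd", "InstanceNorm", "Dropout"]


class Module:
    """Base class: parameter discovery through instance attributes."""

    def named_parameters(self, prefix=""):
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield key, val
            elif isinstance(val, Module):
                yield from val.named_parameters(prefix=key + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{key}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self) -> dict:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"state dict mismatch: {sorted(missing)[:5]}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = state[k].astype(np.float32).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng: np.random.Generator, shape, fan_in) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class ConvNd(Module):
    """'Same' convolution with odd kernel, He-initialized."""

    def __init__(self, in_channels, out_channels, kernel_size, rank, rng, bias=True):
        kshape = (out_channels, in_channels) + (kernel_size,) * rank
        fan_in = in_channels * kernel_size ** rank
        self.weight = Parameter(_he_init(rng, kshape, fan_in))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel_size = kernel_size

    def forward(self, x: Tensor) -> Tensor:
        return F.convnd(x, self.weight, self.bias)


class ConvTransposeNd(Module):
    """Kernel-2 stride-2 transposed convolution (2x upsampling)."""

    def __init__(self, in_channels, out_channels, rank, rng, bias=True):
        kshape = (out_channels, in_channels) + (2,) * rank
        fan_in = in_channels * 2 ** rank
        self.weight = Parameter(_he_init(rng, kshape, fan_in))
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32)) if bias else None
        self.in_channels, self.out_channels = in_channels, out_channels

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose_nd(x, self.weight, self.bias)


class InstanceNorm(Module):
    """Per-channel spatial normalization with learnable scale and shift."""

    def __init__(self, channels, eps=1e-5):
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return F.instance_norm(x, self.gamma, self.beta, self.eps)


class Dropout(Module):
    def __init__(self, p):
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {p}")
        self.p = p

    def forward(self, x: Tensor, rng: np.random.Generator, training: bool) -> Tensor:
        return F.dropout(x, self.p, rng, training)
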