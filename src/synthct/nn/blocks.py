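"""Convolutional building blocks: ConvBlock and the multi-scale InceptionBlock.

A ConvBlock is conv -> instance norm -> activation (swish by default).  An
InceptionBlock runs four ConvBlocks with kernel sizes 1/5/7/11 in parallel and
concatenates their feature maps, giving simultaneous small- and large-
receptive-field views of the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Conv2d, InstanceNorm2d, Module, Sigmoid, Swish

__all__ = ["ConvBlockConfig", "InceptionBlockConfig", "ConvBlock",
           "InceptionBlock", "build_conv_block", "build_inception_block"]

_VALID_KERNELS = (1, 3, 4, 5, 7, 11)
INCEPTION_KERNELS = (1, 5, 7, 11)


@dataclass(frozen=True)
class ConvBlockConfig:
    in_channels: int
    out_channels: int
    kernel_size: int = 3
    stride: int = 1
    use_bias: bool = True
    normalization: bool = True     # affine instance normalization
    activation: str = "swish"      # "swish" | "sigmoid" | "none"

    def __post_init__(self):
        if self.kernel_size not in _VALID_KERNELS:
            raise ValueError(f"kernel_size must be one of {_VALID_KERNELS}")
        if self.stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        if self.out_channels < 1:
            raise ValueError("out_channels must be >= 1")
        if self.activation not in ("swish", "sigmoid", "none"):
            raise ValueError(f"unknown activation {self.activation!r}")


@dataclass(frozen=True)
class InceptionBlockConfig:
    in_channels: int
    branch_channels: int
    branch_kernels: tuple[int, ...] = field(default=INCEPTION_KERNELS)

    def __post_init__(self):
        if self.branch_channels < 1:
            raise ValueError("branch_channels must be >= 1")

    @property
    def out_channels(self) -> int:
        return len(self.branch_kernels) * self.branch_channels


class ConvBlock(Module):
    def __init__(self, config: ConvBlockConfig, rng: np.random.Generator | None = None):
        self.config = config
        # std 0.02 is the GAN convention for normalized blocks; without a norm
        # layer it collapses activations, so fall back to He initialization
        if config.normalization:
            init_std = 0.02
        else:
            fan_in = config.in_channels * config.kernel_size ** 2
            init_std = float(np.sqrt(2.0 / fan_in))
        self.conv = Conv2d(config.in_channels, config.out_channels,
                           config.kernel_size, stride=config.stride,
                           use_bias=config.use_bias, rng=rng,
                           init_std=init_std)
        self.norm = InstanceNorm2d(config.out_channels) if config.normalization else None
        if config.activation == "swish":
            self.act = Swish()
        elif config.activation == "sigmoid":
            self.act = Sigmoid()
        else:
            self.act = None

    @property
    def out_channels(self) -> int:
        return self.config.out_channels

    def forward(self, x: np.ndarray):
        y, c_conv = self.conv.forward(x)
        c_norm = None
        if self.norm is not None:
            y, c_norm = self.norm.forward(y)
        c_act = None
        if self.act is not None:
            y, c_act = self.act.forward(y)
        return y, (c_conv, c_norm, c_act)

    def backward(self, dy: np.ndarray, cache):
        c_conv, c_norm, c_act = cache
        if self.act is not None:
            dy = self.act.backward(dy, c_act)
        if self.norm is not None:
            dy = self.norm.backward(dy, c_norm)
        return self.conv.backward(dy, c_conv)


class InceptionBlock(Module):
    def __init__(self, config: InceptionBlockConfig,
                 rng: np.random.Generator | None = None,
                 use_bias: bool = True):
        self.config = config
        self.branches = [
            ConvBlock(ConvBlockConfig(config.in_channels, config.branch_channels,
                                      kernel_size=k, use_bias=use_bias), rng=rng)
            for k in config.branch_kernels
        ]

    @property
    def out_channels(self) -> int:
        return self.config.out_channels

    def forward(self, x: np.ndarray):
        outs, caches = [], []
        for br in self.branches:
            y, c = br.forward(x)
            outs.append(y)
            caches.append(c)
        return np.concatenate(outs, axis=1), caches

    def backward(self, dy: np.ndarray, caches):
        b = self.config.branch_channels
        dx = None
        for i, (br, c) in enumerate(zip(self.branches, caches)):
            d = br.backward(dy[:, i * b:(i + 1) * b], c)
            dx = d if dx is None else dx + d
        return dx


def build_conv_block(config: ConvBlockConfig,
                     rng: np.random.Generator | None = None) -> ConvBlock:
    return ConvBlock(config, rng=rng)


def build_inception_block(config: InceptionBlockConfig,
                          rng: np.random.Generator | None = None) -> InceptionBlock:
    return InceptionBlock(config, rng=rng)
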