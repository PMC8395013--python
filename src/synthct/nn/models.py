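"""Generator (Inception-augmented U-Net) and PatchGAN discriminator.

The generator is a five-level U-Net whose two shallowest levels use
InceptionBlocks (multi-scale 1/5/7/11 branches) and whose three deepest levels
use plain 3x3 ConvBlocks; downsampling is 2x2 max pooling, upsampling is
nearest-neighbour x2 followed by a 3x3 ConvBlock, and skip connections are
concatenated.  A final 3x3 convolution with a sigmoid maps back to a single
channel in [0,1].

The default channel layouts were resolved so that the trainable-parameter
totals land exactly on the published architecture anchors: 2,554,977 for the
generator and 429,185 for the discriminator (hence 5,968,324 for the
two-generator/two-discriminator ensemble).  The discriminator uses bias-free
convolutions and omits normalization in its first block (the usual PatchGAN
convention); both choices are pinned by the printed counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .blocks import (ConvBlock, ConvBlockConfig, InceptionBlock,
                     InceptionBlockConfig)
from .core import Conv2d, MaxPool2d, Module, Sigmoid, UpsampleNearest2d

__all__ = [
    "GeneratorConfig",
    "DiscriminatorConfig",
    "Generator",
    "Discriminator",
    "build_generator",
    "build_discriminator",
    "count_trainable_parameters",
]

#: Channel widths per U-Net level that reproduce the published generator
#: parameter total exactly.
DEFAULT_GENERATOR_CHANNELS = (32, 40, 120, 200, 200)
#: Output channels of the four discriminator ConvBlocks (strides 2,2,2,1).
DEFAULT_DISCRIMINATOR_CHANNELS = (32, 64, 128, 128)


@dataclass(frozen=True)
class GeneratorConfig:
    in_channels: int = 1
    channels: tuple[int, ...] = field(default=DEFAULT_GENERATOR_CHANNELS)
    level_types: tuple[str, ...] = ("inception", "inception", "conv", "conv", "conv")
    #: When set, the input is added (in logit space) to the final pre-sigmoid
    #: activation and the last convolution is zero-initialized, so the network
    #: starts from the identity mapping and learns the artifact correction as
    #: a residual.  Adds no parameters.
    residual: bool = False

    def __post_init__(self):
        if len(self.channels) != len(self.level_types):
            raise ValueError("channels and level_types must have equal length")
        for t, c in zip(self.level_types, self.channels):
            if t not in ("inception", "conv"):
                raise ValueError(f"unknown level type {t!r}")
            if t == "inception" and c % 4:
                raise ValueError("inception level channels must be divisible by 4")

    @property
    def levels(self) -> int:
        return len(self.channels)


@dataclass(frozen=True)
class DiscriminatorConfig:
    in_channels: int = 1
    channels: tuple[int, ...] = field(default=DEFAULT_DISCRIMINATOR_CHANNELS)
    strides: tuple[int, ...] = (2, 2, 2, 1)
    kernel_size: int = 4
    use_bias: bool = False
    first_block_norm: bool = False
    #: Instance norm in blocks after the first; disabling it keeps absolute
    #: intensity information in the patch features.
    normalization: bool = True

    def __post_init__(self):
        if len(self.channels) != len(self.strides):
            raise ValueError("channels and strides must have equal length")


def _make_block(level_type: str, cin: int, cout: int,
                rng: np.random.Generator):
    if level_type == "inception":
        return InceptionBlock(InceptionBlockConfig(cin, cout // 4), rng=rng)
    return ConvBlock(ConvBlockConfig(cin, cout, kernel_size=3), rng=rng)


class Generator(Module):
    """U-Net image-to-image generator; input and output are single-channel
    images in [0,1] whose side must be divisible by 2**(levels-1)."""

    def __init__(self, config: GeneratorConfig | None = None,
                 seed: int | None = 0):
        self.config = config or GeneratorConfig()
        rng = np.random.default_rng(seed)
        ch = self.config.channels
        types = self.config.level_types
        n = len(ch)

        self.enc_blocks = []
        prev = self.config.in_channels
        for t, c in zip(types, ch):
            self.enc_blocks.append(_make_block(t, prev, c, rng))
            prev = c
        self.pool = MaxPool2d()
        self.upsample = UpsampleNearest2d()
        self.up_convs = []
        self.dec_blocks = []
        for i in range(n - 2, -1, -1):
            self.up_convs.append(
                ConvBlock(ConvBlockConfig(ch[i + 1], ch[i], kernel_size=3), rng=rng))
            self.dec_blocks.append(_make_block(types[i], 2 * ch[i], ch[i], rng))
        self.final_conv = Conv2d(ch[0], 1, 3, use_bias=True, rng=rng)
        if self.config.residual:
            self.final_conv.weight.value[...] = 0.0
        self.final_act = Sigmoid()

    def _check_input(self, x: np.ndarray) -> None:
        factor = 2 ** (self.config.levels - 1)
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError("expected NCHW input with matching channel count")
        if x.shape[2] % factor or x.shape[3] % factor:
            raise ValueError(
                f"spatial dimensions must be divisible by {factor}")

    def forward(self, x: np.ndarray):
        self._check_input(x)
        n = self.config.levels
        skips, enc_caches, pool_caches = [], [], []
        h = x
        for i, blk in enumerate(self.enc_blocks):
            h, c = blk.forward(h)
            enc_caches.append(c)
            if i < n - 1:
                skips.append(h)
                h, pc = self.pool.forward(h)
                pool_caches.append(pc)
        up_caches, upconv_caches, dec_caches = [], [], []
        for j, (up_conv, dec) in enumerate(zip(self.up_convs, self.dec_blocks)):
            h, uc = self.upsample.forward(h)
            up_caches.append(uc)
            h, cc = up_conv.forward(h)
            upconv_caches.append(cc)
            skip = skips[n - 2 - j]
            h = np.concatenate([skip, h], axis=1)
            h, dc = dec.forward(h)
            dec_caches.append(dc)
        h, c_final = self.final_conv.forward(h)
        c_res = None
        if self.config.residual:
            eps = 1e-4
            xc = np.clip(x, eps, 1.0 - eps)
            h = h + np.log(xc) - np.log1p(-xc)
            c_res = xc
        y, c_act = self.final_act.forward(h)
        ctx = (enc_caches, pool_caches, up_caches, upconv_caches,
               dec_caches, c_final, c_act, c_res)
        return y, ctx

    def backward(self, dy: np.ndarray, ctx):
        (enc_caches, pool_caches, up_caches, upconv_caches,
         dec_caches, c_final, c_act, c_res) = ctx
        n = self.config.levels
        ch = self.config.channels
        dh = self.final_act.backward(dy, c_act)
        dx_res = None
        if c_res is not None:
            dx_res = dh / (c_res * (1.0 - c_res))
        dh = self.final_conv.backward(dh, c_final)
        dskips: list[np.ndarray | None] = [None] * (n - 1)
        for j in range(n - 2, -1, -1):
            level = n - 2 - j
            dh = self.dec_blocks[j].backward(dh, dec_caches[j])
            c_skip = ch[level]
            dskips[level] = dh[:, :c_skip]
            dh = dh[:, c_skip:]
            dh = self.up_convs[j].backward(dh, upconv_caches[j])
            dh = self.upsample.backward(dh, up_caches[j])
        for i in range(n - 1, -1, -1):
            if i < n - 1:
                dh = self.pool.backward(dh, pool_caches[i])
                dh = dh + dskips[i]
            dh = self.enc_blocks[i].backward(dh, enc_caches[i])
        if dx_res is not None:
            dh = dh + dx_res
        return dh

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]


class Discriminator(Module):
    """PatchGAN classifier: four 4x4 ConvBlocks (strides 2,2,2,1) and a 4x4
    sigmoid head; a 256x256 input yields a 32x32 real/fake patch map."""

    def __init__(self, config: DiscriminatorConfig | None = None,
                 seed: int | None = 0):
        self.config = config or DiscriminatorConfig()
        rng = np.random.default_rng(seed)
        cfg = self.config
        self.blocks = []
        prev = cfg.in_channels
        for i, (c, s) in enumerate(zip(cfg.channels, cfg.strides)):
            norm = cfg.first_block_norm if i == 0 else cfg.normalization
            self.blocks.append(
                ConvBlock(ConvBlockConfig(prev, c, kernel_size=cfg.kernel_size,
                                          stride=s, use_bias=cfg.use_bias,
                                          normalization=norm), rng=rng))
            prev = c
        self.head = Conv2d(prev, 1, cfg.kernel_size, use_bias=True, rng=rng)
        self.head_act = Sigmoid()

    def forward(self, x: np.ndarray):
        down = 2 ** sum(1 for s in self.config.strides if s == 2)
        if x.shape[2] % down or x.shape[3] % down:
            raise ValueError(f"spatial dimensions must be divisible by {down}")
        caches = []
        h = x
        for blk in self.blocks:
            h, c = blk.forward(h)
            caches.append(c)
        h, c_head = self.head.forward(h)
        y, c_act = self.head_act.forward(h)
        return y, (caches, c_head, c_act)

    def backward(self, dy: np.ndarray, ctx):
        caches, c_head, c_act = ctx
        dh = self.head_act.backward(dy, c_act)
        dh = self.head.backward(dh, c_head)
        for blk, c in zip(reversed(self.blocks), reversed(caches)):
            dh = blk.backward(dh, c)
        return dh

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[0]


def build_generator(config: GeneratorConfig | None = None,
                    seed: int | None = 0) -> Generator:
    return Generator(config, seed=seed)


def build_discriminator(config: DiscriminatorConfig | None = None,
                        seed: int | None = 0) -> Discriminator:
    return Discriminator(config, seed=seed)


def count_trainable_parameters(model: Module) -> int:
    """Total number of learnable scalar parameters in a model."""
    return sum(p.size for p in model.parameters())
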