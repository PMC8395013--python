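"""Shared domain containers for HU images and paired slices."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: HU clipping window used throughout: air floor to dense-bone/metal ceiling.
HU_MIN = -1024.0
HU_MAX = 3200.0
HU_RANGE = HU_MAX - HU_MIN  # 4224
#: Value assigned to masked-out background: anatomically meaningful air.
AIR_HU = -1000.0


@dataclass
class HUImage:
    """A 2D axial image in Hounsfield units with pixel geometry."""

    pixels: np.ndarray
    pixel_spacing: tuple[float, float] = (1.0, 1.0)  # mm (x, y)
    slice_thickness: float = 3.0  # mm

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2:
            raise ValueError("HUImage expects a 2D pixel array")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("HUImage pixels must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def clipped(self) -> "HUImage":
        return HUImage(np.clip(self.pixels, HU_MIN, HU_MAX),
                       self.pixel_spacing, self.slice_thickness)


@dataclass
class BodyMask:
    """Binary body mask: one connected component, no interior holes."""

    pixels: np.ndarray
    source_shape: tuple[int, int] | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ValueError("BodyMask expects a 2D array")
        if self.source_shape is None:
            self.source_shape = self.pixels.shape

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class NormalizedImage:
    """Image linearly rescaled to [0,1] from the HU clip window."""

    pixels: np.ndarray
    provenance: tuple[float, float] = (HU_MIN, HU_MAX)
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    slice_thickness: float = 3.0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.size and (self.pixels.min() < -1e-6
                                 or self.pixels.max() > 1 + 1e-6):
            raise ValueError("NormalizedImage pixels must lie in [0,1]")


@dataclass
class PairedSlice:
    """A co-registered CT/CBCT slice pair from one subject."""

    ct: HUImage
    cbct: HUImage
    subject_id: str
    isocenter_offset: tuple[int, int] = (0, 0)  # (dx, dy) pixels
    seed: int = 0

    def __post_init__(self):
        if self.ct.shape != self.cbct.shape:
            raise ValueError("ct and cbct must have equal dimensions")
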