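"""Pre-processing: body masking, pair alignment, HU normalization,
resampling, and coherent pair augmentation.

The body mask is built volume-wise: a single Otsu threshold over the whole
volume's histogram, then per slice the largest connected component is kept,
interior holes are filled, and the contour is eroded by one 3x3 step to trim
the partial-volume halo.  HU values are clipped to [-1024, 3200] and mapped
linearly to [0,1]; the inverse map restores HU exactly on the clip window.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.transform import resize as _sk_resize

from .types import (AIR_HU, HU_MAX, HU_MIN, HU_RANGE, BodyMask, HUImage,
                    NormalizedImage, PairedSlice)

__all__ = [
    "DegenerateHistogramError",
    "compute_body_mask",
    "body_mask",
    "apply_mask",
    "align_pair",
    "normalize",
    "denormalize",
    "resample",
    "augment_pair",
]


class DegenerateHistogramError(ValueError):
    """Raised when Otsu thresholding is undefined (constant volume)."""


def _as_stack(volume) -> tuple[np.ndarray, list[HUImage]]:
    if isinstance(volume, HUImage):
        volume = [volume]
    if isinstance(volume, np.ndarray):
        arr = volume[None] if volume.ndim == 2 else volume
        images = [HUImage(s) for s in arr]
    else:
        images = list(volume)
        arr = np.stack([im.pixels for im in images])
    if arr.size == 0:
        raise ValueError("empty volume")
    return np.asarray(arr, dtype=np.float32), images


def compute_body_mask(volume, erosion_iterations: int = 1) -> list[BodyMask]:
    """Per-slice body masks from a volume-wise Otsu threshold.

    Steps per slice: threshold, keep the largest connected component, fill
    interior holes, erode with a 3x3 structuring element.
    """
    arr, images = _as_stack(volume)
    if np.ptp(arr) == 0:
        raise DegenerateHistogramError(
            "volume is constant; Otsu threshold undefined")
    thr = threshold_otsu(arr)
    struct = np.ones((3, 3), dtype=bool)
    masks = []
    for sl in arr:
        fg = sl > thr
        labels, n = ndimage.label(fg)
        if n == 0:
            raise DegenerateHistogramError("no foreground above threshold")
        largest = np.argmax(ndimage.sum_labels(fg, labels, range(1, n + 1))) + 1
        m = labels == largest
        m = ndimage.binary_fill_holes(m)
        if erosion_iterations > 0:
            m = ndimage.binary_erosion(m, structure=struct,
                                       iterations=erosion_iterations)
        masks.append(BodyMask(m, source_shape=sl.shape))
    return masks


def body_mask(image: HUImage, erosion_iterations: int = 1) -> BodyMask:
    """Convenience wrapper: mask of a single slice."""
    return compute_body_mask([image], erosion_iterations)[0]


def apply_mask(image: HUImage, mask: BodyMask,
               background_hu: float = AIR_HU) -> HUImage:
    """Set pixels outside the mask to air; pixels inside are unchanged."""
    m = mask.pixels if isinstance(mask, BodyMask) else np.asarray(mask, bool)
    if image.shape != m.shape:
        raise ValueError("image and mask shapes differ")
    out = image.pixels.copy()
    out[~m] = background_hu
    return HUImage(out, image.pixel_spacing, image.slice_thickness)


def _shift_int(img: np.ndarray, dx: int, dy: int, fill: float) -> np.ndarray:
    out = np.full_like(img, fill)
    h, w = img.shape
    src_y = slice(max(0, -dy), min(h, h - dy))
    src_x = slice(max(0, -dx), min(w, w - dx))
    dst_y = slice(max(0, dy), min(h, h + dy))
    dst_x = slice(max(0, dx), min(w, w + dx))
    if src_y.start < src_y.stop and src_x.start < src_x.stop:
        out[dst_y, dst_x] = img[src_y, src_x]
    return out


def align_pair(cbct: HUImage, ct: HUImage,
               isocenter_offset: tuple[float, float],
               subject_id: str = "", seed: int = 0) -> PairedSlice:
    """Rigidly register a pair from its isocenter offset.

    The offset (dx, dy) is given in mm in the CBCT frame (the shift that was
    applied to the CBCT); it is converted to integer pixels via the pixel
    spacing and undone by translating the CBCT by (-dx, -dy).  Vacated pixels
    are filled with air.  No interpolation or rotation is performed.
    """
    if cbct.pixel_spacing != ct.pixel_spacing:
        raise ValueError("pair must share pixel spacing")
    dx_mm, dy_mm = isocenter_offset
    if not (np.isfinite(dx_mm) and np.isfinite(dy_mm)):
        raise ValueError("isocenter offset must be finite")
    sx, sy = cbct.pixel_spacing
    dx = int(round(dx_mm / sx))
    dy = int(round(dy_mm / sy))
    shifted = _shift_int(cbct.pixels, -dx, -dy, AIR_HU)
    aligned = HUImage(shifted, cbct.pixel_spacing, cbct.slice_thickness)
    return PairedSlice(ct=ct, cbct=aligned, subject_id=subject_id,
                       isocenter_offset=(0, 0), seed=seed)


def normalize(image: HUImage) -> NormalizedImage:
    """Clip to [-1024, 3200] then map linearly to [0,1]."""
    y = (np.clip(image.pixels, HU_MIN, HU_MAX) - HU_MIN) / HU_RANGE
    return NormalizedImage(y.astype(np.float32), (HU_MIN, HU_MAX),
                           image.pixel_spacing, image.slice_thickness)


def denormalize(image: NormalizedImage | np.ndarray) -> HUImage:
    """Inverse of :func:`normalize` on the clip window."""
    if isinstance(image, NormalizedImage):
        px = image.pixels
        spacing, thick = image.pixel_spacing, image.slice_thickness
    else:
        px = np.asarray(image, dtype=np.float32)
        spacing, thick = (1.0, 1.0), 3.0
    if px.size and (px.min() < -1e-6 or px.max() > 1 + 1e-6):
        raise ValueError("denormalize input must lie in [0,1]")
    return HUImage(np.clip(px, 0, 1) * HU_RANGE + HU_MIN, spacing, thick)


def resample(image: HUImage, target_size: int) -> HUImage:
    """Bilinear resampling to a square ``target_size`` grid; pixel spacing is
    rescaled to preserve physical extent."""
    if target_size < 2:
        raise ValueError("target_size must be >= 2")
    h, w = image.shape
    if (h, w) == (target_size, target_size):
        return HUImage(image.pixels.copy(), image.pixel_spacing,
                       image.slice_thickness)
    out = _sk_resize(image.pixels, (target_size, target_size), order=1,
                     mode="edge", anti_aliasing=False, preserve_range=True)
    sx, sy = image.pixel_spacing
    new_spacing = (sx * w / target_size, sy * h / target_size)
    return HUImage(out.astype(np.float32), new_spacing, image.slice_thickness)


def _transform(px: np.ndarray, rotation_k: int, flip: bool) -> np.ndarray:
    out = np.rot90(px, k=rotation_k)
    if flip:
        out = np.fliplr(out)
    return np.ascontiguousarray(out)


def augment_pair(pair: PairedSlice, rotation_k: int, flip: bool) -> PairedSlice:
    """Apply the same rotation (multiple of 90 degrees) and optional
    horizontal flip to both members of a pair; 8 distinct configurations."""
    if rotation_k not in (0, 1, 2, 3):
        raise ValueError("rotation_k must be in {0,1,2,3}")
    h, w = pair.ct.shape
    if h != w:
        raise ValueError("augmentation requires square images")
    ct = HUImage(_transform(pair.ct.pixels, rotation_k, flip),
                 pair.ct.pixel_spacing, pair.ct.slice_thickness)
    cbct = HUImage(_transform(pair.cbct.pixels, rotation_k, flip),
                   pair.cbct.pixel_spacing, pair.cbct.slice_thickness)
    return PairedSlice(ct=ct, cbct=cbct, subject_id=pair.subject_id,
                       isocenter_offset=pair.isocenter_offset, seed=pair.seed)
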