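"""Seeded pelvic-like digital phantoms and CBCT degradation.

A phantom slice is an elliptical soft-tissue body on an air background with
embedded high-density bone structures and optional gas cavities.  The CBCT
degradation operator applies, inside the body, a linear HU miscalibration
(gain/offset), a low-frequency cupping depression, a beam-hardening peripheral
brightening, and additive Gaussian noise; outside a circular field of view all
content is truncated to air.  Anatomical mismatch is emulated by re-drawing
the gas cavities with an independent sub-seed, and a rigid isocenter shift is
applied last.

Every operation is a deterministic function of its inputs and an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .types import AIR_HU, HU_MAX, HU_MIN, HUImage, PairedSlice

__all__ = [
    "PhantomSpec",
    "ArtifactModel",
    "PairedSlice",
    "generate_phantom",
    "body_mask_of",
    "apply_cbct_artifacts",
    "generate_dataset",
    "default_spec_ranges",
    "default_model_ranges",
    "identity_model_ranges",
    "sample_spec",
    "sample_model",
]

#: Gas cavities occupy at most this fraction of the body area.
MAX_CAVITY_AREA_FRACTION = 0.15
#: HU threshold below which an in-body pixel counts as gas.
GAS_THRESHOLD_HU = -500.0


class InvalidSpecError(ValueError):
    pass


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and tissue parameters of one synthetic subject."""

    image_size: int = 256
    body_axes: tuple[float, float] = (100.0, 78.0)  # semi-axes, pixels (x, y)
    n_bone_structures: int = 4
    bone_hu_range: tuple[float, float] = (700.0, 1200.0)
    soft_tissue_hu_range: tuple[float, float] = (-100.0, 100.0)
    gas_cavity_probability: float = 0.3
    gas_hu: float = -1000.0
    background_hu: float = -1000.0
    texture_sigma_hu: float = 20.0

    def __post_init__(self):
        ax, ay = self.body_axes
        if 2 * ax >= self.image_size or 2 * ay >= self.image_size:
            raise InvalidSpecError("body ellipse must fit inside the image")
        if not (self.bone_hu_range[0] > self.soft_tissue_hu_range[1]
                > self.soft_tissue_hu_range[0] > self.gas_hu):
            raise InvalidSpecError("expected bone HU > soft tissue HU > gas HU")
        if not 0.0 <= self.gas_cavity_probability <= 1.0:
            raise InvalidSpecError("gas_cavity_probability must be in [0,1]")
        if self.texture_sigma_hu < 0:
            raise InvalidSpecError("texture_sigma_hu must be >= 0")


@dataclass(frozen=True)
class ArtifactModel:
    """Parameters of the CBCT degradation operator."""

    gain: float = 1.0
    offset: float = 0.0               # HU
    cupping_amplitude: float = 0.0    # HU depression at the body centre
    hardening_amplitude: float = 0.0  # HU brightening at the periphery
    hardening_power: float = 2.0
    noise_sigma: float = 0.0          # HU
    fov_radius_fraction: float = 1.0
    cavity_mismatch: bool = False
    isocenter_offset: tuple[int, int] = (0, 0)  # (dx, dy) pixels

    def __post_init__(self):
        if not 0.0 < self.fov_radius_fraction <= 1.0:
            raise InvalidSpecError("fov_radius_fraction must be in (0, 1]")
        if self.noise_sigma < 0:
            raise InvalidSpecError("noise_sigma must be >= 0")

    @property
    def is_identity(self) -> bool:
        return (self.gain == 1.0 and self.offset == 0.0
                and self.cupping_amplitude == 0.0
                and self.hardening_amplitude == 0.0
                and self.noise_sigma == 0.0
                and self.fov_radius_fraction == 1.0
                and not self.cavity_mismatch
                and self.isocenter_offset == (0, 0))


def _ellipse_mask(shape: tuple[int, int], center: tuple[float, float],
                  axes: tuple[float, float], angle: float = 0.0) -> np.ndarray:
    """Rasterize a (possibly rotated) filled ellipse; pixel-centre sampling."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    x = xx - center[1]
    y = yy - center[0]
    c, s = np.cos(angle), np.sin(angle)
    xr = c * x + s * y
    yr = -s * x + c * y
    ax, ay = axes
    return (xr / ax) ** 2 + (yr / ay) ** 2 <= 1.0


def body_mask_of(spec: PhantomSpec) -> np.ndarray:
    """Boolean body-ellipse mask of a phantom generated from ``spec``."""
    n = spec.image_size
    c = (n - 1) / 2.0
    return _ellipse_mask((n, n), (c, c), (spec.body_axes[0], spec.body_axes[1]))


def _draw_cavities(body: np.ndarray, n_cavities: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Elliptical gas cavities inside the body, jointly <= 15% of body area."""
    cav = np.zeros_like(body)
    if n_cavities == 0:
        return cav
    body_area = body.sum()
    ys, xs = np.nonzero(body)
    budget = MAX_CAVITY_AREA_FRACTION * body_area
    for _ in range(n_cavities):
        max_area = budget / n_cavities
        # semi-axes such that pi*a*b <= max_area, drawn with mild eccentricity
        a = rng.uniform(3.0, max(3.5, np.sqrt(max_area / np.pi)))
        b = np.clip(rng.uniform(0.5, 1.5) * a, 2.0, max_area / (np.pi * a))
        b = max(b, 2.0)
        i = rng.integers(len(ys))
        e = _ellipse_mask(body.shape, (float(ys[i]), float(xs[i])), (a, b),
                          rng.uniform(0, np.pi))
        cav |= e & body
    return cav


def generate_phantom(spec: PhantomSpec, seed: int) -> HUImage:
    """Deterministic pelvic-like slice: body, bones, optional gas, texture."""
    rng = np.random.default_rng(seed)
    n = spec.image_size
    img = np.full((n, n), spec.background_hu, dtype=np.float32)
    body = body_mask_of(spec)
    tissue = rng.uniform(*spec.soft_tissue_hu_range)
    img[body] = tissue

    cx = cy = (n - 1) / 2.0
    ax, ay = spec.body_axes
    for _ in range(spec.n_bone_structures):
        ba = rng.uniform(0.08, 0.22) * ax
        bb = rng.uniform(0.08, 0.22) * ay
        # keep the bone comfortably inside the body ellipse
        t = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0.0, 0.6)
        center = (cy + rad * ay * np.sin(t), cx + rad * ax * np.cos(t))
        bone = _ellipse_mask((n, n), center, (ba, bb), rng.uniform(0, np.pi))
        img[bone & body] = rng.uniform(*spec.bone_hu_range)

    if rng.random() < spec.gas_cavity_probability:
        cav = _draw_cavities(body, 1, rng)
        img[cav] = spec.gas_hu

    if spec.texture_sigma_hu > 0:
        tex = rng.normal(0.0, spec.texture_sigma_hu, size=(n, n)).astype(np.float32)
        img[body] += tex[body]

    return HUImage(np.clip(img, HU_MIN, HU_MAX))


def _mask_semi_axes(mask: np.ndarray) -> tuple[float, float]:
    """Principal semi-axes of a binary mask from its second central moments
    (exact for filled ellipses: semi-axis = 2*sqrt(eigenvalue))."""
    ys, xs = np.nonzero(mask)
    pts = np.stack([ys, xs]).astype(np.float64)
    cov = np.cov(pts)
    eig = np.linalg.eigvalsh(cov)
    eig = np.clip(eig, 0.0, None)
    return tuple(2.0 * np.sqrt(eig))  # type: ignore[return-value]


def _shift_with_fill(img: np.ndarray, dx: int, dy: int, fill: float) -> np.ndarray:
    """Integer-pixel translate by (dx, dy) = (columns, rows); vacated pixels
    take ``fill``."""
    out = np.full_like(img, fill)
    h, w = img.shape
    src_y = slice(max(0, -dy), min(h, h - dy))
    src_x = slice(max(0, -dx), min(w, w - dx))
    dst_y = slice(max(0, dy), min(h, h + dy))
    dst_x = slice(max(0, dx), min(w, w + dx))
    out[dst_y, dst_x] = img[src_y, src_x]
    return out


def apply_cbct_artifacts(ct: HUImage, body_mask: np.ndarray,
                         model: ArtifactModel, seed: int) -> HUImage:
    """Degrade a CT slice into a CBCT-like slice.

    Inside the body: ``gain*CT + offset - A*(1-(r/R)^2) + B*(r/R)^p + noise``
    with ``r`` the distance from the body centroid and ``R`` the body's
    effective radius (mean of the mask's principal semi-axes).  Outside the
    circular field of view everything is truncated to air; optionally the gas
    cavities are re-drawn with an independent sub-seed; finally the image is
    rigidly shifted by the isocenter offset and clipped.
    """
    body_mask = np.asarray(body_mask, dtype=bool)
    if ct.shape != body_mask.shape:
        raise ValueError("ct and body_mask must have the same shape")
    rng = np.random.default_rng(seed)
    img = ct.pixels.astype(np.float64).copy()
    h, w = img.shape

    if body_mask.any():
        cy, cx = ndimage.center_of_mass(body_mask)
        sa = _mask_semi_axes(body_mask)
        R = float(np.mean(sa))
        yy, xx = np.mgrid[0:h, 0:w]
        r = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
        rr = np.clip(r / max(R, 1e-9), 0.0, 1.0)
        bias = (-model.cupping_amplitude * (1.0 - rr ** 2)
                + model.hardening_amplitude * rr ** model.hardening_power)
        inside = body_mask
        vals = model.gain * img[inside] + model.offset + bias[inside]
        if model.noise_sigma > 0:
            noise = rng.normal(0.0, model.noise_sigma, size=int(inside.sum()))
            vals = vals + noise
        img[inside] = vals

        if model.cavity_mismatch:
            img = _redraw_cavities(img, ct.pixels, body_mask,
                                   np.random.default_rng(rng.integers(2 ** 31)))

    if model.fov_radius_fraction < 1.0:
        cy0, cx0 = (h - 1) / 2.0, (w - 1) / 2.0
        yy, xx = np.mgrid[0:h, 0:w]
        rimg = np.sqrt((yy - cy0) ** 2 + (xx - cx0) ** 2)
        img[rimg > model.fov_radius_fraction * (w / 2.0)] = AIR_HU

    dx, dy = model.isocenter_offset
    if (dx, dy) != (0, 0):
        img = _shift_with_fill(img, int(dx), int(dy), AIR_HU)

    return HUImage(np.clip(img, HU_MIN, HU_MAX),
                   ct.pixel_spacing, ct.slice_thickness)


def _redraw_cavities(img: np.ndarray, ct_pixels: np.ndarray,
                     body: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Fill the CT's gas cavities with soft tissue and draw the same number of
    cavities at independent positions/shapes (anatomical mismatch)."""
    gas = (ct_pixels < GAS_THRESHOLD_HU) & body
    labels, n = ndimage.label(gas)
    if n == 0:
        return img
    tissue_px = img[body & ~gas]
    fill = float(np.median(tissue_px)) if tissue_px.size else 0.0
    out = img.copy()
    out[gas] = fill
    cav = _draw_cavities(body, n, rng)
    out[cav] = -1000.0
    return out


# ---------------------------------------------------------------------------
# Dataset generation


def default_spec_ranges() -> dict:
    """Per-subject sampling intervals for phantom geometry and tissue."""
    return {
        "image_size": 256,
        "body_axes_x": (85.0, 110.0),
        "body_axes_y": (65.0, 90.0),
        "n_bone_structures": (3, 6),
        "bone_hu": (700.0, 1200.0),
        "soft_tissue_hu": (-100.0, 100.0),
        "gas_cavity_probability": (0.2, 0.5),
        "texture_sigma_hu": (10.0, 30.0),
    }


def default_model_ranges() -> dict:
    """Per-subject sampling intervals for the CBCT degradation operator.

    The magnitudes are plausible clinical scales (tens of HU of shading, a few
    percent gain error, a few-pixel isocenter shift), not published values.
    """
    return {
        "gain": (0.9, 1.1),
        "offset": (-80.0, 80.0),
        "cupping_amplitude": (20.0, 120.0),
        "hardening_amplitude": (0.0, 60.0),
        "hardening_power": (2.0, 4.0),
        "noise_sigma": (5.0, 20.0),
        "fov_radius_fraction": (0.85, 1.0),
        "cavity_mismatch_probability": 0.3,
        "isocenter_offset": (-6, 6),
    }


def identity_model_ranges() -> dict:
    """Degenerate ranges yielding the identity degradation (cbct == ct)."""
    return {
        "gain": (1.0, 1.0),
        "offset": (0.0, 0.0),
        "cupping_amplitude": (0.0, 0.0),
        "hardening_amplitude": (0.0, 0.0),
        "hardening_power": (2.0, 2.0),
        "noise_sigma": (0.0, 0.0),
        "fov_radius_fraction": (1.0, 1.0),
        "cavity_mismatch_probability": 0.0,
        "isocenter_offset": (0, 0),
    }


def _interval(ranges: dict, key: str) -> tuple[float, float]:
    v = ranges[key]
    if np.isscalar(v):
        return float(v), float(v)
    lo, hi = v
    if hi < lo:
        raise InvalidConfigError(f"empty range for {key!r}: {v}")
    return float(lo), float(hi)


def sample_spec(ranges: dict, rng: np.random.Generator) -> PhantomSpec:
    nlo, nhi = _interval(ranges, "n_bone_structures")
    return PhantomSpec(
        image_size=int(ranges.get("image_size", 256)),
        body_axes=(rng.uniform(*_interval(ranges, "body_axes_x")),
                   rng.uniform(*_interval(ranges, "body_axes_y"))),
        n_bone_structures=int(rng.integers(int(nlo), int(nhi) + 1)),
        bone_hu_range=_interval(ranges, "bone_hu"),
        soft_tissue_hu_range=_interval(ranges, "soft_tissue_hu"),
        gas_cavity_probability=rng.uniform(*_interval(ranges, "gas_cavity_probability")),
        texture_sigma_hu=rng.uniform(*_interval(ranges, "texture_sigma_hu")),
    )


def sample_model(ranges: dict, rng: np.random.Generator) -> ArtifactModel:
    olo, ohi = _interval(ranges, "isocenter_offset")
    mismatch_p = float(ranges.get("cavity_mismatch_probability", 0.0))
    return ArtifactModel(
        gain=rng.uniform(*_interval(ranges, "gain")),
        offset=rng.uniform(*_interval(ranges, "offset")),
        cupping_amplitude=rng.uniform(*_interval(ranges, "cupping_amplitude")),
        hardening_amplitude=rng.uniform(*_interval(ranges, "hardening_amplitude")),
        hardening_power=rng.uniform(*_interval(ranges, "hardening_power")),
        noise_sigma=rng.uniform(*_interval(ranges, "noise_sigma")),
        fov_radius_fraction=rng.uniform(*_interval(ranges, "fov_radius_fraction")),
        cavity_mismatch=bool(rng.random() < mismatch_p),
        isocenter_offset=(int(rng.integers(int(olo), int(ohi) + 1)),
                          int(rng.integers(int(olo), int(ohi) + 1))),
    )


def generate_dataset(n_subjects: int, slices_per_subject: int,
                     spec_ranges: dict | None = None,
                     model_ranges: dict | None = None,
                     seed: int = 0) -> list[PairedSlice]:
    """Simulate a cohort: one phantom spec and one artifact model per subject
    (intra-subject consistency), ``slices_per_subject`` independent slices.

    Sub-seeding uses ``SeedSequence(seed).spawn`` keyed by subject and slice
    index, so a given (subject, slice) is stable under dataset-size changes.
    """
    if n_subjects < 1:
        raise InvalidConfigError("n_subjects must be >= 1")
    if slices_per_subject < 1:
        raise InvalidConfigError("slices_per_subject must be >= 1")
    spec_ranges = spec_ranges or default_spec_ranges()
    model_ranges = model_ranges or default_model_ranges()

    pairs: list[PairedSlice] = []
    for si in range(n_subjects):
        subj_ss = np.random.SeedSequence(entropy=(seed, si))
        subj_rng = np.random.default_rng(subj_ss)
        spec = sample_spec(spec_ranges, subj_rng)
        model = sample_model(model_ranges, subj_rng)
        subject_id = f"subj{si:03d}"
        for zi in range(slices_per_subject):
            slice_ss = np.random.SeedSequence(entropy=(seed, si, zi))
            slice_seed = int(slice_ss.generate_state(1)[0] % (2 ** 31))
            ct = generate_phantom(spec, slice_seed)
            body = body_mask_of(spec)
            cbct = apply_cbct_artifacts(ct, body, model, slice_seed + 1)
            pairs.append(PairedSlice(ct=ct, cbct=cbct, subject_id=subject_id,
                                     isocenter_offset=model.isocenter_offset,
                                     seed=slice_seed))
    return pairs
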