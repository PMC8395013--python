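"""Body masking, alignment, normalization, resampling, augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synthct.phantom import (ArtifactModel, PhantomSpec, apply_cbct_artifacts,
                             body_mask_of, generate_phantom)
from synthct.preprocess import (DegenerateHistogramError, align_pair,
                                apply_mask, augment_pair, body_mask,
                                compute_body_mask, denormalize, normalize,
                                resample)
from synthct.types import HUImage, PairedSlice
from scipy import ndimage


def disk_image(n=64, r=20, value=0.0, background=-1000.0):
    yy, xx = np.mgrid[0:n, 0:n]
    img = np.full((n, n), background, dtype=np.float32)
    img[(yy - n // 2) ** 2 + (xx - n // 2) ** 2 <= r * r] = value
    return img


class TestBodyMask:
    def test_disk_recovered_slightly_eroded(self):
        img = HUImage(disk_image())
        m = body_mask(img).pixels
        disk = disk_image() > -500
        assert m.sum() <= disk.sum()
        assert (m & disk).sum() == m.sum()           # mask inside the disk
        assert m.sum() > 0.8 * disk.sum()            # only a thin halo removed

    def test_detached_blob_removed(self):
        img = disk_image()
        img[2:4, 2:4] = 0.0  # non-anatomical residual far from the body
        m = body_mask(HUImage(img)).pixels
        assert not m[0:6, 0:6].any()

    def test_interior_hole_filled(self):
        img = disk_image()
        img[30:34, 30:34] = -1000.0
        m = body_mask(HUImage(img)).pixels
        assert m[31:33, 31:33].all()

    def test_single_component_no_holes(self):
        spec = PhantomSpec(image_size=64, body_axes=(25, 20),
                           gas_cavity_probability=1.0)
        img = generate_phantom(spec, seed=2)
        m = body_mask(img).pixels
        _, n = ndimage.label(m)
        assert n == 1
        assert (ndimage.binary_fill_holes(m) == m).all()

    def test_constant_volume_rejected(self):
        with pytest.raises(DegenerateHistogramError):
            compute_body_mask(HUImage(np.zeros((32, 32))))

    def test_volume_wise_threshold(self):
        slices = [HUImage(disk_image(value=v)) for v in (0.0, 50.0, 100.0)]
        masks = compute_body_mask(slices)
        assert len(masks) == 3
        for m in masks:
            assert m.pixels.sum() > 0

    def test_invariant_to_structures_outside_largest_component(self):
        base = disk_image()
        m1 = body_mask(HUImage(base)).pixels
        with_extra = base.copy()
        with_extra[1:5, 50:60] = 200.0
        m2 = body_mask(HUImage(with_extra)).pixels
        np.testing.assert_array_equal(m1, m2)


class TestApplyMask:
    def test_full_mask_is_identity(self):
        img = HUImage(disk_image())
        from synthct.types import BodyMask
        m = BodyMask(np.ones((64, 64), bool))
        np.testing.assert_array_equal(apply_mask(img, m).pixels, img.pixels)

    def test_outside_set_to_air(self):
        img = HUImage(np.full((8, 8), 500.0))
        from synthct.types import BodyMask
        m = np.zeros((8, 8), bool)
        m[4, 4] = True
        out = apply_mask(img, BodyMask(m)).pixels
        assert out[4, 4] == 500.0
        assert (out[~m] == -1000.0).all()

    def test_couch_bar_removed(self):
        img = disk_image()
        img[60:63, :] = 300.0  # treatment-couch-like bar
        masked = apply_mask(HUImage(img), body_mask(HUImage(img)))
        assert (masked.pixels[60:63, :] == -1000.0).all()

    def test_shape_mismatch_rejected(self):
        from synthct.types import BodyMask
        with pytest.raises(ValueError):
            apply_mask(HUImage(np.zeros((8, 8))), BodyMask(np.ones((4, 4), bool)))


class TestAlign:
    def test_zero_offset_identity(self):
        img = HUImage(disk_image())
        pair = align_pair(img, img, (0.0, 0.0))
        np.testing.assert_array_equal(pair.cbct.pixels, img.pixels)

    def test_alignment_restores_centroid(self):
        spec = PhantomSpec(image_size=64, body_axes=(22, 18),
                           n_bone_structures=0, texture_sigma_hu=0.0,
                           gas_cavity_probability=0.0)
        ct = generate_phantom(spec, seed=1)
        body = body_mask_of(spec)
        cbct = apply_cbct_artifacts(ct, body, ArtifactModel(
            isocenter_offset=(3, 0)), seed=2)
        pair = align_pair(cbct, ct, (3.0, 0.0))
        c_ct = ndimage.center_of_mass(pair.ct.pixels > -500)
        c_cb = ndimage.center_of_mass(pair.cbct.pixels > -500)
        assert abs(c_ct[0] - c_cb[0]) <= 1.0
        assert abs(c_ct[1] - c_cb[1]) <= 1.0

    def test_full_width_offset_blanks_image(self):
        img = HUImage(disk_image())
        pair = align_pair(img, img, (64.0, 0.0))
        assert (pair.cbct.pixels == -1000.0).all()

    def test_non_finite_offset_rejected(self):
        img = HUImage(disk_image())
        with pytest.raises(ValueError):
            align_pair(img, img, (np.nan, 0.0))


class TestNormalize:
    @pytest.mark.parametrize("hu,expected", [(-1024.0, 0.0), (3200.0, 1.0),
                                             (1088.0, 0.5), (5000.0, 1.0)])
    def test_linear_map_anchor_points(self, hu, expected):
        img = HUImage(np.full((4, 4), hu))
        assert normalize(img).pixels[0, 0] == pytest.approx(expected)

    def test_round_trip_on_clip_window(self):
        rng = np.random.default_rng(0)
        img = HUImage(rng.uniform(-1024, 3200, (16, 16)).astype(np.float32))
        back = denormalize(normalize(img))
        np.testing.assert_allclose(back.pixels, img.pixels, atol=5e-4)

    def test_denormalize_range_error(self):
        with pytest.raises(ValueError):
            denormalize(np.full((4, 4), 1.5))

    @given(st.floats(min_value=-2000, max_value=5000),
           st.floats(min_value=-2000, max_value=5000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_non_decreasing(self, a, b):
        lo, hi = sorted((a, b))
        na = normalize(HUImage(np.full((2, 2), lo))).pixels[0, 0]
        nb = normalize(HUImage(np.full((2, 2), hi))).pixels[0, 0]
        assert na <= nb


class TestResample:
    def test_constant_invariance(self):
        img = HUImage(np.full((512, 512), 37.0), (1.0, 1.0))
        out = resample(img, 256)
        assert out.shape == (256, 256)
        np.testing.assert_allclose(out.pixels, 37.0)
        assert out.pixel_spacing == (2.0, 2.0)

    def test_same_size_identity(self):
        img = HUImage(disk_image())
        out = resample(img, 64)
        np.testing.assert_array_equal(out.pixels, img.pixels)


class TestAugment:
    def _pair(self):
        rng = np.random.default_rng(3)
        ct = HUImage(rng.uniform(-1000, 1000, (32, 32)).astype(np.float32))
        cbct = HUImage(rng.uniform(-1000, 1000, (32, 32)).astype(np.float32))
        return PairedSlice(ct=ct, cbct=cbct, subject_id="s")

    def test_identity_configuration(self):
        pair = self._pair()
        out = augment_pair(pair, 0, False)
        np.testing.assert_array_equal(out.ct.pixels, pair.ct.pixels)

    def test_eight_distinct_configurations(self):
        pair = self._pair()
        outs = {augment_pair(pair, k, f).ct.pixels.tobytes()
                for k in range(4) for f in (False, True)}
        assert len(outs) == 8

    def test_rotation_involution(self):
        pair = self._pair()
        out = augment_pair(augment_pair(pair, 2, False), 2, False)
        np.testing.assert_array_equal(out.ct.pixels, pair.ct.pixels)
        np.testing.assert_array_equal(out.cbct.pixels, pair.cbct.pixels)

    @given(st.integers(min_value=0, max_value=3), st.booleans())
    @settings(max_examples=8, deadline=None, derandomize=True)
    def test_marker_coherence(self, k, flip):
        """A marker pixel moves identically in both images of the pair."""
        ct = np.zeros((16, 16), np.float32)
        cbct = np.zeros((16, 16), np.float32)
        ct[3, 5] = 100.0
        cbct[3, 5] = 200.0
        pair = PairedSlice(ct=HUImage(ct), cbct=HUImage(cbct), subject_id="s")
        out = augment_pair(pair, k, flip)
        pos_ct = np.argwhere(out.ct.pixels == 100.0)
        pos_cb = np.argwhere(out.cbct.pixels == 200.0)
        np.testing.assert_array_equal(pos_ct, pos_cb)

    def test_non_square_rejected(self):
        ct = HUImage(np.zeros((8, 16)))
        pair = PairedSlice(ct=ct, cbct=HUImage(np.zeros((8, 16))), subject_id="s")
        with pytest.raises(ValueError):
            augment_pair(pair, 1, False)
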