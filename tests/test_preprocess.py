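"""ROI preprocessing chain: hull, dilation, resampling, normalisation, inputs."""

import numpy as np
import pytest
from scipy.spatial import ConvexHull

from nodenet3d.preprocess import (
    PreprocessSpec,
    clip_normalize,
    convex_hull_mask,
    dilate_mask,
    embed_in_box,
    extract_roi,
    make_small_input,
    preprocess_node,
    resample_axial,
    roi_short_axis_diameter,
)


def brute_force_hull(mask):
    """Independent oracle: half-space membership test against hull facets."""
    pts = np.argwhere(mask).astype(float)
    out = np.zeros_like(mask)
    hull = ConvexHull(pts)
    eq = hull.equations
    for idx in np.ndindex(mask.shape):
        p = np.asarray(idx, dtype=float)
        if np.all(eq[:, :-1] @ p + eq[:, -1] <= 1e-9):
            out[idx] = True
    return out


class TestConvexHull:
    def test_single_voxel_is_fixed_point(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        np.testing.assert_array_equal(convex_hull_mask(m), m)

    def test_filled_cuboid_is_fixed_point(self):
        m = np.zeros((9, 9, 9), bool)
        m[2:7, 2:7, 2:7] = True
        np.testing.assert_array_equal(convex_hull_mask(m), m)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            convex_hull_mask(np.zeros((4, 4, 4), bool))

    def test_superset_of_input(self, rng):
        m = rng.random((12, 12, 12)) < 0.05
        m[0, 0, 0] = True
        hull = convex_hull_mask(m)
        assert (hull & m).sum() == m.sum()

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_brute_force_halfspace_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = np.zeros((20, 20, 20), bool)
        idx = rng.integers(0, 20, size=(30, 3))
        m[tuple(idx.T)] = True
        np.testing.assert_array_equal(convex_hull_mask(m), brute_force_hull(m))

    def test_collinear_points_fill_segment(self):
        m = np.zeros((9, 5, 5), bool)
        m[1, 2, 2] = m[7, 2, 2] = True
        hull = convex_hull_mask(m)
        assert hull[1:8, 2, 2].all()
        assert hull.sum() == 7


class TestDilate:
    def test_zero_dilation_is_identity(self):
        m = np.zeros((6, 6, 6), bool)
        m[2:4, 2:4, 2:4] = True
        np.testing.assert_array_equal(dilate_mask(m, 0), m)

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            dilate_mask(np.ones((3, 3, 3), bool), -1)

    @pytest.mark.parametrize("px", [1, 2, 3])
    def test_ball_count_matches_lattice_enumeration(self, px):
        """Single voxel dilated by r contains exactly the integer lattice ball."""
        m = np.zeros((15, 15, 15), bool)
        m[7, 7, 7] = True
        d = dilate_mask(m, px)
        expected = sum(
            1
            for i in range(-px, px + 1)
            for j in range(-px, px + 1)
            for k in range(-px, px + 1)
            if i * i + j * j + k * k <= px * px
        )
        assert d.sum() == expected

    def test_default_ten_px_symmetric_about_seed(self):
        m = np.zeros((25, 25, 25), bool)
        m[12, 12, 12] = True
        d = dilate_mask(m, 10)
        for axis in range(3):
            np.testing.assert_array_equal(d, np.flip(d, axis=axis))

    def test_monotone_superset(self, rng):
        m = rng.random((10, 10, 10)) < 0.1
        m[5, 5, 5] = True
        d = dilate_mask(m, 2)
        assert (d & m).sum() == m.sum()


class TestResample:
    def test_noop_at_target_spacing(self, rng):
        vol = rng.normal(size=(10, 10, 4)).astype(np.float32)
        mask = np.zeros((10, 10, 4), bool)
        mask[4:7, 4:7, 1:3] = True
        v2, m2, sp = resample_axial(vol, mask, (0.75, 0.75, 3.0), 0.75)
        np.testing.assert_allclose(v2, vol, atol=1e-5)
        np.testing.assert_array_equal(m2, mask)
        assert sp == (0.75, 0.75, 3.0)

    def test_linear_ramp_stays_linear(self):
        x = np.arange(64, dtype=np.float64)
        vol = np.broadcast_to(x[:, None, None], (64, 8, 4)).copy()
        mask = np.ones((64, 8, 4), bool)
        v2, _, _ = resample_axial(vol, mask, (1.5, 1.5, 3.0), 0.75)
        # away from borders (where the spline prefilter's boundary handling
        # decays out) the bicubic interpolant of a linear ramp is linear
        inner = v2[40:-40, 4, 2].astype(np.float64)
        diffs = np.diff(inner)
        # tolerance = float32 storage ULP at the ramp's magnitude (~32)
        np.testing.assert_allclose(diffs, diffs[0], atol=1e-5)

    def test_mask_width_doubles(self):
        mask = np.zeros((30, 30, 4), bool)
        mask[10:20, 10:20, 1:3] = True  # 10 voxels wide at 1.5 mm
        vol = np.zeros_like(mask, dtype=float)
        _, m2, _ = resample_axial(vol, mask, (1.5, 1.5, 3.0), 0.75)
        widths = np.ptp(np.nonzero(m2)[0]) + 1
        assert abs(widths - 20) <= 1

    def test_bad_target_rejected(self):
        with pytest.raises(ValueError):
            resample_axial(np.zeros((4, 4, 2)), np.ones((4, 4, 2), bool), (1, 1, 1), 0.0)

    def test_nonempty_stays_nonempty(self):
        mask = np.zeros((8, 8, 2), bool)
        mask[4, 4, 1] = True
        _, m2, _ = resample_axial(np.zeros((8, 8, 2)), mask, (0.3, 0.3, 3.0), 0.75)
        assert m2.any()


class TestExtractAndNormalize:
    def test_identity_mask_keeps_volume(self, rng):
        vol = rng.normal(size=(5, 5, 3)).astype(np.float32)
        np.testing.assert_array_equal(extract_roi(vol, np.ones_like(vol, bool)), vol)

    def test_background_exactly_zero(self, rng):
        vol = rng.normal(10, 5, size=(6, 6, 3)).astype(np.float32)
        mask = np.zeros((6, 6, 3), bool)
        mask[2, 3, 1] = True
        roi = extract_roi(vol, mask)
        assert roi[2, 3, 1] == vol[2, 3, 1]
        assert (roi != 0).sum() <= 1

    def test_support_equals_mask(self, rng):
        vol = rng.normal(50, 10, size=(8, 8, 4)).astype(np.float32)  # nonzero a.s.
        mask = rng.random((8, 8, 4)) < 0.4
        roi = extract_roi(vol, mask)
        np.testing.assert_array_equal(roi != 0, mask)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            extract_roi(np.zeros((4, 4, 2)), np.ones((4, 4, 3), bool))

    def test_two_point_standardization(self):
        """{-1000, 1000} clips to {-400, 400} then standardises to {-1, +1}."""
        roi = np.zeros((2, 1, 1))
        roi[0, 0, 0], roi[1, 0, 0] = -1000.0, 1000.0
        mask = np.ones((2, 1, 1), bool)
        out, degenerate = clip_normalize(roi, mask)
        assert not degenerate
        np.testing.assert_allclose(sorted(out.ravel()), [-1.0, 1.0], atol=1e-6)

    def test_constant_roi_degenerate(self):
        roi = np.full((3, 3, 1), 55.0)
        out, degenerate = clip_normalize(roi, np.ones((3, 3, 1), bool))
        assert degenerate
        assert (out == 0).all()

    def test_unit_variance_postcondition(self, rng):
        roi = rng.normal(size=(25, 25, 16))
        mask = rng.random((25, 25, 16)) < 0.8
        out, _ = clip_normalize(roi, mask, hu_clip=(-10, 10))
        assert abs(out[mask].std() - 1.0) < 1e-6
        assert abs(out[mask].mean()) < 1e-6

    def test_idempotent(self, rng):
        roi = rng.normal(0, 100, size=(10, 10, 5))
        mask = rng.random((10, 10, 5)) < 0.6
        once, _ = clip_normalize(roi, mask)
        twice, _ = clip_normalize(once, mask)
        np.testing.assert_allclose(twice, once, atol=1e-6)


class TestBoxAndSmall:
    def test_exact_fit_unchanged(self, rng):
        roi = rng.normal(size=(8, 8, 4)).astype(np.float32)
        roi[0, 0, 0] = 5.0  # ensure corner support
        roi[-1, -1, -1] = 5.0
        np.testing.assert_array_equal(embed_in_box(roi, (8, 8, 4)), roi)

    def test_single_voxel_centering(self):
        roi = np.zeros((3, 3, 3))
        roi[1, 1, 1] = 7.0
        out = embed_in_box(roi, (118, 118, 32))
        assert out[58, 58, 15] == 7.0  # floor((118-1)/2)=58, floor((32-1)/2)=15
        assert (out != 0).sum() == 1

    def test_oversize_names_axis(self):
        roi = np.ones((119, 4, 4))
        with pytest.raises(ValueError, match="axis x"):
            embed_in_box(roi, (118, 118, 32))

    def test_centroid_within_one_voxel_of_center(self, rng):
        roi = np.zeros((30, 30, 10))
        roi[10:20, 12:22, 3:7] = 1.0
        out = embed_in_box(roi, (64, 64, 16))
        com = np.array([c.mean() for c in np.nonzero(out)])
        center = (np.array([64, 64, 16]) - 1) / 2
        assert np.all(np.abs(com - center) <= 1.0)

    def test_small_input_noop_at_native_size(self, rng):
        roi = rng.normal(size=(32, 32, 32))
        roi[0, :, :] = roi[-1, :, :] = 1.0  # full tight extent
        roi[:, 0, :] = roi[:, -1, :] = 1.0
        roi[:, :, 0] = roi[:, :, -1] = 1.0
        out = make_small_input(roi, (32, 32, 32))
        np.testing.assert_allclose(out, roi, atol=1e-4)

    def test_step_edge_maps_to_half(self):
        roi = np.zeros((64, 32, 32))
        roi[:32] = 1.0
        roi[32:] = 2.0
        out = make_small_input(roi, (32, 32, 32))
        mid = out[:, 16, 16]
        # the step at x=32/64 should sit near x=16/32
        crossing = np.argmax(mid > 1.5)
        assert abs(crossing - 16) <= 1

    def test_size_invariance(self):
        """Two balls differing only by scale give matching small inputs."""

        def ball_roi(n, r):
            g = np.meshgrid(*[np.arange(n) - (n - 1) / 2] * 3, indexing="ij")
            rho = np.sqrt(sum(x**2 for x in g)) / r
            return np.clip(1.0 - rho, 0, None)

        a = make_small_input(ball_roi(21, 10), (32, 32, 32))
        b = make_small_input(ball_roi(41, 20), (32, 32, 32))
        assert np.abs(a - b).mean() < 0.02


class TestDiameter:
    def test_single_voxel(self):
        m = np.zeros((4, 4, 4), bool)
        m[1, 2, 3] = True
        assert roi_short_axis_diameter(m, (0.75, 0.75, 3.0)) == pytest.approx(0.75)

    def test_cuboid_short_axis(self):
        m = np.zeros((30, 30, 8), bool)
        m[0:20, 0:10, 0:5] = True
        assert roi_short_axis_diameter(m, (0.75, 0.75, 3.0)) == pytest.approx(7.5)

    def test_digital_ellipsoid(self):
        g = np.meshgrid(*[np.arange(25) - 12] * 3, indexing="ij")
        m = (g[0] / 10) ** 2 + (g[1] / 6) ** 2 + (g[2] / 4) ** 2 <= 1
        d = roi_short_axis_diameter(m, (1.0, 1.0, 1.0))
        assert 8.0 <= d <= 9.5  # 2 x 4-voxel semi-axis up to discretisation


class TestFullChain:
    def test_sphere_diameter_includes_dilation(self, sphere_volume):
        """12 mm node + 10 px dilation at 0.75 mm -> ~27 mm ROI diameter."""
        sample = preprocess_node(
            sphere_volume, sphere_volume.nodes[0], spec=PreprocessSpec(box_shape=(118, 118, 32))
        )
        assert sample.roi_diameter_mm == pytest.approx(27.0, abs=2.0)
        assert sample.target == (1, 0)
        assert sample.box_input.shape == (118, 118, 32)
        assert sample.small_input.shape == (32, 32, 32)

    def test_label_maps_to_target(self, sphere_volume):
        sphere_volume.nodes[0].label = "nm_ene"
        sample = preprocess_node(sphere_volume, sphere_volume.nodes[0])
        assert sample.target == (1, 1)

    def test_translation_invariance(self, rng):
        """The same node translated in the volume yields the same box input."""
        from nodenet3d.io import AnnotatedVolume, NodeSegmentation

        shape = (40, 40, 12)
        base = rng.normal(0, 30, size=shape).astype(np.float32)

        def build(offset):
            vox = np.full(shape, -100.0, dtype=np.float32)
            mask = np.zeros(shape, bool)
            sl = tuple(slice(10 + o, 18 + o) for o in (offset, offset, 0))
            sl = (slice(10 + offset, 18 + offset), slice(10 + offset, 18 + offset), slice(4, 8))
            vox[sl] = 60.0 + base[sl]
            mask[sl] = True
            vol = AnnotatedVolume(vox, (0.75, 0.75, 3.0), "p", nodes=[
                NodeSegmentation(mask, "negative", "n")
            ])
            return preprocess_node(vol, vol.nodes[0], spec=PreprocessSpec(dilation_px=2, box_shape=(48, 48, 16)))

        a, b = build(0), build(4)
        # supports agree after centering; intensities differ (different texture draw
        # locations), so compare supports and in-support means
        assert (a.box_input != 0).sum() == pytest.approx((b.box_input != 0).sum(), rel=0.05)
        com_a = [c.mean() for c in np.nonzero(a.box_input)]
        com_b = [c.mean() for c in np.nonzero(b.box_input)]
        np.testing.assert_allclose(com_a, com_b, atol=1.0)

    def test_mask_monotonicity(self, random_volume):
        seg = random_volume.nodes[0]
        hull = convex_hull_mask(seg.mask)
        dilated = dilate_mask(hull, 3)
        assert (hull & seg.mask).sum() == seg.mask.sum()
        assert (dilated & hull).sum() == hull.sum()

    def test_stage_error_carries_stage_name(self, random_volume):
        bad_spec = PreprocessSpec(box_shape=(2, 2, 2), small_shape=(4, 4, 4))
        with pytest.raises(ValueError, match="embed_in_box"):
            preprocess_node(random_volume, random_volume.nodes[0], spec=bad_spec)
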