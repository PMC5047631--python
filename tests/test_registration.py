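"""Point-pair, intensity-based and CPD registration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npreflect.registration import (
    PlanarTransform,
    PointSet,
    cpd_register,
    equalize_pixel_size,
    estimate_from_points,
    landmark_error,
    max_projection,
    min_projection,
    register_intensity,
)


def rigid(angle_deg, ty, tx):
    return PlanarTransform.rigid_about(np.deg2rad(angle_deg), (ty, tx))


class TestPlanarTransform:
    def test_rigid_rejects_reflection(self):
        with pytest.raises(ValueError, match="reflection"):
            PlanarTransform("rigid", np.array([[1.0, 0], [0, -1.0]]), np.zeros(2))

    def test_affine_must_be_invertible(self):
        with pytest.raises(ValueError, match="invertible"):
            PlanarTransform("affine", np.zeros((2, 2)), np.zeros(2))

    @given(
        st.floats(-np.pi, np.pi),
        st.floats(-5000, 5000),
        st.floats(-5000, 5000),
    )
    @settings(max_examples=50, deadline=None)
    def test_inverse_roundtrip_within_1e9_nm(self, angle, ty, tx):
        t = PlanarTransform.rigid_about(angle, (ty, tx), centre_nm=(500.0, -300.0))
        pts = np.array([[0.0, 0.0], [1234.5, -678.9], [5000.0, 5000.0]])
        back = t.invert().apply(t.apply(pts))
        assert np.abs(back - pts).max() < 1e-9 * max(1.0, np.abs(pts).max())

    def test_composition_applies_right_to_left(self):
        a = rigid(90.0, 0.0, 0.0)
        b = rigid(0.0, 100.0, 0.0)
        p = np.array([10.0, 0.0])
        np.testing.assert_allclose(
            a.compose(b).apply(p), a.apply(b.apply(p)), atol=1e-9
        )

    def test_json_roundtrip(self):
        t = rigid(12.0, 40.0, -25.0)
        t2 = PlanarTransform.from_dict(t.to_dict())
        np.testing.assert_allclose(t2.matrix, t.matrix)
        np.testing.assert_allclose(t2.translation, t.translation)


class TestEstimateFromPoints:
    def test_identity_for_equal_sets(self, rng):
        pts = rng.uniform(0, 1e4, (5, 2))
        t = estimate_from_points(pts, pts, "rigid")
        np.testing.assert_allclose(t.matrix, np.eye(2), atol=1e-12)
        np.testing.assert_allclose(t.translation, 0.0, atol=1e-8)

    def test_rigid_recovers_constructed_rotation(self, rng):
        moving = rng.uniform(0, 1e4, (6, 2))
        truth = rigid(30.0, 100.0, -50.0)
        t = estimate_from_points(truth.apply(moving), moving, "rigid")
        assert np.rad2deg(t.rotation_angle) == pytest.approx(30.0, abs=1e-6)
        np.testing.assert_allclose(t.translation, truth.translation, atol=1e-6)
        assert landmark_error(t, truth.apply(moving), moving) < 1e-6

    def test_affine_recovers_anisotropic_shrinkage(self):
        # TEM-like shrinkage: 0.9 / 0.8 scale factors, exact on 4 pairs
        moving = np.array([[0.0, 0.0], [1000.0, 0.0], [0.0, 1000.0],
                           [700.0, 300.0]])
        truth = PlanarTransform(
            "affine", np.diag([0.9, 0.8]), np.array([50.0, -20.0])
        )
        t = estimate_from_points(truth.apply(moving), moving, "affine")
        np.testing.assert_allclose(t.matrix, truth.matrix, atol=1e-9)
        np.testing.assert_allclose(t.translation, truth.translation, atol=1e-6)

    def test_collinear_points_rejected_for_affine(self):
        moving = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]) * 100
        with pytest.raises(ValueError, match="collinear"):
            estimate_from_points(moving + 5.0, moving, "affine")

    def test_minimum_pair_counts_enforced(self):
        with pytest.raises(ValueError, match="at least"):
            estimate_from_points([[0.0, 0.0]], [[1.0, 1.0]], "rigid")


class TestRegisterIntensity:
    def _blob_image(self, rng, n=6, size=96):
        img = np.zeros((size, size))
        yy, xx = np.mgrid[:size, :size]
        for _ in range(n):
            cy, cx = rng.uniform(25, size - 25, 2)
            amp = rng.uniform(300, 1000)
            img += amp * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * 2.5**2)))
        return img

    def test_pure_shift_recovered_within_half_pixel(self, rng):
        fixed = self._blob_image(rng)
        moving = np.roll(fixed, (-5, -3), axis=(0, 1))
        res = register_intensity(
            fixed, moving, pixel_size_nm=60.0, cross_modality=False,
            preprocess=False, max_angle_deg=2.0,
        )
        np.testing.assert_allclose(
            res.transform.translation, [5 * 60.0, 3 * 60.0], atol=30.0
        )

    def test_preprocessing_improves_metric_on_offset_backgrounds(self, rng):
        fixed = self._blob_image(rng) + 200.0
        moving = np.roll(fixed, (-4, -2), axis=(0, 1)) + 300.0  # extra offset
        kwargs = dict(pixel_size_nm=60.0, cross_modality=True,
                      max_angle_deg=2.0)
        with_pre = register_intensity(fixed, moving, preprocess=True, **kwargs)
        without = register_intensity(fixed, moving, preprocess=False, **kwargs)
        assert with_pre.metric_value > without.metric_value

    def test_cross_modality_misalignment_recovered(self):
        from npreflect.experiments import registration_recovery

        df = registration_recovery(3, seed=4)
        assert df.landmark_error_px.mean() <= 1.0


class TestCPD:
    def test_identical_sets_converge_to_identity(self, rng):
        pts = rng.uniform(0, 1e4, (15, 2))
        res = cpd_register(pts, pts, "rigid", w=0.1)
        np.testing.assert_allclose(res.transform.matrix, np.eye(2), atol=1e-6)
        assert res.sigma2 < 1e-6
        assert res.converged

    def test_rotation_recovered_from_shuffled_points(self, rng):
        moving = rng.uniform(0, 1e4, (20, 2))
        truth = rigid(20.0, 300.0, -200.0)
        fixed = truth.apply(moving)
        res = cpd_register(fixed, moving[rng.permutation(20)], "rigid", w=0.1)
        assert np.rad2deg(res.transform.rotation_angle) == pytest.approx(
            20.0, abs=0.5
        )

    def test_w0_clean_sets_match_procrustes_oracle(self, rng):
        moving = rng.uniform(0, 1e4, (12, 2))
        truth = rigid(17.0, 150.0, 250.0)
        fixed = truth.apply(moving)
        oracle = estimate_from_points(fixed, moving, "rigid")
        res = cpd_register(fixed, moving[rng.permutation(12)], "rigid", w=0.0)
        rel = abs(res.transform.rotation_angle - oracle.rotation_angle) / abs(
            oracle.rotation_angle
        )
        assert rel <= 1e-3

    def test_outliers_tolerated_with_nonzero_w(self, rng):
        moving = rng.uniform(0, 1e4, (20, 2))
        truth = rigid(10.0, 100.0, -100.0)
        fixed = truth.apply(moving)
        clean = cpd_register(fixed, moving, "rigid", w=0.1)
        clean_err = landmark_error(clean.transform, fixed, moving)
        spurious = np.vstack([moving, rng.uniform(0, 1e4, (4, 2))])  # +20%
        res = cpd_register(fixed, spurious, "rigid", w=0.3)
        err = landmark_error(res.transform, fixed, moving)
        assert err <= 2.0 * max(clean_err, 1.0)

    def test_affine_model_recovers_shrinkage(self, rng):
        moving = rng.uniform(0, 1e4, (25, 2))
        truth = PlanarTransform("affine", np.diag([0.9, 0.8]),
                                np.array([100.0, 50.0]))
        res = cpd_register(truth.apply(moving), moving, "affine", w=0.0)
        np.testing.assert_allclose(res.transform.matrix, truth.matrix, atol=1e-3)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            cpd_register(np.zeros((0, 2)), np.ones((3, 2)))

    def test_point_set_source_tag(self):
        ps = PointSet([[0.0, 0.0], [1.0, 1.0]], source="nuclear_centroids")
        assert len(ps) == 2 and ps.source == "nuclear_centroids"


class TestResamplingAndProjections:
    def test_equal_pitches_unchanged(self, rng):
        a = rng.random((10, 10))
        out_a, out_b, pitch = equalize_pixel_size(a, 60.0, a.copy(), 60.0)
        assert pitch == 60.0
        np.testing.assert_array_equal(out_a, a)

    def test_constant_image_resampled_to_constant(self):
        a = np.full((8, 8), 3.0)
        b = np.full((16, 16), 5.0)
        out_a, out_b, pitch = equalize_pixel_size(a, 120.0, b, 60.0)
        assert pitch == 60.0
        assert out_a.shape == (16, 16)
        np.testing.assert_allclose(out_a, 3.0)

    def test_linear_ramp_recovered_after_equalisation(self):
        fine = np.tile(np.arange(32, dtype=float), (32, 1))
        coarse = fine[::2, ::2]
        out_c, out_f, pitch = equalize_pixel_size(coarse, 120.0, fine, 60.0)
        assert out_c.shape == out_f.shape
        interior = out_c[8:-8, 8:-8] / 2.0  # coarse ramp has half the slope
        np.testing.assert_allclose(interior, out_f[8:-8, 8:-8] / 2.0, atol=0.6)

    def test_min_projection_keeps_dark_spots(self):
        a = np.full((8, 8), 200.0)
        b = a.copy()
        b[4, 4] = 30.0
        out = min_projection([a, b])
        assert out[4, 4] == 30.0
        np.testing.assert_array_equal(min_projection([a]), a)

    def test_max_projection_keeps_bright_spots(self):
        stack = np.zeros((3, 5, 5))
        stack[1, 2, 2] = 7.0
        assert max_projection(stack)[2, 2] == 7.0

    def test_empty_section_list_rejected(self):
        with pytest.raises(ValueError):
            min_projection([])
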