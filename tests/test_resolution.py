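"""Line profiles and FWHM estimation against closed-form oracles."""

import numpy as np
import pytest

from npreflect.image import VolumeImage
from npreflect.psf import FWHM_PER_SIGMA
from npreflect.resolution import (
    FWHMEstimate,
    LineProfile,
    fwhm_from_profile,
    line_profile,
    measure_regions,
    split_at_interior_minimum,
    summarize_fwhm,
)

VOXEL = (200.0, 60.0, 60.0)


def gaussian_volume(sigma_nm=(400.0, 120.0, 120.0), centre_vox=(6, 48, 48),
                    shape=(12, 96, 96), amplitude=1000.0):
    z, y, x = np.ogrid[: shape[0], : shape[1], : shape[2]]
    coords = [
        (z - centre_vox[0]) * VOXEL[0],
        (y - centre_vox[1]) * VOXEL[1],
        (x - centre_vox[2]) * VOXEL[2],
    ]
    data = amplitude * np.exp(
        -sum((c / s) ** 2 for c, s in zip(coords, sigma_nm)) / 2.0
    )
    return VolumeImage(data, VOXEL)


class TestLineProfile:
    def test_on_grid_row_returned_exactly(self, rng):
        data = rng.random((6, 10, 10)) * 100
        img = VolumeImage(data, VOXEL)
        centre = (3 * 200.0, 4 * 60.0, 5 * 60.0)
        prof = line_profile(img, centre, "x", 240.0)
        np.testing.assert_array_equal(prof.intensities, data[3, 4, 1:10])

    def test_constant_image_gives_constant_profile(self):
        img = VolumeImage(np.full((6, 12, 12), 5.0), VOXEL)
        prof = line_profile(img, (600.0, 360.0, 360.0), "y", 300.0)
        np.testing.assert_allclose(prof.intensities, 5.0)

    def test_matches_closed_form_gaussian(self):
        img = gaussian_volume()
        prof = line_profile(img, (1200.0, 2880.0, 2880.0), "x", 600.0)
        expected = 1000.0 * np.exp(
            -((prof.positions_nm - 2880.0) / 120.0) ** 2 / 2.0
        )
        np.testing.assert_allclose(prof.intensities, expected, rtol=1e-9)

    def test_out_of_bounds_rejected(self):
        img = gaussian_volume()
        with pytest.raises(ValueError, match="bounds"):
            line_profile(img, (1200.0, 2880.0, 60.0), "x", 600.0)


class TestFwhmFromProfile:
    def test_sampled_gaussian_matches_closed_form(self):
        # FWHM = 2*sqrt(2 ln 2) * sigma = 235.5 nm for sigma = 100 nm
        x = np.arange(-10, 11) * 60.0
        prof = LineProfile(x, np.exp(-(x / 100.0) ** 2 / 2.0), "x")
        est = fwhm_from_profile(prof, baseline="zero")
        assert est.fwhm_nm == pytest.approx(100.0 * FWHM_PER_SIGMA, abs=30.0)

    @pytest.mark.parametrize("sigma_nm", [50.0, 100.0, 200.0, 350.0, 500.0])
    def test_oracle_agreement_across_widths(self, sigma_nm):
        x = np.arange(-40, 41) * 60.0
        prof = LineProfile(x, np.exp(-(x / sigma_nm) ** 2 / 2.0), "x")
        est = fwhm_from_profile(prof, baseline="zero")
        assert abs(est.fwhm_nm - FWHM_PER_SIGMA * sigma_nm) <= 30.0

    def test_triangle_peak_halfwidth(self):
        # triangle of half-width-at-half-height w: FWHM = w (=480 nm)
        x = np.arange(-8, 9) * 120.0
        v = np.clip(1.0 - np.abs(x) / 960.0, 0.0, None)
        est = fwhm_from_profile(LineProfile(x, v, "x"), baseline="zero")
        assert est.fwhm_nm == pytest.approx(960.0)

    def test_two_peak_profile_split_at_interior_minimum(self):
        # two sigma=49 nm Gaussians 400 nm apart: the high-res line scan
        # shows two peaks where the low-res one shows a single envelope
        x = np.arange(-12, 13) * 60.0
        v = np.exp(-((x + 200) / 49.0) ** 2 / 2) + np.exp(
            -((x - 200) / 49.0) ** 2 / 2
        )
        halves = split_at_interior_minimum(LineProfile(x, v, "x"))
        assert len(halves) == 2
        ests = [fwhm_from_profile(h, baseline="zero") for h in halves]
        assert ests[0].peak_position_nm == pytest.approx(-200.0, abs=30.0)
        assert ests[1].peak_position_nm == pytest.approx(200.0, abs=30.0)
        for e in ests:
            assert e.fwhm_nm == pytest.approx(49.0 * FWHM_PER_SIGMA, rel=0.3)

    def test_boundary_peak_error_names_side(self):
        x = np.arange(0, 6) * 60.0
        with pytest.raises(ValueError, match="left"):
            fwhm_from_profile(LineProfile(x, np.array([5.0, 4, 3, 2, 1, 0]), "x"))

    def test_missing_crossing_reported(self):
        x = np.arange(-3, 4) * 60.0
        v = np.array([0.9, 0.95, 0.99, 1.0, 0.99, 0.95, 0.9])
        with pytest.raises(ValueError, match="crossing"):
            fwhm_from_profile(LineProfile(x, v, "x"), baseline="zero")

    def test_scale_and_translation_equivariance(self):
        x = np.arange(-10, 11) * 60.0
        v = np.exp(-(x / 150.0) ** 2 / 2.0)
        base = fwhm_from_profile(LineProfile(x, v, "x"), baseline="zero")
        scaled = fwhm_from_profile(LineProfile(x, 7.3 * v, "x"), baseline="zero")
        assert scaled.fwhm_nm == pytest.approx(base.fwhm_nm)
        shifted = fwhm_from_profile(LineProfile(x + 500.0, v, "x"), baseline="zero")
        assert shifted.fwhm_nm == pytest.approx(base.fwhm_nm)
        assert shifted.peak_position_nm == pytest.approx(
            base.peak_position_nm + 500.0
        )


class TestMeasureRegions:
    def _regions_for(self, image, threshold=100.0):
        from npreflect.quantify import connected_components

        return connected_components(
            image.data > threshold, voxel_size_nm=VOXEL, intensity=image
        )

    def test_empty_region_table_gives_empty_list(self):
        import pandas as pd

        img = gaussian_volume()
        assert measure_regions(img, pd.DataFrame(columns=["label"])) == []

    def test_lateral_estimate_averages_x_and_y(self):
        img = gaussian_volume(sigma_nm=(400.0, 100.0, 160.0))
        regions = self._regions_for(img)
        ests = measure_regions(img, regions, axes=("x", "y"),
                               half_length_nm=700.0)
        assert len(ests) == 1 and ests[0].axis == "lateral"
        expected = FWHM_PER_SIGMA * (100.0 + 160.0) / 2.0
        assert ests[0].fwhm_nm == pytest.approx(expected, rel=0.06)

    def test_noiseless_fwhm_monotone_in_preset(self):
        from npreflect.psf import PSFPreset
        from npreflect.simulate import (
            Cluster, NoiseParams, SceneParams, generate_ground_truth,
            render_scene,
        )

        params = SceneParams(shape=(12, 96, 96), n_clusters=0,
                             control_flag=True, background_fraction=0.0)
        measured = []
        for fwhm in (150.0, 250.0, 400.0):
            truth = generate_ground_truth(params, seed=1)
            truth.np_clusters = [Cluster((1200.0, 2880.0, 2880.0), 1000.0, 1.0)]
            truth.control_flag = False
            preset = PSFPreset("RCM", fwhm_lateral=fwhm, fwhm_axial=3 * fwhm)
            refl = render_scene(truth, preset,
                                NoiseParams(0.0, 0.0, 0))["reflectance"]
            regions = self._regions_for(refl)
            est = measure_regions(refl, regions, axes=("x",),
                                  half_length_nm=3 * fwhm)[0]
            measured.append(est.fwhm_nm)
        assert measured == sorted(measured)
        assert measured[0] < measured[2] * 0.5


class TestSummarizeFwhm:
    def test_degenerate_spread(self):
        s = summarize_fwhm([100.0, 100.0, 100.0])
        assert s["mean_nm"] == 100.0 and s["sd_nm"] == 0.0 and s["n"] == 3

    def test_hand_computed_mean_and_sd(self):
        s = summarize_fwhm([300.0, 400.0])
        assert s["mean_nm"] == pytest.approx(350.0)
        assert s["sd_nm"] == pytest.approx(70.71, abs=0.01)
        assert s["density_fit"]["mu"] == pytest.approx(350.0)

    def test_accepts_estimate_objects(self):
        ests = [
            FWHMEstimate(f, 0.0, 1.0, "lateral") for f in (330.0, 350.0, 370.0)
        ]
        assert summarize_fwhm(ests)["mean_nm"] == pytest.approx(350.0)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            summarize_fwhm([300.0])
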