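"""Synthetic-data generators: determinism, point statistics, rendering laws."""

import dataclasses

import numpy as np
import pytest

from astrotopo import (
    FluorescenceImage,
    NetworkPointSet,
    RoiPolygon,
    SyntheticNetworkSpec,
    generate_immuno_field,
    generate_network_points,
    render_network_image,
    render_spots,
)
from astrotopo.intensity import mean_grey_value, polygon_pixel_mask


def square_roi(side=100.0, offset=(0.0, 0.0), label="LSO"):
    x0, y0 = offset
    return RoiPolygon(
        [[x0, y0], [x0 + side, y0], [x0 + side, y0 + side], [x0, y0 + side]], label
    )


class TestNetworkPoints:
    def test_patched_cell_at_origin(self, wt_points):
        np.testing.assert_array_equal(wt_points.patched, [0.0, 0.0])
        assert wt_points.n_coupled == 63

    def test_seed_determinism(self, wt_spec):
        a = generate_network_points(wt_spec)
        b = generate_network_points(wt_spec)
        np.testing.assert_array_equal(a.cells, b.cells)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            generate_network_points(SyntheticNetworkSpec(n_cells=0))
        with pytest.raises(ValueError):
            generate_network_points(
                SyntheticNetworkSpec(sigma_major=10.0, sigma_minor=20.0)
            )
        with pytest.raises(ValueError):
            generate_network_points(SyntheticNetworkSpec(decay_length=0.0))

    def test_equal_sigmas_give_isotropic_covariance(self):
        spec = SyntheticNetworkSpec(
            n_cells=10_000, sigma_major=60.0, sigma_minor=60.0, alpha_true=0.0,
            min_spacing=0.0, seed=1,
        )
        pts = generate_network_points(spec)
        cov = np.cov(pts.cells.T)
        assert cov[0, 0] == pytest.approx(3600.0, rel=0.1)
        assert cov[1, 1] == pytest.approx(3600.0, rel=0.1)

    @pytest.mark.parametrize("alpha_true", [0.0, 30.0, 90.0, 150.0])
    def test_principal_axis_recovers_alpha_true(self, alpha_true):
        spec = SyntheticNetworkSpec(
            n_cells=10_000, sigma_major=80.0, sigma_minor=40.0,
            alpha_true=alpha_true, min_spacing=0.0, seed=2,
        )
        pts = generate_network_points(spec)
        cov = np.cov(pts.cells.T)
        w, v = np.linalg.eigh(cov)
        major = v[:, np.argmax(w)]
        est = np.rad2deg(np.arctan2(major[1], major[0])) % 180.0
        d = abs(est - alpha_true)
        assert min(d, 180.0 - d) <= 5.0

    def test_hard_core_spacing_is_honoured(self, wt_points):
        pts = wt_points.all_points()
        d = np.hypot(*(pts[:, None, :] - pts[None, :, :]).T)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 10.0


class TestNetworkImage:
    def test_single_cell_peak_is_closed_form(self):
        spec = SyntheticNetworkSpec(n_cells=1, noise_sd=0.0, seed=0)
        pts = NetworkPointSet([0.0, 0.0], [[0.0, 0.0001]])
        img = render_network_image(pts, spec)
        # central pixel: both spots at r ~ 0 overlap -> ~2x peak + background
        rc = img.um_to_pixel([[0.0, 0.0]]).astype(int)[0]
        val = img.intensities[rc[0], rc[1]]
        assert val == pytest.approx(
            2 * spec.peak_intensity + spec.background_level, rel=0.01
        )

    def test_peak_decays_by_e_at_decay_length(self):
        spec = SyntheticNetworkSpec(n_cells=1, noise_sd=0.0, decay_length=200.0, seed=0)
        pts = NetworkPointSet([0.0, 0.0], [[200.0, 0.0]])
        img = render_network_image(pts, spec)
        rc = img.um_to_pixel([[200.0, 0.0]]).astype(int)[0]
        peak_above_bg = img.intensities[rc[0], rc[1]] - spec.background_level
        assert peak_above_bg == pytest.approx(spec.peak_intensity / np.e, rel=0.02)

    def test_same_seed_bit_identical(self, wt_points):
        spec = SyntheticNetworkSpec(noise_sd=5.0, seed=9)
        a = render_network_image(wt_points, spec)
        b = render_network_image(wt_points, spec)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_marginals_track_point_histogram(self, wt_spec, wt_points):
        spec = dataclasses.replace(wt_spec, noise_sd=0.0)
        img = render_network_image(wt_points, spec)
        colsum = (img.intensities - spec.background_level).sum(axis=0)
        x_px = ((wt_points.all_points()[:, 0] - img.origin[0]) / img.pixel_size)
        hist, _ = np.histogram(x_px, bins=np.arange(img.shape[1] + 1) - 0.5)
        # compare smoothed marginal of the point pattern with the image marginal
        from scipy.ndimage import gaussian_filter1d

        expected = gaussian_filter1d(hist.astype(float), spec.spot_sigma / spec.pixel_size)
        corr = np.corrcoef(colsum, expected)[0, 1]
        assert corr > 0.9

    def test_nonpositive_pixel_size_rejected(self, wt_points):
        spec = SyntheticNetworkSpec(pixel_size=0.0)
        with pytest.raises(ValueError):
            render_network_image(wt_points, spec)


class TestImmunoField:
    def test_equal_densities_give_equal_means(self):
        roi = square_roi(80.0, offset=(10.0, 10.0))
        img = generate_immuno_field(roi, 4000.0, 4000.0, noise_sd=0.0, seed=3)
        inside = mean_grey_value(img, roi)
        mask_out = ~polygon_pixel_mask(img, roi)
        outside = float(img.intensities[mask_out].mean())
        assert inside == pytest.approx(outside, rel=0.25)

    def test_zero_densities_give_pure_background(self):
        roi = square_roi(50.0)
        img = generate_immuno_field(
            roi, 0.0, 0.0, noise_sd=0.0, background_level=40.0, seed=1
        )
        assert np.all(img.intensities == 40.0)

    def test_contrast_survives_background_correction(self):
        roi = square_roi(80.0)
        img = generate_immuno_field(roi, 20_000.0, 500.0, seed=5)
        inside = mean_grey_value(img, roi)
        mask_out = ~polygon_pixel_mask(img, roi)
        outside = float(img.intensities[mask_out].mean())
        assert inside - outside > 0.0

    def test_seed_determinism(self):
        roi = square_roi(60.0)
        a = generate_immuno_field(roi, 5000.0, 1000.0, seed=7)
        b = generate_immuno_field(roi, 5000.0, 1000.0, seed=7)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            generate_immuno_field(square_roi(50.0), -1.0, 0.0, seed=0)


class TestRenderSpots:
    def test_flat_background_without_spots_noise(self):
        img = render_spots(
            np.array([[0.0, 0.0]]), np.array([0.0]),
            pixel_size=1.0, spot_sigma=2.0, background=7.0,
        )
        assert isinstance(img, FluorescenceImage)
        assert np.all(img.intensities == 7.0)

    def test_rejects_bad_pixel_size(self):
        with pytest.raises(ValueError):
            render_spots(
                np.array([[0.0, 0.0]]), np.array([1.0]),
                pixel_size=-1.0, spot_sigma=2.0, background=0.0,
            )
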