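"""Anisotropy ratio, rotation scan, sinusoid fit, classification, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from astrotopo import (
    CLASS_ISOTROPIC,
    CLASS_ORTHOGONAL,
    CLASS_PARALLEL,
    NetworkPointSet,
    RotationScan,
    SinusoidFitResult,
    SyntheticNetworkSpec,
    classify_network,
    fit_sinusoid,
    generate_network_points,
    network_metrics,
    rotation_scan,
    sector_ratio,
)

from conftest import random_point_set
from oracles import brute_force_sector_ratio


class TestSectorRatio:
    def test_fourfold_symmetric_pattern_is_isotropic(self):
        pts = NetworkPointSet([0, 0], [[0, 10], [0, -10], [10, 0], [-10, 0]])
        r, decomp = sector_ratio(pts, 0.0)
        assert r == pytest.approx(1.0)
        assert decomp.total_count == 4

    def test_hand_computed_ratio(self):
        # numerator: |(0,3)|/2 + |(0,-1)|/1 = 2.5; denominator: 1/1 + 2/1 = 3
        pts = NetworkPointSet([0, 0], [[0, 1], [0, 2], [0, -1], [1, 0], [-2, 0]])
        r, _ = sector_ratio(pts, 0.0)
        assert r == pytest.approx(2.5 / 3.0, abs=1e-12)

    def test_counts_partition_the_cells(self, wt_points):
        _, decomp = sector_ratio(wt_points, 37.0)
        assert decomp.total_count == wt_points.n_coupled

    def test_undefined_when_denominator_empty(self):
        # all cells exactly on the +y axis: x sectors stay empty
        pts = NetworkPointSet([0, 0], [[0, 1], [0, 2], [0, 3]])
        r, _ = sector_ratio(pts, 0.0)
        assert np.isnan(r)

    @pytest.mark.parametrize("theta", [0.0, 15.0, 52.5, 200.0])
    def test_half_turn_symmetry(self, theta):
        rng = np.random.default_rng(7)
        for _ in range(20):
            pts = random_point_set(rng)
            r1, _ = sector_ratio(pts, theta)
            r2, _ = sector_ratio(pts, theta + 180.0)
            assert r1 == pytest.approx(r2, abs=1e-9)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            pts = random_point_set(rng)
            theta = float(rng.uniform(0, 360))
            r_lib, _ = sector_ratio(pts, theta)
            r_ref = brute_force_sector_ratio(pts.patched, pts.cells, theta)
            if np.isnan(r_ref):
                assert np.isnan(r_lib)
            else:
                assert r_lib == pytest.approx(r_ref, abs=1e-9)

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        pts = random_point_set(rng, n=25)
        shifted = pts.translated([123.4, -56.7])
        for theta in (0.0, 30.0, 75.0):
            assert sector_ratio(pts, theta)[0] == pytest.approx(
                sector_ratio(shifted, theta)[0], abs=1e-9
            )

    def test_scale_invariance(self):
        rng = np.random.default_rng(6)
        pts = random_point_set(rng, n=25)
        scaled = NetworkPointSet(pts.patched * 3.7, pts.cells * 3.7)
        for theta in (0.0, 45.0, 110.0):
            assert sector_ratio(pts, theta)[0] == pytest.approx(
                sector_ratio(scaled, theta)[0], abs=1e-9
            )


class TestRotationScan:
    def test_default_step_gives_24_angles(self, wt_points):
        scan = rotation_scan(wt_points)
        assert len(scan.angles_deg) == 24
        assert scan.angles_deg[1] - scan.angles_deg[0] == 15.0

    def test_step_must_divide_360(self, wt_points):
        with pytest.raises(ValueError):
            rotation_scan(wt_points, step_deg=17.0)

    def test_isotropic_large_n_ratios_near_unity(self):
        spec = SyntheticNetworkSpec(
            n_cells=10_000, sigma_major=600, sigma_minor=600, alpha_true=0,
            min_spacing=0.0, seed=11,
        )
        scan = rotation_scan(generate_network_points(spec))
        assert np.all(scan.ratios >= 0.8) and np.all(scan.ratios <= 1.25)

    def test_elongated_along_y_peaks_at_zero_rotation(self):
        spec = SyntheticNetworkSpec(
            n_cells=1000, sigma_major=100, sigma_minor=50, alpha_true=90,
            min_spacing=0.0, seed=3,
        )
        scan = rotation_scan(generate_network_points(spec))
        peak_angle = scan.angles_deg[np.nanargmax(scan.ratios)]
        assert peak_angle in (0.0, 180.0)


class TestSinusoidFit:
    def test_noiseless_self_consistency(self):
        angles = np.arange(0.0, 360.0, 15.0)
        y = 1.2 + 0.4 * np.sin(2.0 * np.deg2rad(angles) + 0.0 + 0.75 * np.pi)
        fit = fit_sinusoid(RotationScan(angles, y))
        assert fit.a0 == pytest.approx(1.2, abs=1e-6)
        assert fit.amplitude == pytest.approx(0.4, abs=1e-6)
        assert fit.omega == pytest.approx(2.0, abs=1e-6)
        # phase is identified modulo 2*pi
        assert min(fit.phi % (2 * np.pi), 2 * np.pi - fit.phi % (2 * np.pi)) < 1e-6
        assert fit.r_max == pytest.approx(1.6, abs=1e-6)

    def test_constant_scan_degenerates_gracefully(self):
        angles = np.arange(0.0, 360.0, 15.0)
        fit = fit_sinusoid(RotationScan(angles, np.ones(24)))
        assert fit.amplitude == pytest.approx(0.0, abs=1e-6)
        assert fit.r_max == pytest.approx(1.0, abs=1e-6)

    def test_too_few_defined_ratios_raises(self):
        angles = np.arange(0.0, 360.0, 15.0)
        y = np.full(24, np.nan)
        y[:7] = 1.0
        with pytest.raises(ValueError):
            fit_sinusoid(RotationScan(angles, y))

    def test_two_to_one_pattern_recovery(self):
        spec = SyntheticNetworkSpec(
            n_cells=1000, sigma_major=100, sigma_minor=50, alpha_true=90,
            min_spacing=0.0, seed=21,
        )
        fit = fit_sinusoid(rotation_scan(generate_network_points(spec)))
        d = abs(fit.alpha_deg - 90.0)
        assert min(d, 180.0 - d) <= 5.0
        assert abs(fit.omega - 2.0) <= 0.2

    def test_rotation_equivariance(self):
        spec = SyntheticNetworkSpec(
            n_cells=1000, sigma_major=100, sigma_minor=50, alpha_true=90,
            min_spacing=0.0, seed=8,
        )
        pts = generate_network_points(spec)
        alpha_0 = fit_sinusoid(rotation_scan(pts)).alpha_deg
        for delta in (15.0, 30.0, 60.0):
            alpha_d = fit_sinusoid(rotation_scan(pts.rotated(delta))).alpha_deg
            diff = (alpha_d - alpha_0 - delta) % 180.0
            assert min(diff, 180.0 - diff) <= 2.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_fitted_omega_near_two_for_elliptical_patterns(self, seed):
        spec = SyntheticNetworkSpec(
            n_cells=300, sigma_major=120, sigma_minor=60,
            alpha_true=float((seed * 37) % 180), min_spacing=0.0, seed=seed,
        )
        fit = fit_sinusoid(rotation_scan(generate_network_points(spec)))
        assert fit.converged
        assert abs(fit.omega - 2.0) < 0.5


class TestClassification:
    @pytest.mark.parametrize(
        "r_max,alpha,expected",
        [
            (1.05, 90.0, CLASS_ISOTROPIC),
            (1.5, 90.0, CLASS_ORTHOGONAL),
            (1.5, 10.0, CLASS_PARALLEL),
            (1.1, 90.0, CLASS_ISOTROPIC),     # boundary: R_max <= 1.1 is round
            (1.2, 45.0, CLASS_PARALLEL),      # boundary: alpha = 45 is parallel
            (1.2, 135.0, CLASS_ORTHOGONAL),   # boundary: alpha = 135 is orthogonal
            (1.2, 170.0, CLASS_PARALLEL),
        ],
    )
    def test_threshold_semantics(self, r_max, alpha, expected):
        fit = SinusoidFitResult(
            a0=r_max - 0.1, amplitude=0.1, omega=2.0, phi=0.0,
            r_max=r_max, alpha_deg=alpha, rmse=0.0,
        )
        assert classify_network(fit).network_class == expected

    def test_failed_fit_is_unclassifiable(self):
        bad = SinusoidFitResult(
            a0=np.nan, amplitude=np.nan, omega=np.nan, phi=np.nan,
            r_max=np.nan, alpha_deg=np.nan, rmse=np.nan, converged=False,
        )
        with pytest.raises(ValueError):
            classify_network(bad)


class TestNetworkMetrics:
    def test_square_hull(self):
        pts = NetworkPointSet(
            [50, 50], [[0, 0], [100, 0], [100, 100], [0, 100]]
        )
        m = network_metrics(pts)
        assert m.n_cells == 5  # patched cell is counted
        assert m.area_mm2 == pytest.approx(0.01)
        assert m.density_per_mm2 == pytest.approx(500.0)

    def test_collinear_cells_flag_area_undefined(self):
        pts = NetworkPointSet([0, 0], [[1, 1], [2, 2]])
        m = network_metrics(pts)
        assert m.area_mm2 is None and m.density_per_mm2 is None

    def test_default_spec_matches_study_scale(self, wt_points):
        m = network_metrics(wt_points)
        assert m.n_cells == 64
        assert abs(m.density_per_mm2 - 1484.0) / 1484.0 <= 0.25
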