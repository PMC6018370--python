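"""Reflectivity normalization, curvature/thickness oracles, CDF descriptors."""

import numpy as np
import pytest

from octdr import (
    BoundarySet,
    LayerMap,
    OCTBScan,
    PhantomConfig,
    build_cdf,
    compute_curvature,
    compute_thickness,
    generate_bscan,
    normalize_reflectivity,
    select_reflectivity_regions,
    assemble_descriptor,
)
from octdr.features import FEATURE_FAMILIES


def _flat_boundaries(width: int, rows: list[float]) -> BoundarySet:
    return BoundarySet(np.tile(np.asarray(rows, dtype=float)[:, None],
                               (1, width)))


class TestReflectivityNormalization:
    def test_calibration_anchors_map_to_zero_and_thousand(self,
                                                          noisy_phantom):
        _, scan, truth = noisy_phantom
        norm = normalize_reflectivity(scan, truth.layer_map)
        vit = scan.intensities[truth.layer_map.labels == 0]
        rpe = scan.intensities[truth.layer_map.labels == 12]
        v_med, r_med = np.median(vit), np.median(rpe)
        mid = 0.5 * (v_med + r_med)
        # apply the fitted map to the anchor values themselves
        at = lambda x: (x - v_med) / (r_med - v_med) * 1000.0
        assert at(v_med) == pytest.approx(0.0, abs=1e-9)
        assert at(r_med) == pytest.approx(1000.0, abs=1e-9)
        assert at(mid) == pytest.approx(500.0, abs=1e-9)
        # and check the image was actually transformed with it
        np.testing.assert_allclose(
            norm, np.clip(at(scan.intensities), -100, 1100), atol=1e-9)

    def test_inverted_contrast_signals_failed_segmentation(self,
                                                           noiseless_phantom):
        cfg, scan, truth = noiseless_phantom
        inverted = OCTBScan(1.0 - scan.intensities, cfg.axial_um_per_px,
                            cfg.lateral_um_per_px,
                            fovea_column_px=scan.fovea_column_px)
        with pytest.raises(ValueError, match="segmentation"):
            normalize_reflectivity(inverted, truth.layer_map)

    def test_descriptor_invariant_to_global_affine_intensity_change(
            self, noisy_phantom):
        cfg, scan, truth = noisy_phantom
        rescaled = OCTBScan(0.6 * scan.intensities + 0.2, cfg.axial_um_per_px,
                            cfg.lateral_um_per_px,
                            fovea_column_px=scan.fovea_column_px)
        d1 = assemble_descriptor(scan, truth.layer_map, truth.boundaries)
        d2 = assemble_descriptor(rescaled, truth.layer_map, truth.boundaries)
        # identical up to float rounding flipping a rare sample across a
        # CDF grid point
        np.testing.assert_allclose(d1.vector(), d2.vector(), atol=0.02)


class TestRegionSelection:
    def test_windows_flank_the_fovea_symmetrically(self, noiseless_phantom):
        _, scan, truth = noiseless_phantom
        fc = truth.fovea_column_px
        windows = select_reflectivity_regions(truth.layer_map, fc)
        assert len(windows) == 2
        for lo, hi in windows:
            assert hi - lo == 60
            assert not (lo <= fc < hi)
        (l0, h0), (l1, h1) = windows
        # mirror images about the fovea within rasterization slack
        assert abs((fc - h0) - (l1 - fc)) <= 2

    def test_window_centres_on_a_constructed_parafoveal_bump(self):
        h, w = 120, 200
        labels = np.zeros((h, w), dtype=np.int8)
        top, bottom = 30, 80
        labels[top:bottom, :] = 6
        bump_col = 40
        labels[top - 10:top, bump_col - 3:bump_col + 4] = 6  # thickest at 40
        labels[bottom:, :] = 13
        windows = select_reflectivity_regions(LayerMap(labels), 100, width=20)
        lo, hi = windows[0]  # temporal side
        assert lo <= bump_col < hi
        assert abs((lo + hi) // 2 - bump_col) <= 1

    def test_fovea_at_edge_gives_one_sided_result(self):
        labels = np.full((110, 120), 6, dtype=np.int8)
        with pytest.warns(UserWarning, match="edge"):
            windows = select_reflectivity_regions(LayerMap(labels), 0)
        assert len(windows) == 1

    def test_fovea_outside_image_rejected(self):
        labels = np.full((110, 120), 6, dtype=np.int8)
        with pytest.raises(ValueError):
            select_reflectivity_regions(LayerMap(labels), 200)


class TestCurvature:
    def test_straight_line_has_zero_curvature(self):
        x = np.arange(200, dtype=float)
        curve = 5.0 + 0.3 * x
        k = compute_curvature(curve, 2.0, 3.0)
        np.testing.assert_allclose(k, 0.0, atol=1e-9)

    def test_circular_arc_matches_inverse_radius(self):
        # circle of radius 100 um sampled densely: kappa = 0.01 per um
        r, lateral, axial = 100.0, 1.0, 1.0
        x_um = np.arange(-40.0, 40.0, lateral)
        y_um = r - np.sqrt(r**2 - x_um**2)
        k = compute_curvature(y_um / axial, lateral, axial)
        interior = k[10:-10]
        np.testing.assert_allclose(interior, 0.01, rtol=0.02)

    def test_sinusoid_peak_curvature_matches_closed_form(self):
        # y = A sin(w x): max kappa = A w^2 (at the crests, where y' = 0)
        amp_um, wavelength_um, lateral = 10.0, 600.0, 2.0
        w = 2 * np.pi / wavelength_um
        x_um = np.arange(0, 1800.0, lateral)
        curve = amp_um * np.sin(w * x_um)  # axial spacing 1 um
        k = compute_curvature(curve, lateral, 1.0)
        assert abs(k.max() - amp_um * w**2) / (amp_um * w**2) < 0.03

    def test_invariant_under_vertical_translation(self):
        rng = np.random.default_rng(3)
        curve = 40 + np.cumsum(rng.normal(0, 0.1, 150))
        k1 = compute_curvature(curve, 2.0, 3.0)
        k2 = compute_curvature(curve + 17.0, 2.0, 3.0)
        np.testing.assert_allclose(k1, k2, atol=1e-12)

    def test_short_curve_rejected(self):
        with pytest.raises(ValueError):
            compute_curvature(np.arange(5.0), 1.0, 1.0, smooth_window=7)


class TestThickness:
    def test_flat_layers_have_constant_thickness(self):
        bset = _flat_boundaries(30, [float(r) for r in
                                     [10, 50, 60, 62, 64, 66, 68, 70, 72, 74,
                                      76, 78, 80]])
        thick = compute_thickness(bset, 1, axial_um_per_px=3.0)
        np.testing.assert_allclose(thick, (50 - 10) * 3.0)

    def test_coincident_boundaries_give_zero(self):
        rows = [10.0] * 2 + list(np.arange(20.0, 31.0))
        bset = _flat_boundaries(12, rows)
        np.testing.assert_allclose(compute_thickness(bset, 1, 3.0), 0.0)

    def test_layer_thicknesses_telescope_to_retina_thickness(
            self, noiseless_phantom):
        cfg, _, truth = noiseless_phantom
        total = sum(compute_thickness(truth.boundaries, k, cfg.axial_um_per_px)
                    for k in range(1, 13))
        retina = truth.boundaries.retina_thickness_px() * cfg.axial_um_per_px
        np.testing.assert_allclose(total, retina, atol=1e-9)


class TestCDF:
    def test_empirical_cdf_definition(self):
        cdf = build_cdf(np.array([1.0, 2.0, 3.0, 4.0]),
                        np.array([0.0, 2.5, 5.0]))
        np.testing.assert_allclose(cdf.values, [0.0, 0.5, 1.0])

    def test_monotone_and_bounded(self, rng):
        samples = rng.normal(0, 1, 500)
        grid = np.linspace(-5, 5, 64)
        cdf = build_cdf(samples, grid)
        assert (np.diff(cdf.values) >= 0).all()
        assert cdf.values[0] == 0.0
        assert cdf.values[-1] == 1.0

    def test_empty_samples_flagged_zero(self):
        cdf = build_cdf(np.array([]), np.linspace(0, 1, 8))
        assert cdf.flagged_empty
        np.testing.assert_array_equal(cdf.values, 0.0)

    def test_non_ascending_grid_rejected(self):
        with pytest.raises(ValueError):
            build_cdf(np.array([1.0]), np.array([0.0, 0.0, 1.0]))


class TestDescriptorAssembly:
    def test_descriptor_has_36_slots_and_is_deterministic(self,
                                                          noiseless_phantom):
        _, scan, truth = noiseless_phantom
        d1 = assemble_descriptor(scan, truth.layer_map, truth.boundaries)
        d2 = assemble_descriptor(scan, truth.layer_map, truth.boundaries)
        assert len(d1.cdfs) == 36
        np.testing.assert_array_equal(d1.vector(), d2.vector())

    def test_perturbing_one_layer_thickness_touches_only_its_slots(self):
        base = PhantomConfig(noise_sd=0.0, fovea_depth_um=0.0, seed=6)
        thick = list(base.layer_base_thickness_um)
        thick[4] = thick[4] + 8.0  # layer 5
        alt = PhantomConfig(noise_sd=0.0, fovea_depth_um=0.0, seed=6,
                            layer_base_thickness_um=tuple(thick))
        descs = []
        for cfg in (base, alt):
            scan, truth = generate_bscan(cfg)
            descs.append(assemble_descriptor(scan, truth.layer_map,
                                             truth.boundaries))
        changed = [
            i for i in range(36)
            if not np.allclose(descs[0].cdfs[i].values,
                               descs[1].cdfs[i].values)
        ]
        # slot 3*(5-1)+2 = 14 is the layer-5 thickness CDF
        assert changed == [14]
        assert FEATURE_FAMILIES[14 % 3] == "thickness"

    def test_missing_fovea_column_rejected(self, noiseless_phantom):
        _, scan, truth = noiseless_phantom
        lmap = LayerMap(truth.layer_map.labels)  # no fovea recorded
        scan_nofovea = OCTBScan(scan.intensities, scan.axial_um_per_px,
                                scan.lateral_um_per_px)
        with pytest.raises(ValueError, match="fovea"):
            assemble_descriptor(scan_nofovea, lmap, truth.boundaries)
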