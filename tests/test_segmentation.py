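"""Shape atlas, LCDG fitting, MGRF/ICM labelling, boundaries, metrics."""

import numpy as np
import pytest

from octdr import (
    BoundarySet,
    LayerMap,
    MGRFParams,
    PhantomConfig,
    boundary_error_um,
    build_shape_atlas,
    dice_coefficient,
    extract_boundaries,
    fit_lcdg,
    generate_bscan,
    histogram_of,
    joint_map_label,
    mean_layer_dice,
    segment_bscan,
)
from octdr.geometry import N_LABELS
from octdr.io import OCTBScan
from octdr.segmentation import ShapeAtlas


class TestShapeAtlas:
    def test_identical_maps_give_confident_prior(self, noiseless_phantom):
        _, _, truth = noiseless_phantom
        n = 5
        atlas = build_shape_atlas([truth.layer_map] * n)
        h, w = truth.layer_map.shape
        true_prob = atlas.prior[truth.layer_map.labels,
                                np.arange(h)[:, None], np.arange(w)[None, :]]
        assert true_prob.min() >= n / (n + N_LABELS) - 1e-6

    def test_prior_sums_to_one_everywhere(self, normal_atlas):
        np.testing.assert_allclose(normal_atlas.prior.sum(axis=0), 1.0,
                                   atol=1e-6)

    def test_prior_entropy_elevated_exactly_where_maps_disagree(self):
        # two groups of maps differing only in layer-6 thickness: the prior
        # is uncertain exactly on the pixels where the two maps disagree
        # (boundary 6 and, cumulatively, everything below it) and maximally
        # certain everywhere else
        base = list(PhantomConfig().layer_base_thickness_um)
        thick = list(base)
        thick[5] += 12.0  # move boundary 6 by 3 rows at 4 um/px
        maps = []
        for t in (base, thick):
            cfg = PhantomConfig(noise_sd=0.0, undulation_amp_um=0.0,
                                fovea_depth_um=0.0,
                                layer_base_thickness_um=tuple(t), seed=1)
            _, truth = generate_bscan(cfg)
            maps.append(truth.layer_map)
        atlas = build_shape_atlas(maps * 2)
        p = atlas.prior.astype(float)
        entropy = -(p * np.log(p)).sum(axis=0)
        floor = entropy.min()
        uncertain = entropy > floor + 1e-6
        disagree = maps[0].labels != maps[1].labels
        assert disagree.any() and uncertain.any()
        np.testing.assert_array_equal(uncertain, disagree)
        # the perturbation leaves everything above interface 6 untouched
        first_disagree_row = int(np.where(disagree.any(axis=1))[0].min())
        assert first_disagree_row > 60

    def test_empty_or_single_training_set_rejected(self, noiseless_phantom):
        _, _, truth = noiseless_phantom
        with pytest.raises(ValueError):
            build_shape_atlas([])
        with pytest.raises(ValueError):
            build_shape_atlas([truth.layer_map])

    def test_prior_normalisation_is_validated(self):
        bad = np.full((N_LABELS, 4, 4), 0.5)
        with pytest.raises(ValueError, match="sum to 1"):
            ShapeAtlas(prior=bad, reference_fovea_column=2, reference_ilm_row=1)


class TestLCDG:
    def test_two_gaussian_parameter_recovery(self):
        rng = np.random.default_rng(42)
        n = 50_000
        x = np.where(rng.random(n) < 0.5,
                     rng.normal(0.3, 0.05, n), rng.normal(0.7, 0.05, n))
        hist = np.bincount(np.clip((x * 255).round().astype(int), 0, 255),
                           minlength=256).astype(float)
        model = fit_lcdg(hist, n_classes=2)
        means = model.class_means
        assert abs(means[0] - 0.3) < 0.01
        assert abs(means[1] - 0.7) < 0.01
        assert abs(model.class_weights[0] - 0.5) < 0.03
        assert abs(model.class_weights[1] - 0.5) < 0.03

    def test_em_loglikelihood_is_monotone(self, noisy_phantom):
        _, scan, _ = noisy_phantom
        model = fit_lcdg(histogram_of(scan), n_classes=14)
        trace = np.asarray(model.loglik_trace)
        assert trace.size >= 2
        assert (np.diff(trace) >= -1e-6 * np.abs(trace[:-1])).all()

    def test_single_level_histogram_flags_fallback(self):
        hist = np.zeros(256)
        hist[100] = 500.0
        model = fit_lcdg(hist, n_classes=3)
        assert model.single_class_fallback
        assert model.n_classes == 1

    def test_densities_are_normalised_and_nonnegative(self, noisy_phantom):
        _, scan, _ = noisy_phantom
        model = fit_lcdg(histogram_of(scan), n_classes=14)
        np.testing.assert_allclose(model.class_density.sum(axis=1), 1.0,
                                   atol=1e-6)
        assert model.class_density.min() >= 0.0
        np.testing.assert_allclose(model.density().sum(), 1.0, atol=1e-6)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_lcdg(np.array([]), 2)
        with pytest.raises(ValueError):
            fit_lcdg(np.ones(10), 1)


class TestJointLabelling:
    def test_noise_free_limit_recovers_every_layer_exactly(self,
                                                           noiseless_phantom):
        # atlas from the truth map itself + potts 0 reduces the model to
        # per-pixel maximum-likelihood over intensity classes
        cfg, scan, truth = noiseless_phantom
        atlas = build_shape_atlas([truth.layer_map] * 2)
        lcdg = fit_lcdg(histogram_of(scan), n_classes=14)
        lmap = joint_map_label(scan, atlas, lcdg,
                               MGRFParams(potts_potential=0.0))
        assert np.array_equal(lmap.labels, truth.layer_map.labels)

    def test_potts_potential_removes_isolated_labels(self, normal_atlas):
        cfg = PhantomConfig(noise_sd=0.0, seed=13)
        scan, truth = generate_bscan(cfg)
        # salt-and-pepper corruption of the scan
        rng = np.random.default_rng(0)
        img = scan.intensities.copy()
        flip = rng.random(img.shape) < 0.02
        img[flip] = rng.random(flip.sum())
        corrupted = OCTBScan(img, cfg.axial_um_per_px, cfg.lateral_um_per_px,
                             fovea_column_px=scan.fovea_column_px)
        lcdg = fit_lcdg(histogram_of(corrupted), n_classes=14)

        def n_isolated(labels):
            pad = np.pad(labels, 1, mode="edge")
            same = np.zeros_like(labels, dtype=int)
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    same += (pad[1 + dr:labels.shape[0] + 1 + dr,
                                 1 + dc:labels.shape[1] + 1 + dc] == labels)
            return int((same == 0).sum())

        loose = joint_map_label(corrupted, normal_atlas, lcdg,
                                MGRFParams(potts_potential=0.0))
        tight = joint_map_label(corrupted, normal_atlas, lcdg,
                                MGRFParams(potts_potential=6.0))
        assert n_isolated(tight.labels) < n_isolated(loose.labels)

    def test_icm_energy_is_nonincreasing(self, normal_atlas, noisy_phantom):
        _, scan, _ = noisy_phantom
        lcdg = fit_lcdg(histogram_of(scan), n_classes=14)
        _, energies = joint_map_label(scan, normal_atlas, lcdg,
                                      MGRFParams(icm_max_iters=4),
                                      return_trace=True)
        diffs = np.diff(energies)
        assert (diffs <= 1e-6).all()

    def test_grid_mismatch_is_an_error(self, normal_atlas):
        cfg = PhantomConfig(image_height_px=150, seed=0)
        scan, _ = generate_bscan(cfg)
        lcdg = fit_lcdg(histogram_of(scan), n_classes=14)
        with pytest.raises(ValueError, match="mismatch"):
            joint_map_label(scan, normal_atlas, lcdg, MGRFParams())

    def test_segmentation_invariant_to_affine_intensity_rescale(
            self, normal_atlas):
        cfg = PhantomConfig(noise_sd=0.03, seed=17)
        scan, _ = generate_bscan(cfg)
        lmap1, _, _ = segment_bscan(scan, normal_atlas)
        rescaled = OCTBScan(0.7 * scan.intensities + 0.15,
                            cfg.axial_um_per_px, cfg.lateral_um_per_px,
                            fovea_column_px=scan.fovea_column_px)
        lmap2, _, _ = segment_bscan(rescaled, normal_atlas)
        agreement = (lmap1.labels == lmap2.labels).mean()
        assert agreement > 0.99


class TestBoundaryExtraction:
    def test_phantom_map_round_trips_within_half_pixel(self,
                                                       noiseless_phantom):
        _, _, truth = noiseless_phantom
        bset = extract_boundaries(truth.layer_map, median_window=1)
        err = np.abs(bset.curves - truth.boundaries.curves)
        assert err.max() <= 0.5 + 1e-9

    def test_missing_layer_collapses_to_zero_thickness(self):
        labels = np.zeros((40, 12), dtype=np.int8)
        for k in range(1, 14):
            labels[2 * k:, :] = k
        labels[labels == 5] = 6  # layer 5 absent everywhere
        bset = extract_boundaries(LayerMap(labels), median_window=1)
        np.testing.assert_array_equal(bset.curves[4], bset.curves[5])
        assert bset.flagged_columns.all()

    def test_output_always_ordered(self, rng):
        # scrambled maps must still yield ordered boundary curves
        for _ in range(5):
            labels = rng.integers(0, 14, (40, 20)).astype(np.int8)
            bset = extract_boundaries(LayerMap(labels))
            assert (np.diff(bset.curves, axis=0) >= 0).all()


class TestMetrics:
    def test_dice_identity_disjoint_and_hand_case(self):
        a = np.zeros((4, 4), dtype=np.int8)
        a[0, :4] = 1  # |A| = 4
        b = np.zeros((4, 4), dtype=np.int8)
        b[0, 1:4] = 1  # overlap 3
        b[1, :3] = 1   # |B| = 6
        assert dice_coefficient(a, a, 1) == 1.0
        assert dice_coefficient(a, 1 - a, 1) == 0.0
        assert dice_coefficient(a, b, 1) == pytest.approx(0.6)

    def test_dice_of_two_empty_masks_is_one_with_warning(self):
        a = np.zeros((4, 4), dtype=np.int8)
        with pytest.warns(UserWarning, match="empty"):
            assert dice_coefficient(a, a, 7) == 1.0

    def test_boundary_error_converts_rows_to_micrometres(self):
        a = BoundarySet(np.tile(np.arange(13.0)[:, None] * 3, (1, 8)))
        b = BoundarySet(a.curves + 2.0)
        err = boundary_error_um(a, b, axial_um_per_px=3.0)
        np.testing.assert_allclose(err, 6.0)
        assert err.shape == (13,)


class TestEndToEnd:
    def test_noiseless_phantoms_are_recovered(self, normal_atlas):
        dices, errs = [], []
        for seed in range(3):
            cfg = PhantomConfig(noise_sd=0.0, seed=200 + seed)
            scan, truth = generate_bscan(cfg)
            lmap, bset, _ = segment_bscan(scan, normal_atlas)
            dices.append(mean_layer_dice(lmap, truth.layer_map))
            errs.append(boundary_error_um(bset, truth.boundaries,
                                          cfg.axial_um_per_px).mean())
        assert np.mean(dices) >= 0.95
        assert np.mean(errs) <= cfg.axial_um_per_px  # <= 1 axial px
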