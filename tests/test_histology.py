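"""Histomorphometry: counting protocol, stain deconvolution, morphometry."""

import numpy as np
import pytest
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from vasomech import histology as h
from vasomech import synthetic as syn


def square_image(gray_value=1.0, size=64):
    pixels = np.full((size, size, 3), int(gray_value * 255), dtype=np.uint8)
    roi = np.array([[2, 2], [size - 3, 2], [size - 3, size - 3], [2, size - 3]], float)
    return h.HistologyImage(pixels, 1.0, roi)


class TestPreprocess:
    def test_uniform_image_stays_uniform(self):
        gray, mask = h.preprocess(square_image(0.5))
        assert np.ptp(gray[mask]) < 1e-6

    def test_zero_sigma_is_grayscale_only(self):
        image = square_image(0.5)
        image.pixels[10, 10] = [0, 0, 0]
        gray, _ = h.preprocess(image, blur_sigma=0.0)
        assert gray[10, 10] == pytest.approx(0.0, abs=1e-6)
        assert gray[10, 12] > 0.4

    def test_impulse_mass_preserved_by_blur(self):
        image = square_image(0.0)
        image.pixels[32, 32] = [255, 255, 255]
        sharp, _ = h.preprocess(image, blur_sigma=0.0)
        blurred, _ = h.preprocess(image, blur_sigma=2.0)
        assert blurred.sum() == pytest.approx(sharp.sum(), rel=0.01)

    def test_roi_outside_bounds_rejected(self):
        pixels = np.zeros((32, 32, 3), np.uint8)
        roi = np.array([[0, 0], [100, 0], [100, 100]], float)
        with pytest.raises(ValueError, match="outside"):
            h.HistologyImage(pixels, 1.0, roi).roi_mask()


class TestSegmentNuclei:
    def test_phantom_counts_are_exact(self, nuclei_phantom, nuclei_analysis):
        ph, _, _ = nuclei_phantom
        labels, stats = nuclei_analysis
        assert stats.count == ph.n_nuclei

    def test_two_overlapping_discs_split_by_watershed(self):
        gray = np.ones((60, 90))
        for center in ((30, 30), (30, 45)):  # centers 1.5 radii apart
            rr, cc = draw_disk(center, 10)
            gray[rr, cc] = 0.0
        labels = h.segment_nuclei(gray, np.ones_like(gray, bool), 0.5)
        assert labels.max() == 2

    def test_blank_roi_yields_zero_labels(self):
        gray = np.ones((40, 40)) * 0.8
        labels = h.segment_nuclei(gray, np.ones_like(gray, bool), 1.0)
        assert labels.max() == 0

    def test_touching_pairs_recovered_over_seeded_phantoms(self, rng):
        # pairs of touching discs at 1.5 radii: ≥95% of objects recovered
        recovered = 0
        for _ in range(20):
            gray = np.ones((80, 80))
            angle = rng.uniform(0, np.pi)
            c = np.array([40.0, 40.0])
            offset = 7.5 * np.array([np.cos(angle), np.sin(angle)])
            for center in (c - offset, c + offset):
                rr, cc = draw_disk(center, 10, shape=gray.shape)
                gray[rr, cc] = 0.0
            labels = h.segment_nuclei(gray, np.ones_like(gray, bool), 0.5)
            recovered += labels.max()
        assert recovered >= 0.95 * 40


class TestNucleiStats:
    def test_disc_roundness_is_one(self):
        labels = np.zeros((64, 64), int)
        rr, cc = draw_disk((32, 32), 15)
        labels[rr, cc] = 1
        stats = h.nuclei_stats(labels, 1.0, 64 * 64.0)
        assert stats.roundness[0] == pytest.approx(1.0, abs=0.05)

    def test_two_to_one_ellipse_roundness_is_half(self):
        labels = np.zeros((80, 120), int)
        rr, cc = draw_ellipse(40, 60, 15, 30)
        labels[rr, cc] = 1
        stats = h.nuclei_stats(labels, 1.0, 80 * 120.0)
        assert stats.roundness[0] == pytest.approx(0.5, abs=0.05)

    def test_density_hand_arithmetic(self):
        # 20 one-pixel nuclei in a 0.01 mm² ROI -> 2000 count/mm²
        labels = np.zeros((100, 100), int)
        for i in range(20):
            labels[5 * i, 5 * i] = i + 1
        stats = h.nuclei_stats(labels, 1.0, 10_000.0)
        assert stats.density_per_mm2 == pytest.approx(2000.0)

    def test_phantom_density_and_area_recovery(self, nuclei_phantom, nuclei_analysis):
        _, image, truth = nuclei_phantom
        _, stats = nuclei_analysis
        assert stats.density_per_mm2 == pytest.approx(truth.nuclei_density_per_mm2, rel=0.05)
        assert stats.mean_area_um2 == pytest.approx(truth.nucleus_areas_um2.mean(), rel=0.05)


class TestDeconvolution:
    def test_white_pixel_is_zero_concentration(self):
        pixels = np.full((2, 2, 3), 255, np.uint8)
        conc = h.deconvolve_stains(pixels)
        np.testing.assert_allclose(conc, 0.0, atol=1e-9)

    def test_pure_and_mixed_stains_recovered(self):
        stains = h.default_evg_stains()
        pure = 255.0 * 10.0 ** -(1.0 * stains.matrix[0])
        mixed = 255.0 * 10.0 ** -(0.3 * stains.matrix[0] + 0.7 * stains.matrix[1])
        pixels = np.stack([np.tile(pure, (2, 1)), np.tile(mixed, (2, 1))]).reshape(2, 2, 3)
        conc = h.deconvolve_stains(pixels, stains)
        np.testing.assert_allclose(conc[0, 0], [1.0, 0.0, 0.0], atol=1e-6)
        np.testing.assert_allclose(conc[1, 0], [0.3, 0.7, 0.0], atol=1e-6)

    def test_round_trip_with_rgb_noise_within_five_percent(self, rng):
        stains = h.default_evg_stains()
        truth = np.array([0.6, 0.3, 0.1])
        od = truth @ stains.matrix
        clean = 255.0 * 10.0**-od
        pixels = np.clip(clean + rng.normal(0, 3.0, size=(200, 200, 3)), 1, 255)
        conc = h.deconvolve_stains(pixels, stains)
        np.testing.assert_allclose(conc.mean(axis=(0, 1)), truth, rtol=0.05, atol=0.01)

    def test_singular_matrix_rejected(self):
        row = np.array([0.6, 0.6, 0.52915026])
        with pytest.raises(ValueError, match="singular|ill-conditioned"):
            h.StainMatrix(np.array([row, row, [0.1, 0.2, 0.97467943]]))


class TestFiberFractions:
    def test_phantom_fractions_within_one_point(self, fiber_phantom):
        _, image, truth = fiber_phantom
        conc = h.deconvolve_stains(image.pixels)
        fr = h.fiber_fractions(conc, image.roi_mask())
        assert fr.elastin_pct == pytest.approx(100 * truth.elastin_fraction, abs=1.0)
        assert fr.collagen_pct == pytest.approx(100 * truth.collagen_fraction, abs=1.0)

    def test_blank_roi_is_zero(self):
        conc = np.zeros((10, 10, 3))
        fr = h.fiber_fractions(conc, np.zeros((10, 10), bool))
        assert fr.elastin_pct == 0.0 and fr.collagen_pct == 0.0

    def test_monotone_in_threshold(self, fiber_phantom):
        _, image, _ = fiber_phantom
        conc = h.deconvolve_stains(image.pixels)
        mask = image.roi_mask()
        previous = 101.0
        for threshold in (0.05, 0.15, 0.5, 0.9):
            pct = h.fiber_fractions(conc, mask, threshold).elastin_pct
            assert pct <= previous + 1e-9
            previous = pct


class TestMorphometry:
    def test_circle_diameter_from_perimeter(self):
        m = h.morphometry_from_perimeters(np.pi * 1000, np.pi * 1200, np.pi * 1500)
        assert m.internal_diameter == pytest.approx(1000.0)
        assert m.external_diameter == pytest.approx(1500.0)
        assert m.intima_media_thickness == pytest.approx(100.0)
        assert m.adventitia_thickness == pytest.approx(150.0)

    def test_reference_aorta_media_lumen_ratio(self):
        # printed group means: internal 1610 µm, intima-media 121.4 µm imply
        # a media/lumen ratio of 1.151, within 1.3% of the reported 1.165
        m = h.morphometry_from_perimeters(
            np.pi * 1610.0, np.pi * (1610.0 + 2 * 121.4), np.pi * 2089.0
        )
        assert m.media_lumen_ratio == pytest.approx(1.1508, abs=0.001)
        assert m.media_lumen_ratio == pytest.approx(1.165, rel=0.02)

    def test_scale_equivariance(self):
        base = h.morphometry_from_perimeters(1000.0, 1500.0, 2000.0)
        scaled = h.morphometry_from_perimeters(3000.0, 4500.0, 6000.0)
        assert scaled.internal_diameter == pytest.approx(3 * base.internal_diameter)
        assert scaled.cross_section_area == pytest.approx(9 * base.cross_section_area)
        assert scaled.media_lumen_ratio == pytest.approx(base.media_lumen_ratio)

    def test_ordering_violation_rejected(self):
        with pytest.raises(ValueError, match="perimeters"):
            h.morphometry_from_perimeters(1000.0, 900.0, 2000.0)


class TestTracePerimeters:
    def test_phantom_perimeters_within_two_percent(self, vessel_phantom):
        _, image, truth = vessel_phantom
        lum, med, adv = h.trace_perimeters(image, image.pixel_size)
        assert lum == pytest.approx(truth.luminal_perimeter_um, rel=0.02)
        assert med == pytest.approx(truth.medial_perimeter_um, rel=0.02)
        assert adv == pytest.approx(truth.adventitial_perimeter_um, rel=0.02)

    def test_phantom_diameters_within_two_percent(self, vessel_phantom):
        ph, image, _ = vessel_phantom
        m = h.morphometry_from_perimeters(*h.trace_perimeters(image, image.pixel_size))
        assert m.internal_diameter == pytest.approx(ph.inner_diameter, rel=0.02)
        assert m.external_diameter == pytest.approx(ph.outer_diameter, rel=0.02)

    def test_non_annular_image_rejected(self):
        blank = np.full((64, 64, 3), 255, np.uint8)
        with pytest.raises(ValueError, match="no tissue"):
            h.trace_perimeters(blank, 1.0)
        two_blobs = np.full((64, 64, 3), 255, np.uint8)
        two_blobs[5:15, 5:15] = 100
        two_blobs[40:50, 40:50] = 100
        with pytest.raises(ValueError, match="single"):
            h.trace_perimeters(two_blobs, 1.0)

    def test_pixel_size_scales_perimeters(self, vessel_phantom):
        _, image, _ = vessel_phantom
        gray = image.pixels
        p1 = h.trace_perimeters(gray, 2.0)
        p2 = h.trace_perimeters(gray, 4.0)
        np.testing.assert_allclose(p2, np.asarray(p1) * 2.0)
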