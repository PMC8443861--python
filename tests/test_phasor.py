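import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lipidphasor as lp
from lipidphasor.phasor import phasor_histogram, reciprocity_select

from conftest import naive_phasor, random_image


def _single_pixel_image(spectrum, axis):
    return lp.HyperspectralImage(np.asarray(spectrum, float)[None, None, :], axis)


class TestComputePhasor:
    def test_delta_spectrum_in_first_channel_maps_to_unit_phasor(self, axis):
        spec = np.zeros(22)
        spec[0] = 7.0
        fld = lp.compute_phasor(_single_pixel_image(spec, axis))
        assert fld.g[0, 0] == pytest.approx(1.0, abs=1e-12)
        assert fld.s[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_uniform_spectrum_maps_to_origin(self, axis):
        fld = lp.compute_phasor(_single_pixel_image(np.full(22, 3.0), axis))
        assert abs(fld.g[0, 0]) < 1e-12
        assert abs(fld.s[0, 0]) < 1e-12

    def test_gaussian_pixel_matches_bruteforce_fourier_loop(self, axis):
        k = np.arange(22)
        spec = np.exp(-0.5 * ((k - 8) / 2.0) ** 2)
        img = lp.HyperspectralImage(np.tile(spec, (3, 2, 1)), axis)
        fld = lp.compute_phasor(img)
        g0, s0 = naive_phasor(img.data)
        np.testing.assert_allclose(fld.g, g0, atol=1e-12)
        np.testing.assert_allclose(fld.s, s0, atol=1e-12)

    def test_zero_intensity_pixels_flagged_invalid_not_nan(self, axis):
        data = np.zeros((2, 2, 22))
        data[0, 0] = 1.0
        fld = lp.compute_phasor(lp.HyperspectralImage(data, axis))
        assert fld.valid[0, 0]
        assert not fld.valid[1, 1]
        assert np.all(np.isfinite(fld.g)) and np.all(np.isfinite(fld.s))

    def test_all_zero_image_rejected(self, axis):
        with pytest.raises(ValueError, match="all-zero"):
            lp.compute_phasor(lp.HyperspectralImage(np.zeros((2, 2, 22)), axis))

    def test_negative_intensities_rejected(self, axis):
        with pytest.raises(ValueError, match="negative"):
            lp.HyperspectralImage(np.full((2, 2, 22), -1.0), axis)

    def test_min_intensity_threshold_masks_dim_pixels(self, axis):
        data = np.ones((1, 2, 22))
        data[0, 1] *= 100
        fld = lp.compute_phasor(lp.HyperspectralImage(data, axis), min_intensity=50)
        assert not fld.valid[0, 0] and fld.valid[0, 1]


class TestPhasorProperties:
    def test_linearity_of_image_sum(self, axis):
        rng = np.random.default_rng(7)
        a = random_image(rng, axis=axis)
        b = random_image(rng, axis=axis)
        fa, fb = lp.compute_phasor(a), lp.compute_phasor(b)
        fsum = lp.compute_phasor(lp.HyperspectralImage(a.data + b.data, axis))
        ia, ib = a.total_intensity, b.total_intensity
        np.testing.assert_allclose(
            fsum.g, (ia * fa.g + ib * fb.g) / (ia + ib), atol=1e-12)
        np.testing.assert_allclose(
            fsum.s, (ia * fa.s + ib * fb.s) / (ia + ib), atol=1e-12)

    def test_invariance_to_global_intensity_scaling(self, axis):
        rng = np.random.default_rng(8)
        img = random_image(rng, axis=axis)
        f1 = lp.compute_phasor(img)
        f2 = lp.compute_phasor(lp.HyperspectralImage(img.data * 37.5, axis))
        np.testing.assert_allclose(f1.g, f2.g, atol=1e-12)
        np.testing.assert_allclose(f1.s, f2.s, atol=1e-12)

    def test_vectorized_equals_naive_loop_on_random_images(self, axis):
        rng = np.random.default_rng(9)
        for _ in range(5):
            img = random_image(rng, axis=axis)
            fld = lp.compute_phasor(img)
            g0, s0 = naive_phasor(img.data)
            np.testing.assert_allclose(fld.g, g0, atol=1e-12)
            np.testing.assert_allclose(fld.s, s0, atol=1e-12)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(shift=st.integers(min_value=0, max_value=21),
           harmonic=st.integers(min_value=1, max_value=3))
    def test_circular_shift_rotates_phasor_by_harmonic_angle(self, axis, shift, harmonic):
        rng = np.random.default_rng(11)
        spec = rng.gamma(2.0, 1.0, size=22)
        g0, s0 = lp.spectrum_phasor(spec, harmonic)
        g1, s1 = lp.spectrum_phasor(np.roll(spec, shift), harmonic)
        rot = 2 * np.pi * harmonic * shift / 22
        assert g1 == pytest.approx(g0 * np.cos(rot) - s0 * np.sin(rot), abs=1e-12)
        assert s1 == pytest.approx(g0 * np.sin(rot) + s0 * np.cos(rot), abs=1e-12)

    def test_nonnegative_spectra_stay_inside_unit_circle(self, axis):
        rng = np.random.default_rng(12)
        data = rng.exponential(1.0, size=(100, 100, 22))
        fld = lp.compute_phasor(lp.HyperspectralImage(data, axis))
        _, m = lp.phase_modulation(fld)
        assert np.nanmax(m) <= 1 + 1e-12


class TestPhaseModulation:
    @pytest.mark.parametrize("g,s,theta,m", [
        (1.0, 0.0, 0.0, 1.0),
        (0.0, 0.5, np.pi / 2, 0.5),
        (-0.5, 0.0, np.pi, 0.5),
        (0.0, -0.5, 3 * np.pi / 2, 0.5),
    ])
    def test_known_positions(self, g, s, theta, m):
        fld = lp.PhasorField(
            g=np.array([[g]]), s=np.array([[s]]),
            total_intensity=np.ones((1, 1)), valid=np.ones((1, 1), bool))
        th, mm = lp.phase_modulation(fld)
        assert th[0, 0] == pytest.approx(theta, abs=1e-12)
        assert mm[0, 0] == pytest.approx(m, abs=1e-12)

    def test_red_shift_increases_phase_angle(self, axis):
        thetas = []
        for peak in (520.0, 580.0, 640.0):
            spec = lp.make_component_spectrum("x", peak, 50.0, axis)
            g, s = lp.spectrum_phasor(spec)
            thetas.append(np.mod(np.arctan2(s, g), 2 * np.pi))
        assert thetas[0] < thetas[1] < thetas[2]

    def test_band_narrowing_increases_modulation(self, axis):
        mods = []
        for fwhm in (100.0, 60.0, 30.0):
            g, s = lp.spectrum_phasor(lp.make_component_spectrum("x", 580.0, fwhm, axis))
            mods.append(np.hypot(g, s))
        assert mods[0] < mods[1] < mods[2]

    def test_invalid_pixels_flagged_not_raised(self):
        fld = lp.PhasorField(
            g=np.zeros((1, 2)), s=np.zeros((1, 2)),
            total_intensity=np.array([[0.0, 1.0]]), valid=np.array([[False, True]]))
        th, m = lp.phase_modulation(fld)
        assert np.isnan(th[0, 0]) and np.isfinite(th[0, 1])


class TestPhasorHistogram:
    def _field(self, gs, valid=None):
        gs = np.asarray(gs, float)
        n = gs.shape[0]
        if valid is None:
            valid = np.ones(n, bool)
        return lp.PhasorField(g=gs[:, 0], s=gs[:, 1],
                              total_intensity=np.ones(n), valid=valid)

    def test_single_pixel_gives_one_nonzero_bin(self):
        hist, _, _ = phasor_histogram(self._field([[0.3, 0.2]]), bins=64)
        assert (hist > 0).sum() == 1
        assert hist.sum() == 1

    def test_coincident_pixels_accumulate(self):
        hist, _, _ = phasor_histogram(self._field([[0.3, 0.2], [0.3, 0.2]]), bins=64)
        assert hist.max() == 2

    def test_uniform_spectrum_image_mass_at_center(self, axis):
        img = lp.HyperspectralImage(np.ones((4, 4, 22)), axis)
        hist, ge, se = phasor_histogram(lp.compute_phasor(img), bins=21)
        i = np.searchsorted(ge, 0.0, side="right") - 1
        j = np.searchsorted(se, 0.0, side="right") - 1
        assert hist[i, j] == 16 and hist.sum() == 16

    def test_counts_sum_to_valid_pixels(self):
        fld = self._field([[0.1, 0.1], [0.2, 0.2], [0.3, 0.3]],
                          valid=np.array([True, True, False]))
        hist, _, _ = phasor_histogram(fld, bins=16)
        assert hist.sum() == 2

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError):
            phasor_histogram(self._field([[0.0, 0.0]]), bins=1)


class TestReciprocitySelect:
    def _field(self, axis):
        rng = np.random.default_rng(21)
        return lp.compute_phasor(random_image(rng, shape=(8, 8), axis=axis))

    def test_polygon_covering_unit_disk_selects_all_valid(self, axis):
        fld = self._field(axis)
        square = np.array([[-1.1, -1.1], [1.1, -1.1], [1.1, 1.1], [-1.1, 1.1]])
        np.testing.assert_array_equal(reciprocity_select(fld, square), fld.valid)

    def test_polygon_away_from_cloud_selects_nothing(self, axis):
        fld = self._field(axis)
        far = np.array([[-1.0, -1.0], [-0.99, -1.0], [-0.99, -0.99], [-1.0, -0.99]])
        assert not reciprocity_select(fld, far).any()

    def test_degenerate_polygon_rejected(self, axis):
        fld = self._field(axis)
        with pytest.raises(ValueError, match="degenerate"):
            reciprocity_select(fld, np.array([[0, 0], [1, 1], [0.5, 0.5]]))

    def test_egfp_vertex_region_recovers_egfp_pixels(self, spectra, pure_phasors):
        _, egfp_img = lp.render_calibration_controls(photon_budget=1000, seed=4)
        fld = lp.compute_phasor(egfp_img)
        c = pure_phasors["egfp"]
        t = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        poly = np.column_stack([c[0] + 0.25 * np.cos(t), c[1] + 0.25 * np.sin(t)])
        sel = reciprocity_select(fld, poly)
        h, w = egfp_img.shape
        truth = np.zeros((h, w), bool)
        truth[h // 4: 3 * h // 4, w // 4: 3 * w // 4] = True
        jaccard = (sel & truth).sum() / (sel | truth).sum()
        assert jaccard >= 0.95
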