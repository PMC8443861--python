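import dataclasses

import numpy as np
import pytest

import lipidphasor as lp


class TestRenderScene:
    def _one_cell_config(self, **kw):
        defaults = dict(shape=(32, 32),
                        cells=(lp.CellSpec("round_droplet", (16, 16), 8.0),),
                        seed=7)
        defaults.update(kw)
        return lp.SceneConfig(**defaults)

    def test_same_seed_bit_identical(self):
        cfg = self._one_cell_config()
        img1, _ = lp.render_scene(cfg)
        img2, _ = lp.render_scene(cfg)
        np.testing.assert_array_equal(img1.data, img2.data)

    def test_pure_egfp_pixel_spectrum_proportional_to_egfp(self, spectra):
        cfg = lp.SceneConfig(
            shape=(8, 8), background=0.0,
            cells=(lp.CellSpec("irregular_no_droplet", (4, 4), 3.0, egfp=1.0),),
            poisson=False, seed=0)
        img, truth = lp.render_scene(cfg)
        r, c = np.argwhere(truth.labels > 0)[0]
        np.testing.assert_allclose(truth.fractions[r, c], [0, 0, 1], atol=1e-12)
        pix = img.data[r, c]
        np.testing.assert_allclose(pix / pix.sum(), spectra["egfp"].values, atol=1e-12)

    def test_empty_scene_rejected(self):
        with pytest.raises(ValueError, match="empty scene"):
            lp.SceneConfig(shape=(8, 8), photon_budget=0.0, background=0.0)

    def test_ground_truth_fractions_sum_to_one_on_cells(self):
        _, truth = lp.render_scene(self._one_cell_config())
        fg = truth.labels > 0
        np.testing.assert_allclose(truth.fractions[fg].sum(axis=1), 1.0, atol=1e-12)
        assert np.all(truth.fractions[~fg] == 0)

    def test_noiseless_render_unmixes_to_exact_truth(self, true_vertices):
        cfg = self._one_cell_config(background=0.0, poisson=False)
        img, truth = lp.render_scene(cfg)
        fr = lp.unmix_three_component(lp.compute_phasor(img), true_vertices)
        fg = truth.labels > 0
        assert np.abs(fr.alpha[fg] - truth.fractions[fg]).max() < 1e-10

    def test_expected_total_intensity_matches_photon_budget(self):
        # one big uniform cell covering > 10^4 pixels
        cfg = lp.SceneConfig(
            shape=(128, 128), background=2.0, photon_budget=300.0,
            cells=(lp.CellSpec("irregular_no_droplet", (64, 64), 200.0),), seed=3)
        img, truth = lp.render_scene(cfg)
        fg = truth.labels > 0
        assert fg.sum() > 10_000
        totals = img.total_intensity[fg]
        expected = 300.0 + 2.0 * 22
        se = np.sqrt(expected / totals.size)
        assert abs(totals.mean() - expected) < 3 * se

    def test_ground_truth_invariant_to_noise_seed(self):
        cfg = self._one_cell_config(seed=1)
        _, t1 = lp.render_scene(cfg)
        _, t2 = lp.render_scene(dataclasses.replace(cfg, seed=99))
        np.testing.assert_array_equal(t1.fractions, t2.fractions)
        np.testing.assert_array_equal(t1.labels, t2.labels)
        assert t1.cell_stats.equals(t2.cell_stats)

    def test_droplet_cell_has_polar_rim_around_neutral_core(self):
        _, truth = lp.render_scene(self._one_cell_config())
        stats = truth.cell_stats.iloc[0]
        fr = truth.fractions
        # rim pixels (cell boundary) are polar-dominated, core neutral-rich
        from scipy import ndimage
        cell = truth.labels == 1
        interior = ndimage.binary_erosion(cell, iterations=3)
        rim = cell & ~ndimage.binary_erosion(cell)
        assert fr[rim][:, 0].mean() > fr[rim][:, 1].mean()
        assert fr[interior][:, 1].mean() > fr[interior][:, 0].mean()
        assert stats["class"] == "outside"

    def test_unknown_shape_rejected(self):
        with pytest.raises(ValueError, match="unknown cell shape"):
            lp.CellSpec("blob", (4, 4), 3.0)


class TestCalibrationControls:
    def test_wildtype_control_is_nile_red_only(self, spectra, axis):
        wt, _ = lp.render_calibration_controls(photon_budget=800, seed=2, poisson=False)
        # no EGFP anywhere: every pixel is a polar/neutral mixture, so its
        # spectrum is a convex combination of the two Nile Red spectra
        basis = np.stack([spectra["polar_nilered"].values,
                          spectra["neutral_nilered"].values])
        coef, res, *_ = np.linalg.lstsq(basis.T, wt.data.reshape(-1, 22).T, rcond=None)
        assert float(res.max()) < 1e-12
        assert coef.min() > -1e-9

    def test_egfp_control_foreground_is_pure_egfp(self, spectra):
        _, eg = lp.render_calibration_controls(
            photon_budget=800, seed=2, poisson=False, background=0.0)
        h, w = eg.shape
        block = eg.data[h // 4: 3 * h // 4, w // 4: 3 * w // 4]
        pix = block.reshape(-1, 22)
        pix = pix / pix.sum(axis=1, keepdims=True)
        assert np.abs(pix - spectra["egfp"].values).max() < 1e-12

    def test_zero_budget_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            lp.render_calibration_controls(photon_budget=0.0)


class TestCohortConfig:
    def test_geometry_deterministic_in_seed(self):
        c1 = lp.cohort_config(n_polar=4, n_droplet=4, seed=5)
        c2 = lp.cohort_config(n_polar=4, n_droplet=4, seed=5)
        assert c1 == c2

    def test_cohort_composition(self):
        cfg = lp.cohort_config(n_polar=3, n_droplet=5, seed=1)
        shapes = [c.shape for c in cfg.cells]
        assert shapes.count("irregular_no_droplet") == 3
        assert shapes.count("round_droplet") == 5

    def test_full_pipeline_recovers_true_cm_within_3_points(self, true_vertices):
        # one droplet cell (neutral core, polar rim) and one droplet-free
        # polar cell, analyzed end to end at 500 expected counts/pixel
        cfg = lp.SceneConfig(
            shape=(64, 96), background=2.0, photon_budget=500.0,
            cells=(lp.CellSpec("round_droplet", (32, 28), 9.0),
                   lp.CellSpec("irregular_no_droplet", (32, 68), 9.0)),
            seed=13)
        img, truth = lp.render_scene(cfg)
        from lipidphasor.phasor import estimate_background_spectrum, subtract_background
        bg = estimate_background_spectrum(img, 150.0)
        img = subtract_background(img, bg)
        fld = lp.compute_phasor(img, min_intensity=150.0 - bg.sum())
        fr = lp.unmix_three_component(fld, true_vertices)
        f, _ = lp.nile_red_neutral_fraction(fr)
        for cid in (1, 2):
            mask = truth.labels == cid
            values = f[mask]
            values = values[np.isfinite(values)]
            p = lp.cell_polarity_profile(values)
            true_cm = truth.cell_stats.set_index("cell_id").loc[cid, "cm"]
            assert abs(p.cm - true_cm) <= 3.0
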