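"""Scan-grid processing tests: masking, averaging, merging, heat maps,
background subtraction, background-cell selection."""

import numpy as np
import pytest

from fibrilsaxs import (CROSSBETA_Q, DetectorGeometry, Profile1D, ScanGrid,
                        SyntheticScanSpec, circular_average, crossbeta_heatmap,
                        gen_scan, grid_shape_from_extent, mask_substrate_peaks,
                        merge_profiles, normalize_beam, render_image,
                        select_background_cells, subtract_background)

GEOM = DetectorGeometry(beam_center=(64.0, 64.0), pixel_size=0.172,
                        distance=300.0, wavelength=1.0)


class TestMasking:
    def test_empty_region_list_is_identity(self):
        img = np.arange(36.0).reshape(6, 6)
        out = mask_substrate_peaks(img, [])
        np.testing.assert_array_equal(out.data, img)
        assert not out.mask.any()

    def test_masked_spikes_do_not_bias_average(self):
        q = np.linspace(0.02, 2.0, 200)
        prof = Profile1D(q, 10.0 / (1 + (q / 0.3) ** 2))
        clean = render_image(prof, GEOM, (128, 128))
        spikes = [(20, 30, 500.0, 1.5), (90, 100, 800.0, 1.5), (40, 90, 300.0, 1.5)]
        spiked = render_image(prof, GEOM, (128, 128), spikes=spikes)
        regions = [(r - 11, r + 12, c - 11, c + 12) for (r, c, _, _) in spikes]
        masked = mask_substrate_peaks(spiked, regions)
        ref = circular_average(mask_substrate_peaks(clean, regions), GEOM)
        got = circular_average(masked, GEOM)
        np.testing.assert_allclose(got.intensity, ref.intensity, rtol=1e-6)

    def test_out_of_bounds_region_rejected(self):
        with pytest.raises(ValueError):
            mask_substrate_peaks(np.zeros((8, 8)), [(0, 10, 0, 2)])

    def test_fully_masked_image_cannot_be_averaged(self):
        out = mask_substrate_peaks(np.ones((8, 8)), [(0, 8, 0, 8)])
        with pytest.raises(ValueError):
            circular_average(out, GEOM)


class TestCircularAverage:
    def test_uniform_image_gives_flat_profile(self):
        prof = circular_average(np.full((64, 64), 7.5), GEOM, n_bins=40)
        np.testing.assert_allclose(prof.intensity, 7.5, rtol=1e-12)

    def test_render_average_round_trip(self):
        q = np.linspace(0.02, 2.0, 300)
        truth = Profile1D(q, 5.0 * np.exp(-((q - 0.8) / 0.5) ** 2) + 1.0)
        img = render_image(truth, GEOM, (256, 256))
        prof = circular_average(img, GEOM, n_bins=150)
        expected = np.interp(prof.q, q, truth.intensity)
        rms = np.sqrt(np.mean((prof.intensity - expected) ** 2))
        assert rms / np.sqrt(np.mean(expected ** 2)) < 0.01

    def test_wedge_mask_preserves_azimuthally_uniform_mean(self):
        q = np.linspace(0.02, 2.0, 300)
        truth = Profile1D(q, 1.0 + q)
        img = render_image(truth, GEOM, (128, 128))
        full = circular_average(img, GEOM, n_bins=60)
        wedge = mask_substrate_peaks(img, [(0, 64, 0, 64)])
        partial = circular_average(wedge, GEOM, n_bins=60)
        common = np.intersect1d(
            np.round(full.q, 10), np.round(partial.q, 10))
        f = np.interp(common, full.q, full.intensity)
        p = np.interp(common, partial.q, partial.intensity)
        np.testing.assert_allclose(p, f, rtol=5e-3)


class TestMergeNormalize:
    def test_known_scale_recovered_and_continuous(self):
        qs = np.linspace(0.01, 0.6, 200)
        qw = np.linspace(0.4, 2.2, 300)
        base = lambda q: 10.0 * np.exp(-q) + 0.3
        saxs = Profile1D(qs, base(qs))
        waxs = Profile1D(qw, 2.0 * base(qw))
        merged = merge_profiles(saxs, waxs, overlap=(0.4, 0.6))
        # the scale estimate carries only the overlap-grid interpolation error
        assert merged.meta["merge_scale"] == pytest.approx(0.5, rel=1e-4)
        np.testing.assert_allclose(merged.intensity,
                                   base(merged.q), rtol=1e-3)

    def test_noisy_split_round_trip(self):
        rng = np.random.default_rng(5)
        q = np.linspace(0.01, 2.2, 500)
        truth = 8.0 * np.exp(-q) + 0.5
        noise = lambda x: x * (1 + rng.normal(0, 0.01, x.size))
        saxs = Profile1D(q[q < 0.7], noise(truth[q < 0.7]))
        waxs = Profile1D(q[q > 0.35], 3.0 * noise(truth[q > 0.35]))
        merged = merge_profiles(saxs, waxs, overlap=(0.35, 0.7))
        expected = np.interp(merged.q, q, truth)
        assert np.max(np.abs(merged.intensity - expected) / expected) < 0.05

    def test_disjoint_ranges_rejected(self):
        saxs = Profile1D(np.linspace(0.01, 0.2, 50), np.ones(50))
        waxs = Profile1D(np.linspace(1.0, 2.0, 50), np.ones(50))
        with pytest.raises(ValueError):
            merge_profiles(saxs, waxs, overlap=(0.3, 0.5))

    def test_monitor_normalization_invertible(self):
        q = np.linspace(0.01, 1.0, 50)
        prof = Profile1D(q, np.exp(-q), 0.1 * np.exp(-q))
        out = normalize_beam(normalize_beam(prof, 2.0), 0.5)
        np.testing.assert_allclose(out.intensity, prof.intensity, rtol=1e-12)
        np.testing.assert_allclose(out.sigma, prof.sigma, rtol=1e-12)
        with pytest.raises(ValueError):
            normalize_beam(prof, 0.0)


class TestHeatMap:
    def test_grid_bookkeeping_inclusive_counting(self):
        assert grid_shape_from_extent(300.0, 400.0, 5.0) == (61, 81)
        nx, ny = grid_shape_from_extent(300.0, 400.0, 5.0)
        assert nx * ny == 4941

    def test_scan_without_plaques_maps_to_zero(self):
        blank, _ = gen_scan(SyntheticScanSpec(nx=7, ny=7, plaques=(), seed=1))
        with_plaque, _ = gen_scan(
            SyntheticScanSpec(nx=7, ny=7, plaques=((3, 3, 1.5),), seed=1))
        h_blank = crossbeta_heatmap(blank)
        h_plaque = crossbeta_heatmap(with_plaque)
        assert h_blank.values.max() < 0.05 * h_plaque.values.max()

    def test_planted_plaque_located(self):
        spec = SyntheticScanSpec(nx=15, ny=15, plaques=((5, 9, 2.0),), seed=2)
        grid, truth = gen_scan(spec)
        heat = crossbeta_heatmap(grid)
        ix, iy = heat.argmax_cell
        assert truth.plaque_mask[iy, ix]
        plaque_vals = heat.values[truth.plaque_mask]
        background = np.median(heat.values[~truth.plaque_mask])
        assert np.all(plaque_vals > 5 * max(background, 1e-12))

    def test_q_linear_baseline_invariance(self):
        spec = SyntheticScanSpec(nx=5, ny=5, plaques=((2, 2, 1.2),), seed=3)
        grid, _ = gen_scan(spec)
        heat0 = crossbeta_heatmap(grid)
        shifted_rows = []
        for row in grid.profiles:
            shifted_rows.append([
                Profile1D(p.q, p.intensity + 3.0 + 1.7 * p.q, p.sigma)
                for p in row])
        grid2 = ScanGrid(grid.nx, grid.ny, grid.step, shifted_rows)
        heat1 = crossbeta_heatmap(grid2)
        np.testing.assert_allclose(heat1.values, heat0.values,
                                   rtol=1e-8, atol=1e-10)

    def test_window_outside_grid_rejected(self):
        spec = SyntheticScanSpec(nx=3, ny=3, plaques=(), seed=0)
        grid, _ = gen_scan(spec, qgrid=np.linspace(0.01, 0.5, 100))
        with pytest.raises(ValueError):
            crossbeta_heatmap(grid)


class TestBackgroundSubtraction:
    @staticmethod
    def _triplet(a_true):
        q = np.linspace(0.05, 2.2, 400)
        substrate = 0.3 + 0.1 * np.cos(q)
        tissue_excess = 2.0 * np.exp(-q / 1.5)
        lesion = substrate + a_true * tissue_excess
        return (Profile1D(q, lesion), Profile1D(q, substrate + tissue_excess),
                Profile1D(q, substrate))

    def test_exact_scale_recovery_on_noiseless_input(self):
        lesion, tissue, substrate = self._triplet(2.0)
        out, model = subtract_background(lesion, tissue, substrate)
        assert model.a == pytest.approx(2.0, rel=1e-12)
        np.testing.assert_allclose(out.intensity, 0.0, atol=1e-12)

    def test_lesion_equal_substrate_gives_zero_scale(self):
        _, tissue, substrate = self._triplet(1.0)
        out, model = subtract_background(substrate, tissue, substrate)
        assert model.a == pytest.approx(0.0, abs=1e-14)
        np.testing.assert_allclose(out.intensity, 0.0, atol=1e-12)

    def test_fibril_component_recovered_with_boosted_tissue(self):
        # lesion = substrate + 1.3 x tissue excess + fibril peak that is
        # negligible inside the 1.6-2.0 fit window
        q = np.linspace(0.05, 2.2, 400)
        substrate = 0.3 + 0.1 * np.cos(q)
        tissue_excess = 2.0 * np.exp(-q / 1.5)
        fibril = 0.8 * np.exp(-0.5 * ((q - CROSSBETA_Q) / 0.01) ** 2)
        lesion = Profile1D(q, substrate + 1.3 * tissue_excess + fibril)
        out, model = subtract_background(
            lesion, Profile1D(q, substrate + tissue_excess),
            Profile1D(q, substrate))
        assert model.a == pytest.approx(1.30, abs=0.01)
        np.testing.assert_allclose(out.intensity, fibril, atol=1e-9)

    def test_degenerate_tissue_rejected(self):
        q = np.linspace(0.05, 2.2, 400)
        flat = Profile1D(q, np.ones_like(q))
        with pytest.raises(ValueError):
            subtract_background(flat, flat, flat)


class TestBackgroundCellSelection:
    def test_uniform_map_tie_break_is_deterministic(self):
        spec = SyntheticScanSpec(nx=11, ny=11, plaques=(), seed=4)
        grid, _ = gen_scan(spec)
        from fibrilsaxs import HeatMap
        heat = HeatMap(np.zeros((11, 11)), 1.337, 0.03)
        _, cells = select_background_cells(grid, heat, (5, 5), n=4)
        # ties resolved by distance then row-major order: the four nearest
        # annulus cells are straight up/left-right at distance 3
        assert cells == [(5, 2), (2, 5), (8, 5), (5, 8)]

    def test_selected_cells_avoid_planted_plaque(self):
        spec = SyntheticScanSpec(nx=15, ny=15, plaques=((7, 7, 2.5),), seed=5)
        grid, truth = gen_scan(spec)
        heat = crossbeta_heatmap(grid)
        _, cells = select_background_cells(grid, heat, (7, 7), n=5)
        for ix, iy in cells:
            assert not truth.plaque_mask[iy, ix]

    def test_insufficient_annulus_population_rejected(self):
        spec = SyntheticScanSpec(nx=5, ny=5, plaques=(), seed=6)
        grid, _ = gen_scan(spec)
        from fibrilsaxs import HeatMap
        heat = HeatMap(np.zeros((5, 5)), 1.337, 0.03)
        with pytest.raises(ValueError):
            select_background_cells(grid, heat, (2, 2), n=50)


class TestScanIO:
    def test_directory_round_trip(self, tmp_path):
        spec = SyntheticScanSpec(nx=3, ny=2, plaques=(), seed=7)
        grid, _ = gen_scan(spec, qgrid=np.linspace(0.01, 2.1, 60))
        grid.write_dir(tmp_path / "scan")
        back = ScanGrid.read_dir(tmp_path / "scan")
        assert (back.nx, back.ny, back.step) == (3, 2, 5.0)
        np.testing.assert_allclose(back.cell(2, 1).intensity,
                                   grid.cell(2, 1).intensity, rtol=1e-6)

    def test_missing_cell_reported_with_indices(self, tmp_path):
        spec = SyntheticScanSpec(nx=2, ny=2, plaques=(), seed=8)
        grid, _ = gen_scan(spec, qgrid=np.linspace(0.01, 2.1, 30))
        grid.write_dir(tmp_path / "scan")
        (tmp_path / "scan" / "001_001.dat").unlink()
        with pytest.raises(FileNotFoundError, match="ix=1, iy=1"):
            ScanGrid.read_dir(tmp_path / "scan")
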