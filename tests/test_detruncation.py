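import numpy as np
import pytest

from efovct.containers import CTImage, Sinogram
from efovct.detruncation import (
    EmptyMaskError,
    binarize_object,
    cosine_detruncate,
    hdfov_reconstruct,
    linear_cos2_detruncate,
    mask_to_sinogram,
    merge_sinograms,
    projection_mass,
)
from efovct.phantom import EllipseComponent, PhantomSpec
from efovct.projection import (
    DEFAULT_MU_WATER,
    fbp_reconstruct,
    forward_project,
    hu_to_mu,
    pad_to_bore,
    truncate,
)


class TestProjectionMass:
    def test_untruncated_profile_is_flat_and_matches_integral(self, thorax_case):
        """For complete data the mass profile is angle-invariant and
        equals the area integral of the attenuation (oracle)."""
        prof = projection_mass(thorax_case["wide_sino"])
        assert prof.normalized.min() > 0.995
        img = thorax_case["image"]
        integral = hu_to_mu(img).sum() * img.pixel_spacing_mm**2
        assert abs(prof.reference[0] / integral - 1.0) < 0.005

    def test_truncated_profile_drops_below_one(self, thorax_case):
        prof = projection_mass(thorax_case["measured"])
        assert prof.normalized.min() < 0.99

    def test_scaling_leaves_normalized_profile_unchanged(self, thorax_case):
        sino = thorax_case["measured"]
        prof = projection_mass(sino)
        scaled = Sinogram(3.0 * sino.values, sino.geometry, sino.measured)
        prof3 = projection_mass(scaled)
        assert np.allclose(prof3.mass, 3.0 * prof.mass)
        assert np.allclose(prof3.normalized, prof.normalized)

    def test_all_zero_rejected(self, geo360):
        sino = Sinogram(np.zeros((1, geo360.n_angles, geo360.n_channels)), geo360)
        with pytest.raises(ValueError):
            projection_mass(sino)


class TestCosineDetruncate:
    def test_untruncated_rows_returned_unchanged(self, geo360, wide360):
        spec = PhantomSpec((EllipseComponent((0, 0), (120.0, 90.0), 0.0, 0.0),))
        img, _ = spec.rasterize(800.0 / 256, 256)
        sino = truncate(forward_project(img, wide360))
        det = cosine_detruncate(sino)
        i0, i1 = det.sinogram.measured_range
        assert np.array_equal(det.sinogram.values[:, :, i0:i1], sino.values)
        # object inside the sFoV: nothing to extend
        assert np.allclose(det.sinogram.values[:, :, :i0], 0.0)
        assert np.allclose(det.sinogram.values[:, :, i1:], 0.0)

    def test_single_row_deficit_absorbed_exactly(self, geo360):
        """On a constructed single truncated row, the added weighted mass
        equals the deficit (quadrature oracle)."""
        nc = geo360.n_channels
        values = np.zeros((1, geo360.n_angles, nc))
        # one flat-ish row with signal reaching both edges
        u = np.linspace(-1, 1, nc)
        row = 4.0 - 1.5 * u**2
        values[0, 0] = row
        values[0, 1:] = row * 1.12  # reference rows (larger mass, untruncated shape)
        sino = Sinogram(values, geo360)
        det = cosine_detruncate(sino)
        prof = projection_mass(det.sinogram)
        assert abs(prof.normalized[0, 0] - 1.0) <= 1e-3

    def test_thorax_scan_mass_consistent_after_detruncation(self, thorax_case):
        det = cosine_detruncate(thorax_case["measured"])
        prof = projection_mass(det.sinogram)
        assert np.abs(prof.normalized - 1.0).max() <= 1e-3

    def test_extension_decays_monotonically(self, thorax_case):
        det = cosine_detruncate(thorax_case["measured"])
        i0, i1 = det.sinogram.measured_range
        # worst truncated view: check outward decay of the right extension
        a = int(np.argmax(det.added_mass[0]))
        right = det.sinogram.values[0, a, i1:]
        nz = right[right > 0]
        assert (np.diff(nz) <= 1e-12).all()

    def test_added_mass_nonnegative(self, thorax_case):
        det = cosine_detruncate(thorax_case["measured"])
        assert (det.added_mass >= 0.0).all()


class TestLinearCos2:
    def _row_sinogram(self, geo360, left_val, slope_in):
        nc = geo360.n_channels
        values = np.zeros((1, geo360.n_angles, nc))
        u = np.arange(nc, dtype=float)
        values[0, :, :] = left_val + slope_in * u
        return Sinogram(values, geo360)

    def test_flat_edge_gives_pure_cos2_decay(self, geo360):
        sino = self._row_sinogram(geo360, 2.0, 0.0)
        det = linear_cos2_detruncate(sino)
        i0, i1 = det.sinogram.measured_range
        tail = det.sinogram.values[0, 0, i1:]
        du = det.sinogram.geometry.channel_spacing_mm
        w_bore = (det.sinogram.geometry.n_channels - i1 + 0.5) * du
        x = (np.arange(tail.size) + 1) * du
        expected = 2.0 * np.cos(0.5 * np.pi * np.minimum(x / w_bore, 1.0)) ** 2
        assert np.allclose(tail, expected)

    def test_edge_value_continuity_and_zero_at_bore(self, thorax_case):
        det = linear_cos2_detruncate(thorax_case["measured"])
        i0, i1 = det.sinogram.measured_range
        vals = det.sinogram.values
        # continuity: first extension channel close to the edge channel
        a = int(np.argmax(vals[0, :, i1 - 1]))
        assert vals[0, a, i1] == pytest.approx(vals[0, a, i1 - 1], rel=0.1)
        # the outermost channel of the bore-wide grid is (near) zero
        assert np.abs(vals[0, :, -1]).max() < 1e-3 * vals.max()

    def test_slope_matches_measured_slope(self, geo360):
        sino = self._row_sinogram(geo360, 1.0, 0.002)
        det = linear_cos2_detruncate(sino)
        i0, i1 = det.sinogram.measured_range
        du = det.sinogram.geometry.channel_spacing_mm
        row = det.sinogram.values[0, 0]
        slope_ext = (row[i1] - row[i1 - 1]) / du
        slope_meas = (row[i1 - 1] - row[i1 - 2]) / du
        assert slope_ext == pytest.approx(slope_meas, rel=0.1)


class TestBinarize:
    def test_air_image_signals_empty_mask(self):
        img = CTImage(np.full((1, 32, 32), -1000.0), 4.0)
        with pytest.raises(EmptyMaskError):
            binarize_object(img)

    def test_disc_mask_area_close_to_analytic(self):
        spec = PhantomSpec((EllipseComponent((0, 0), (100.0, 100.0), 0.0, 0.0),))
        img, _ = spec.rasterize(2.0, 256)
        mask = binarize_object(img, sigma_mm=5.0, sigma_slices=0.0, threshold_hu=-400.0)
        area = mask.sum() * 4.0
        assert abs(area / (np.pi * 100.0**2) - 1.0) < 0.03

    def test_cross_slice_smoothing_couples_slices(self):
        vals = np.full((3, 64, 64), -1000.0)
        vals[1, 24:40, 24:40] = 200.0
        img = CTImage(vals, 4.0)
        coupled = binarize_object(img, sigma_mm=4.0, sigma_slices=1.0, threshold_hu=-700.0)
        uncoupled = binarize_object(img, sigma_mm=4.0, sigma_slices=0.0, threshold_hu=-700.0)
        assert coupled[0].any() and coupled[2].any()
        assert not uncoupled[0].any() and not uncoupled[2].any()


class TestMaskToSinogram:
    def test_empty_mask_projects_to_zero(self, geo360):
        grid = CTImage(np.zeros((1, 64, 64)), 800.0 / 64)
        sino = mask_to_sinogram(np.zeros((1, 64, 64), dtype=bool), grid, geo360)
        assert np.allclose(sino.values, 0.0)

    def test_disc_mask_central_chord(self, geo360):
        spec = PhantomSpec((EllipseComponent((0, 0), (100.0, 100.0), 0.0, 0.0),))
        img, mask = spec.rasterize(800.0 / 512, 512)
        sino = mask_to_sinogram(mask, img, geo360)
        center = sino.values[0, :, geo360.n_channels // 2]
        assert np.allclose(center, 2 * 100.0 * DEFAULT_MU_WATER, rtol=0.02)

    def test_water_phantom_mask_projection_matches_forward_projection(self, geo360):
        """For a water-HU phantom the water-filled mask and the phantom
        itself produce the same projections."""
        spec = PhantomSpec((EllipseComponent((0, 40), (150.0, 100.0), 0.2, 0.0),))
        img, mask = spec.rasterize(800.0 / 256, 256)
        direct = forward_project(img, geo360)
        from_mask = mask_to_sinogram(mask, img, geo360)
        assert np.allclose(direct.values, from_mask.values, atol=1e-9)


class TestMerge:
    def test_measured_block_is_bit_exact(self, thorax_case, wide360):
        measured = thorax_case["measured"]
        rng = np.random.default_rng(0)
        sim = Sinogram(
            rng.uniform(0, 5, (1, wide360.n_angles, wide360.n_channels)), wide360
        )
        merged = merge_sinograms(measured, sim)
        i0, i1 = merged.measured_range
        assert np.array_equal(merged.values[:, :, i0:i1], measured.values)

    def test_identical_overlap_merges_to_simulated(self, thorax_case):
        wide = thorax_case["wide_sino"]
        measured = thorax_case["measured"]
        merged = merge_sinograms(measured, wide, fade_channels=3)
        assert np.allclose(merged.values, wide.values, atol=1e-12)

    def test_zero_simulated_equals_zero_padding(self, thorax_case, wide360):
        measured = thorax_case["measured"]
        sim = Sinogram(np.zeros((1, wide360.n_angles, wide360.n_channels)), wide360)
        merged = merge_sinograms(measured, sim, fade_channels=0)
        assert np.array_equal(merged.values, pad_to_bore(measured).values)
        # with a fade window only the fade channels may differ from padding
        faded = merge_sinograms(measured, sim, fade_channels=3)
        i0, i1 = faded.measured_range
        assert np.allclose(faded.values[:, :, : i0 - 3], 0.0)
        assert np.allclose(faded.values[:, :, i1 + 3 :], 0.0)

    def test_grid_mismatch_rejected(self, thorax_case, geo360):
        sim = Sinogram(np.zeros((1, geo360.n_angles, geo360.n_channels)), geo360)
        with pytest.raises(ValueError):
            merge_sinograms(thorax_case["measured"], sim)


class TestHDFoVPipeline:
    def test_object_inside_sfov_equals_plain_fbp(self, geo360, wide360):
        spec = PhantomSpec((EllipseComponent((0, 0), (120.0, 90.0), 0.0, 50.0),))
        img, _ = spec.rasterize(800.0 / 256, 256)
        sino = truncate(forward_project(img, wide360))
        from efovct.detruncation import HDFoVConfig

        hd = hdfov_reconstruct(sino, HDFoVConfig(matrix=256))
        plain = fbp_reconstruct(pad_to_bore(sino), fov_mm=800.0, matrix=256)
        assert np.abs(hd.values - plain.values).max() < 2.0

    def test_improves_over_naive_fbp(self, thorax_case, geo360, recon_grid):
        from efovct.evaluation import jaccard_efov, object_mask

        measured = thorax_case["measured"]
        hd = hdfov_reconstruct(measured)
        naive = fbp_reconstruct(pad_to_bore(measured), fov_mm=800.0, matrix=512)
        x, y = recon_grid.grid_coords()
        mask_true = np.stack([thorax_case["spec"].mask(x, y, 0)])
        j_hd = jaccard_efov(mask_true, object_mask(hd), recon_grid, geo360)
        j_naive = jaccard_efov(mask_true, object_mask(naive), recon_grid, geo360)
        assert j_hd > j_naive
        assert j_hd > 0.8
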