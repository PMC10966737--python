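"""Geometry calibration, azimuthal integration, peak fitting, maps."""

import numpy as np
import pytest

from enamelmap.geometry import (
    GAP_SENTINEL,
    DetectorGeometry,
    Diffractogram1D,
    GapSpec,
    Image2D,
    RasterGrid,
)
from enamelmap.phantom import build_enamel_phantom, evolve_demineralization, DeminParams
from enamelmap.simulate import (
    LiquidBackground,
    ReflectionList,
    TextureModel,
    detector_polar,
    simulate_calibrant_pattern,
    simulate_waxs_pattern,
)
from enamelmap.waxs import (
    azimuthal_integrate,
    azimuthal_profile,
    build_detector_mask,
    build_maps,
    calibrate_geometry,
    fit_peak,
    raster_lookup_correction,
    summed_intensity,
    texture_width,
)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

class TestCalibration:
    def test_exact_start_is_fixed_point(self, desk_detector, lab6):
        pattern = simulate_calibrant_pattern(desk_detector, lab6,
                                             detector_shape=(256, 256))
        res = calibrate_geometry(pattern, list(lab6.d_spacings), desk_detector,
                                 n_rays=120)
        assert res.residual_rms_px < 0.05
        assert res.geometry.distance == pytest.approx(9.6, rel=1e-4)
        assert res.geometry.beam_center[0] == pytest.approx(127.5, abs=0.02)

    def test_perturbed_start_recovers_geometry(self, desk_detector, lab6):
        pattern = simulate_calibrant_pattern(desk_detector, lab6, seed=3,
                                             detector_shape=(256, 256),
                                             amplitude=3000.0)
        start = desk_detector.replace(distance=10.1,
                                      beam_center=(130.0, 125.0))
        res = calibrate_geometry(pattern, list(lab6.d_spacings), start, n_rays=120)
        assert res.geometry.distance == pytest.approx(9.6, rel=1e-3)
        assert res.geometry.beam_center[0] == pytest.approx(127.5, abs=0.1)
        assert res.geometry.beam_center[1] == pytest.approx(127.5, abs=0.1)

    def test_single_ring_insufficient(self, desk_detector):
        one = ReflectionList(entries=((1, 0, 0, 4.1569, 100.0),), lattice=(4.1569, 4.1569))
        pattern = simulate_calibrant_pattern(desk_detector, one,
                                             detector_shape=(256, 256))
        with pytest.raises(RuntimeError, match="2 resolvable rings"):
            calibrate_geometry(pattern, [4.1569, 2.9393], desk_detector, n_rays=60)


# ---------------------------------------------------------------------------
# Masking
# ---------------------------------------------------------------------------

class TestMask:
    def test_no_gaps_all_usable(self):
        mask = build_detector_mask((64, 64))
        assert mask.values.all()

    def test_gap_rows_masked_fraction(self):
        gaps = GapSpec(row_gaps=((100, 17), (300, 17)))
        mask = build_detector_mask((512, 64), gaps)
        assert (~mask.values).mean() == pytest.approx(34 / 512)

    def test_user_mask_anded(self):
        user = Image2D(np.zeros((32, 32), dtype=bool), 1.0, "mask")
        user.values[:16] = True
        gaps = GapSpec(col_gaps=((0, 8),))
        mask = build_detector_mask((32, 32), gaps, user)
        assert not mask.values[20:, :].any()
        assert not mask.values[:, :8].any()
        assert mask.values[:16, 8:].all()


# ---------------------------------------------------------------------------
# Azimuthal integration
# ---------------------------------------------------------------------------

def brute_force_integration(values, mask, q, lo, hi, n_bins):
    """Per-pixel reference binning: explicit edge comparisons per bin."""
    edges = np.linspace(lo, hi, n_bins + 1)
    intensity = np.zeros(n_bins)
    coverage = np.zeros(n_bins)
    for j in range(n_bins):
        if j < n_bins - 1:
            sel = mask & (q >= edges[j]) & (q < edges[j + 1])
        else:
            sel = mask & (q >= edges[j]) & (q <= edges[j + 1])
        coverage[j] = sel.sum()
        if coverage[j]:
            intensity[j] = values[sel].mean()
    return intensity, coverage


class TestIntegration:
    def test_constant_pattern_integrates_to_constant(self, desk_detector):
        img = Image2D(np.full((128, 128), 3.25), 172.0, "waxs")
        geo = desk_detector.replace(beam_center=(63.5, 63.5))
        dg = azimuthal_integrate(img, geo, None, n_bins=32)
        assert np.allclose(dg.intensity[dg.valid], 3.25, rtol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_brute_force_oracle(self, desk_detector, seed):
        rng = np.random.default_rng(seed)
        values = rng.random((96, 96)) * 100.0
        maskarr = rng.random((96, 96)) > 0.1
        geo = desk_detector.replace(beam_center=(47.5 + seed, 45.0))
        img = Image2D(values, 172.0, "waxs")
        mask = Image2D(maskarr, 1.0, "mask")
        dg = azimuthal_integrate(img, geo, mask, n_bins=24)
        r, _ = detector_polar((96, 96), geo.beam_center)
        q = np.asarray(geo.q_of_radius(r))
        lo, hi = q[maskarr].min(), q[maskarr].max()
        ref_i, ref_c = brute_force_integration(values, maskarr, q, lo, hi, 24)
        assert np.array_equal(dg.coverage, ref_c)
        nz = ref_c > 0
        assert np.max(np.abs(dg.intensity[nz] - ref_i[nz])
                      / np.maximum(np.abs(ref_i[nz]), 1e-300)) < 1e-10

    def test_integration_conserves_masked_sum(self, desk_detector):
        rng = np.random.default_rng(7)
        values = rng.random((96, 96))
        img = Image2D(values, 172.0, "waxs")
        geo = desk_detector.replace(beam_center=(47.5, 47.5))
        dg = azimuthal_integrate(img, geo, None, n_bins=40)
        total = np.sum(dg.intensity * dg.coverage)
        assert total == pytest.approx(values.sum(), rel=1e-10)

    def test_sample_vs_background_peak_contrast(self, compact_detector, hap):
        ph = build_enamel_phantom((64, 64, 64), 2.0, rod_pitch=5.0, seed=2)
        grid = RasterGrid(origin=(64.0, 64.0), step=(200.0, 10.0), counts=(2, 1),
                          beam_size=(10.0, 10.0))
        kw = dict(texture=TextureModel(kappa=0.0),
                  background=LiquidBackground(container_level=0.0), dark_level=1.0)
        on = simulate_waxs_pattern(ph, grid, (0, 0), compact_detector, (128, 128),
                                   hap, noise_seed=1, **kw)
        off = simulate_waxs_pattern(ph, grid, (1, 0), compact_detector, (128, 128),
                                    hap, noise_seed=2, **kw)
        q002 = 2.0 * np.pi / hap.d_of((0, 0, 2))
        window = (q002 - 0.12, q002 + 0.12)
        amp_on = fit_peak(azimuthal_integrate(on, compact_detector, None, 100),
                          window).amplitude
        amp_off = fit_peak(azimuthal_integrate(off, compact_detector, None, 100),
                           window).amplitude
        assert amp_on > 5.0 * max(amp_off, 1e-9)

    def test_empty_mask_rejected(self, desk_detector):
        img = Image2D(np.ones((32, 32)), 172.0, "waxs")
        mask = Image2D(np.zeros((32, 32), dtype=bool), 1.0, "mask")
        with pytest.raises(ValueError, match="mask"):
            azimuthal_integrate(img, desk_detector, mask, n_bins=16)


# ---------------------------------------------------------------------------
# Azimuthal profiles (texture)
# ---------------------------------------------------------------------------

def _arc_pattern(shape, center, r0, sigma_r, phi0=None, sigma_phi=None, amp=100.0):
    r, phi = detector_polar(shape, center)
    img = amp * np.exp(-0.5 * ((r - r0) / sigma_r) ** 2)
    if phi0 is not None:
        d = (phi - phi0 + 180.0) % 360.0 - 180.0
        img *= np.exp(-0.5 * (d / sigma_phi) ** 2)
    return img


class TestAzimuthalProfile:
    def test_isotropic_ring_flat_profile(self, desk_detector):
        geo = desk_detector.replace(beam_center=(95.5, 95.5))
        img = Image2D(_arc_pattern((192, 192), geo.beam_center, 60.0, 2.0), 172.0,
                      "waxs")
        q0 = float(geo.q_of_radius(60.0))
        prof = azimuthal_profile(img, geo, None, (q0 * 0.95, q0 * 1.05), n_phi=48)
        assert prof.intensity.std() / prof.intensity.mean() < 0.02

    def test_gaussian_arc_parameters_recovered(self, desk_detector):
        geo = desk_detector.replace(beam_center=(95.5, 95.5))
        img = Image2D(
            _arc_pattern((192, 192), geo.beam_center, 60.0, 2.0, phi0=90.0,
                         sigma_phi=15.0),
            172.0, "waxs",
        )
        q0 = float(geo.q_of_radius(60.0))
        prof = azimuthal_profile(img, geo, None, (q0 * 0.95, q0 * 1.05), n_phi=72)
        bin_width = 360.0 / 72
        peak_phi = prof.phi[np.argmax(prof.intensity)]
        assert abs(peak_phi - 90.0) <= bin_width
        # spread of the arc: weighted circular SD of a Gaussian ~ sigma
        assert texture_width(prof) == pytest.approx(15.0, rel=0.10)

    def test_gap_bins_flagged_invalid(self, desk_detector):
        geo = desk_detector.replace(beam_center=(95.5, 95.5))
        values = _arc_pattern((192, 192), geo.beam_center, 60.0, 2.0)
        gaps = GapSpec(row_gaps=((90, 12),))  # cuts through the annulus
        values[gaps.gap_mask((192, 192))] = GAP_SENTINEL
        img = Image2D(values, 172.0, "waxs")
        mask = build_detector_mask((192, 192), gaps)
        q0 = float(geo.q_of_radius(60.0))
        prof = azimuthal_profile(img, geo, mask, (q0 * 0.97, q0 * 1.03), n_phi=72)
        assert (~prof.valid).any()
        # starved bins sit where the gap rows cross the ring (phi ~ 0 and 180)
        bad_phi = prof.phi[~prof.valid]
        assert np.all((np.minimum(bad_phi, 360 - bad_phi) < 30)
                      | (np.abs(bad_phi - 180) < 30))

    def test_fully_masked_annulus_rejected(self, desk_detector):
        img = Image2D(np.ones((64, 64)), 172.0, "waxs")
        geo = desk_detector.replace(beam_center=(31.5, 31.5))
        with pytest.raises(ValueError, match="annulus"):
            azimuthal_profile(img, geo, None, (50.0, 60.0), n_phi=16)


# ---------------------------------------------------------------------------
# Peak fitting
# ---------------------------------------------------------------------------

def _synthetic_peak(q, center, amplitude, fwhm, slope, intercept):
    g = amplitude * np.exp(-4 * np.log(2) * ((q - center) / fwhm) ** 2)
    return g + slope * q + intercept


def grid_search_peak(q, y, window, n_grid=400):
    """Dense (center, fwhm) grid search with linear solve for amp/background."""
    best = (np.inf, None)
    for c in np.linspace(window[0], window[1], n_grid):
        for w in np.linspace(0.01, 0.25, 60):
            g = np.exp(-4 * np.log(2) * ((q - c) / w) ** 2)
            A = np.column_stack([g, q, np.ones_like(q)])
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            if coef[0] < 0:
                continue
            rss = np.sum((y - A @ coef) ** 2)
            if rss < best[0]:
                best = (rss, (c, coef[0], w))
    return best[1]


class TestPeakFit:
    def test_noise_free_gaussian_recovered_exactly(self):
        q = np.linspace(1.6, 2.1, 80)
        y = _synthetic_peak(q, 1.827, 40.0, 0.08, -3.0, 12.0)
        dg = Diffractogram1D(q=q, intensity=y, coverage=np.full(80, 50.0),
                             valid=np.ones(80, bool))
        fit = fit_peak(dg, (1.70, 1.95), model="gaussian")
        assert fit.center == pytest.approx(1.827, rel=1e-6)
        assert fit.amplitude == pytest.approx(40.0, rel=1e-6)
        assert fit.fwhm == pytest.approx(0.08, rel=1e-6)
        assert fit.background[0] == pytest.approx(-3.0, rel=1e-4)

    def test_noisy_peak_matches_grid_search_oracle(self):
        rng = np.random.default_rng(21)
        q = np.linspace(1.6, 2.1, 80)
        y = _synthetic_peak(q, 1.83, 40.0, 0.08, -3.0, 12.0) + rng.normal(0, 1.0, 80)
        dg = Diffractogram1D(q=q, intensity=y, coverage=np.full(80, 50.0),
                             valid=np.ones(80, bool))
        fit = fit_peak(dg, (1.70, 1.95), model="gaussian")
        oc, oa, _ = grid_search_peak(q, y, (1.70, 1.95))
        bin_width = q[1] - q[0]
        assert abs(fit.center - oc) <= 0.5 * bin_width
        assert fit.amplitude == pytest.approx(oa, rel=0.05)
        assert abs(fit.center - 1.83) <= 0.5 * bin_width
        assert fit.amplitude == pytest.approx(40.0, rel=0.05)

    def test_windows_without_peak_fit_near_zero(self):
        rng = np.random.default_rng(5)
        q = np.linspace(1.6, 2.1, 80)
        y = 8.0 + 2.0 * q + rng.normal(0, 0.5, 80)
        dg = Diffractogram1D(q=q, intensity=y, coverage=np.full(80, 50.0),
                             valid=np.ones(80, bool))
        fit = fit_peak(dg, (1.70, 1.95))
        assert fit.amplitude < 3.0 * 0.5

    def test_too_few_valid_bins_rejected(self):
        q = np.linspace(1.6, 2.1, 10)
        dg = Diffractogram1D(q=q, intensity=np.ones(10), coverage=np.ones(10),
                             valid=np.zeros(10, bool))
        with pytest.raises(ValueError, match="valid bins"):
            fit_peak(dg, (1.70, 1.95))


class TestSummedIntensity:
    def test_zero_pattern(self):
        assert summed_intensity(Image2D(np.zeros((16, 16)), 172.0, "waxs")) == 0.0

    def test_equals_masked_sum_oracle(self):
        rng = np.random.default_rng(9)
        values = rng.random((64, 64))
        maskarr = rng.random((64, 64)) > 0.3
        total = summed_intensity(Image2D(values, 172.0, "waxs"),
                                 Image2D(maskarr, 1.0, "mask"))
        # explicit double loop oracle
        ref = 0.0
        for i in range(64):
            for j in range(64):
                if maskarr[i, j]:
                    ref += values[i, j]
        assert total == pytest.approx(ref, rel=1e-12)


# ---------------------------------------------------------------------------
# Maps and the raster lookup correction
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def lesion_scene(compact_detector):
    """Small raster scene over a phantom with and without a lesion."""
    hap = ReflectionList.hydroxyapatite()
    # slab face sits at x = 102.4; 40 000 s at 8e-4 um/s erodes 32 um of rods,
    # so the lesion zone spans x in [70.4, 102.4] within the window's (y, z)
    window = ((70.4, 129.0), (30.0, 98.0), (40.0, 88.0))
    ph0 = build_enamel_phantom((64, 64, 64), 2.0, rod_pitch=5.0, seed=4,
                               window=window)
    ph1 = evolve_demineralization(
        ph0, 40000.0, DeminParams(rate_rod=8e-4, rate_inter=4e-4, softening=0.12))
    grid = RasterGrid(origin=(30.0, 24.0), step=(24.0, 26.0), counts=(4, 3),
                      beam_size=(10.0, 10.0))
    # sigma_r = 1.2 px keeps the (002) q-width well inside the fit window
    # on this short-distance detector
    kw = dict(texture=TextureModel(kappa=2.0), sigma_r=1.2,
              background=LiquidBackground(container_level=0.0), dark_level=1.0)
    patterns = {}
    for tag, ph in (("t0", ph0), ("t1", ph1)):
        patterns[tag] = {
            (iy, ix): simulate_waxs_pattern(ph, grid, (ix, iy), compact_detector,
                                            (128, 128), hap,
                                            noise_seed=hash((tag, ix, iy)) % 2**31,
                                            **kw)
            for iy in range(3) for ix in range(4)
        }
    q002 = 2.0 * np.pi / hap.d_of((0, 0, 2))
    return {"grid": grid, "patterns": patterns, "window": window,
            "q002_window": (q002 - 0.12, q002 + 0.12), "phantoms": (ph0, ph1)}


class TestMaps:
    def test_map_shapes_follow_grid(self, lesion_scene, compact_detector):
        maps = build_maps(lesion_scene["patterns"]["t0"], lesion_scene["grid"],
                          compact_detector, q002_window=lesion_scene["q002_window"],
                          n_bins=100)
        for m in maps:
            assert m.values.shape == (3, 4)
        names = {m.quantity for m in maps}
        assert {"total_intensity", "peak002_intensity", "texture_width"} <= names

    def test_all_background_grid_has_no_peak(self, compact_detector, hap):
        ph = build_enamel_phantom((64, 64, 64), 2.0, rod_pitch=5.0, seed=4)
        grid = RasterGrid(origin=(-500.0, 24.0), step=(10.0, 20.0), counts=(2, 2),
                          beam_size=(10.0, 10.0))
        patterns = {
            (iy, ix): simulate_waxs_pattern(
                ph, grid, (ix, iy), compact_detector, (128, 128), hap,
                background=LiquidBackground(container_level=0.0), dark_level=1.0,
                sigma_r=1.2, noise_seed=iy * 2 + ix)
            for iy in range(2) for ix in range(2)
        }
        q002 = 2.0 * np.pi / hap.d_of((0, 0, 2))
        maps = {m.quantity: m for m in build_maps(
            patterns, grid, compact_detector, q002_window=(q002 - 0.12, q002 + 0.12),
            n_bins=100)}
        amp = maps["peak002_intensity"]
        assert not amp.valid.any()
        assert np.abs(amp.values).max() < 1.0

    def test_missing_pattern_leaves_validity_hole(self, lesion_scene, compact_detector):
        patterns = dict(lesion_scene["patterns"]["t0"])
        del patterns[(1, 2)]
        maps = {m.quantity: m for m in build_maps(
            patterns, lesion_scene["grid"], compact_detector,
            q002_window=lesion_scene["q002_window"], n_bins=100)}
        assert not maps["peak002_intensity"].valid[1, 2]
        assert maps["peak002_intensity"].values[1, 2] == 0.0

    def test_amplitude_drops_only_at_lesion_points(self, lesion_scene, compact_detector):
        grid = lesion_scene["grid"]
        (wx0, wx1), (wy0, wy1), _ = lesion_scene["window"]
        out = {}
        for tag in ("t0", "t1"):
            out[tag] = {m.quantity: m for m in build_maps(
                lesion_scene["patterns"][tag], grid, compact_detector,
                q002_window=lesion_scene["q002_window"], n_bins=100)}
        delta = (out["t1"]["peak002_intensity"].values
                 - out["t0"]["peak002_intensity"].values)
        both_valid = (out["t0"]["peak002_intensity"].valid
                      & out["t1"]["peak002_intensity"].valid)
        hw, hh = grid.beam_size[0] / 2, grid.beam_size[1] / 2
        drops = []
        stable = []
        for iy in range(3):
            for ix in range(4):
                if not both_valid[iy, ix]:
                    continue
                x, y = grid.point_xy(ix, iy)
                touches = (wx0 - hw <= x <= wx1 + hw) and (wy0 - hh <= y <= wy1 + hh)
                (drops if touches else stable).append(delta[iy, ix])
        assert min(drops) < -5.0
        assert np.max(np.abs(stable)) < 0.2 * abs(min(drops))


class TestLookupCorrection:
    def test_identical_geometry_zero_offsets(self, desk_detector):
        grid = RasterGrid(origin=(0, 0), step=(10, 10), counts=(3, 2))
        cal = {(iy, ix): desk_detector for iy in range(2) for ix in range(3)}
        lut = raster_lookup_correction(cal, desk_detector, grid)
        assert np.all(lut.d_center_x == 0) and np.all(lut.d_distance == 0)

    def test_missing_point_nearest_filled(self, desk_detector, caplog):
        grid = RasterGrid(origin=(0, 0), step=(10, 10), counts=(3, 1))
        shifted = desk_detector.replace(beam_center=(128.5, 127.5))
        cal = {(0, 0): desk_detector, (0, 2): shifted}
        with caplog.at_level("WARNING", logger="enamelmap"):
            lut = raster_lookup_correction(cal, desk_detector, grid)
        assert any("nearest" in r.message for r in caplog.records)
        assert lut.d_center_x[0, 1] in (0.0, 1.0)

    def test_injected_drift_slope_recovered(self, desk_detector, lab6):
        grid = RasterGrid(origin=(0, 0), step=(24, 20), counts=(6, 1),
                          beam_size=(10, 10))
        cal = {}
        for ix in range(6):
            g = desk_detector.replace(
                beam_center=(127.5 + 0.5 * ix, 127.5))
            pat = simulate_calibrant_pattern(g, lab6, seed=ix,
                                             detector_shape=(256, 256),
                                             amplitude=3000.0)
            cal[(0, ix)] = calibrate_geometry(pat, list(lab6.d_spacings),
                                              desk_detector, n_rays=90).geometry
        lut = raster_lookup_correction(cal, desk_detector, grid)
        slope = np.polyfit(np.arange(6), lut.d_center_x[0], 1)[0]
        assert slope == pytest.approx(0.5, rel=0.05)

    def test_correction_shrinks_peak_center_spread(self, desk_detector, hap):
        # beam rastering drifts the centre by 0.5 px per column; integrating
        # with the per-point geometry must collapse the (002) centre spread
        ph = build_enamel_phantom((96, 64, 96), 2.0, rod_pitch=5.0, seed=6)
        grid = RasterGrid(origin=(60.0, 64.0), step=(12.0, 10.0), counts=(6, 1),
                          beam_size=(10.0, 10.0))
        q002 = 2.0 * np.pi / hap.d_of((0, 0, 2))
        window = (q002 - 0.12, q002 + 0.12)
        centers_ref, centers_cor = [], []
        for ix in range(6):
            true_geo = desk_detector.replace(beam_center=(127.5 + 0.5 * ix, 127.5))
            pat = simulate_waxs_pattern(
                ph, grid, (ix, 0), true_geo, (256, 256), hap,
                texture=TextureModel(kappa=0.0),
                background=LiquidBackground(container_level=0.0), dark_level=0.0)
            for geo, out in ((desk_detector, centers_ref), (true_geo, centers_cor)):
                dg = azimuthal_integrate(pat, geo, None, n_bins=150)
                out.append(fit_peak(dg, window).center)
        assert np.std(centers_ref) > 5.0 * max(np.std(centers_cor), 1e-9)
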