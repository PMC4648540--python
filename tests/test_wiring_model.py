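"""Numerical receptive fields, tuning extraction and orientation maps."""

import math

import numpy as np
import pytest

from moiremap import analytic_moire as am
from moiremap import mosaics as mo
from moiremap import wiring_model as wm
from moiremap.io import load_map, save_map

from conftest import make_hex_pair


def dipole_mosaic(angle, separation=100.0, extent=1500.0):
    """One ON and one OFF cell straddling the origin along ``angle``."""
    v = 0.5 * separation * np.array([math.cos(angle), math.sin(angle)])
    return mo.RGCMosaic(
        np.stack([v, -v]), np.array([mo.ON, mo.OFF], dtype=object),
        mo.Rect.centered(extent),
    )


class TestCorticalRF:
    def test_single_cell_gaussian(self, std_wiring):
        m = mo.RGCMosaic(np.zeros((1, 2)), np.array([mo.ON], dtype=object),
                         mo.Rect.centered(1200.0))
        rf = wm.cortical_rf(m, (0.0, 0.0), std_wiring)
        xg, yg = np.meshgrid(rf.xs_um, rf.ys_um)
        expected = np.exp(-(xg**2 + yg**2) / (2 * std_wiring.sigma_r**2))
        assert np.allclose(rf.values, expected, atol=1e-12)

    def test_dipole_antisymmetry(self, std_wiring):
        m = dipole_mosaic(0.0)
        rf = wm.cortical_rf(m, (0.0, 0.0), std_wiring, n_px=81)
        # reflection through the dipole's perpendicular bisector (x -> -x)
        assert np.allclose(rf.values, -rf.values[:, ::-1], atol=1e-12)

    def test_matches_theta_closed_form(self, std_params, std_wiring):
        """Master oracle: numerical lattice sum equals the theta-function
        closed form at interior positions."""
        mosaic = make_hex_pair(std_params, 10.0 * std_params.r)
        rng = np.random.default_rng(19)
        # sample a full Moiré cell: near the origin the two lattices nearly
        # coincide and ON/OFF contributions cancel almost exactly
        ys = rng.uniform(-600, 600, (10, 2))
        pairs = []
        for y in ys:
            rf = wm.cortical_rf(mosaic, y, std_wiring, n_px=24,
                                weight_tol=0.0)
            xg, yg = np.meshgrid(rf.xs_um, rf.ys_um)
            pts = np.stack([xg.ravel(), yg.ravel()], axis=-1)
            ref = am.analytic_rf(y, pts, std_params).reshape(rf.values.shape)
            pairs.append((rf.values, ref))
        scale = max(np.max(np.abs(ref)) for _, ref in pairs)
        for vals, ref in pairs:
            assert np.max(np.abs(vals - ref)) <= 1e-8 * scale

    def test_missing_margin_rejected(self, std_wiring):
        m = mo.hexagonal_mosaic(170.0, 0.0, mo.Rect.centered(400.0))
        with pytest.raises(ValueError):
            wm.cortical_rf(m, (0.0, 0.0), std_wiring)


class TestRFTuning:
    def test_rotationally_symmetric_rf_untuned(self, std_wiring):
        m = mo.RGCMosaic(np.zeros((1, 2)), np.array([mo.ON], dtype=object),
                         mo.Rect.centered(1200.0))
        rf = wm.cortical_rf(m, (0.0, 0.0), std_wiring)
        theta, _, osi = wm.rf_tuning(rf)
        assert osi < 1e-6
        assert math.isnan(theta)

    def test_all_zero_rf_rejected(self, std_wiring):
        rf = wm.ReceptiveField(np.zeros((16, 16)), np.arange(16.0),
                               np.arange(16.0), np.zeros(2), std_wiring)
        with pytest.raises(ValueError):
            wm.rf_tuning(rf)

    @pytest.mark.parametrize("deg", range(0, 180, 5))
    def test_dipole_prefers_perpendicular_edge(self, std_wiring, deg):
        """θ_pref = dipole angle + 90° (mod 180°), within 1°."""
        psi = math.radians(deg)
        rf = wm.cortical_rf(dipole_mosaic(psi), (0.0, 0.0), std_wiring,
                            n_px=96)
        theta, _, osi = wm.rf_tuning(rf, n_theta=90)
        assert osi > 0.2
        expected = (psi + math.pi / 2.0) % math.pi
        err = abs(math.degrees(math.atan2(math.sin(2 * (theta - expected)),
                                          math.cos(2 * (theta - expected))))
                  ) / 2.0
        assert err < 1.0

    def test_polarity_flip_invariance(self, std_wiring):
        m = dipole_mosaic(0.7)
        flipped = mo.RGCMosaic(
            m.positions.copy(),
            np.where(m.polarity == mo.ON, mo.OFF, mo.ON).astype(object),
            m.extent,
        )
        rf1 = wm.cortical_rf(m, (0.0, 0.0), std_wiring, n_px=96)
        rf2 = wm.cortical_rf(flipped, (0.0, 0.0), std_wiring, n_px=96)
        assert np.allclose(rf1.values, -rf2.values, atol=1e-12)
        t1, _, _ = wm.rf_tuning(rf1)
        t2, _, _ = wm.rf_tuning(rf2)
        assert t1 == pytest.approx(t2, abs=1e-9)

    def test_center_of_mass_smaller_than_maximum(self, std_wiring):
        rf = wm.cortical_rf(dipole_mosaic(0.0), (0.0, 0.0), std_wiring,
                            n_px=96)
        _, k_com, _ = wm.rf_tuning(rf, k_method="center_of_mass")
        _, k_max, _ = wm.rf_tuning(rf, k_method="maximum")
        assert k_com < k_max

    def test_center_of_mass_osi_smaller(self, std_wiring):
        """OSI from the center-of-mass frequency is substantially smaller
        than from the maximum or CV-maximization estimates."""
        rf = wm.cortical_rf(dipole_mosaic(0.3), (0.0, 0.0), std_wiring,
                            n_px=96)
        _, _, o_com = wm.rf_tuning(rf, k_method="center_of_mass")
        _, _, o_max = wm.rf_tuning(rf, k_method="maximum")
        _, _, o_cv = wm.rf_tuning(rf, k_method="cv_max")
        assert o_com < o_max
        assert o_com < o_cv


class TestUnfilteredMap:
    def test_osi_range_and_masks(self, small_map):
        assert np.all(small_map.osi >= 0.0)
        assert np.all(small_map.osi <= 1.0)
        valid = small_map.valid_mask
        assert np.all(np.isfinite(small_map.theta[valid]))
        z = small_map.z
        assert np.all(np.isfinite(z))

    def test_translation_equivariance(self, std_params, std_wiring):
        """Shifting the mosaic by an integer number of pixels shifts the
        map by the same number of pixels."""
        _, lam_um = am.moire_geometry(std_params)
        lam_mm = lam_um / 1000.0
        grid = wm.CorticalGrid.square(1.5 * lam_mm, 32.0 / lam_mm)
        px_um = grid.pixel_size_mm * 1000.0
        shift_px = 5
        half = lam_um + wm.required_margin_um(std_wiring) + shift_px * px_um
        mosaic = make_hex_pair(std_params, half)
        shifted = mo.RGCMosaic(
            mosaic.positions + np.array([shift_px * px_um, 0.0]),
            mosaic.polarity.copy(), mosaic.extent.pad(shift_px * px_um),
        )
        m1 = wm.compute_unfiltered_map(mosaic, grid, std_wiring)
        m2 = wm.compute_unfiltered_map(shifted, grid, std_wiring)
        a = m1.theta[:, : -shift_px]
        b = m2.theta[:, shift_px:]
        ok = np.isfinite(a) & np.isfinite(b)
        diff = np.abs(np.angle(np.exp(2j * (a[ok] - b[ok])))) / 2
        assert np.percentile(diff, 99) < 1e-6

    def test_rotation_equivariance_single_units(self, std_params,
                                                std_wiring, small_map):
        """Rotating the mosaic rotates preferred orientations."""
        mosaic = make_hex_pair(std_params, 1700.0)
        phi = math.radians(25.0)
        c, s = math.cos(phi), math.sin(phi)
        omega = np.array([[c, -s], [s, c]])
        rotated = mo.RGCMosaic(mosaic.positions @ omega.T,
                               mosaic.polarity.copy(),
                               mosaic.extent.pad(800.0))  # rotated corners
        # probe at strongly tuned map locations (high-OSI bands are sparse)
        y_ret = small_map.grid.retinal_positions_um(std_wiring)
        idx = np.argsort(small_map.osi.ravel())[-6:]
        for y in y_ret[idx]:
            rf1 = wm.cortical_rf(mosaic, y, std_wiring, n_px=96)
            t1, _, o1 = wm.rf_tuning(rf1, n_theta=90)
            rf2 = wm.cortical_rf(rotated, omega @ y, std_wiring, n_px=96)
            t2, _, o2 = wm.rf_tuning(rf2, n_theta=90)
            assert o1 > 0.2 and o2 > 0.2
            err = abs(np.angle(np.exp(2j * (t2 - t1 - phi)))) / 2
            # cartesian FFT grids are mildly anisotropic; allow a few deg
            assert math.degrees(err) < 4.0

    def test_direct_route_matches_fft_route(self, std_params, std_wiring,
                                            small_map):
        """Per-pixel closed-form spectra agree with FFT-based tuning."""
        _, lam_um = am.moire_geometry(std_params)
        grid = small_map.grid
        mosaic = make_hex_pair(std_params,
                               lam_um + wm.required_margin_um(std_wiring))
        y_ret = grid.retinal_positions_um(std_wiring)
        th = small_map.theta.ravel()
        osi = small_map.osi.ravel()
        idx = np.argsort(osi)[-12:]  # strongly tuned units
        checked = 0
        for i in idx:
            rf = wm.cortical_rf(mosaic, y_ret[i], std_wiring, n_px=96)
            t_fft, _, o_fft = wm.rf_tuning(rf, n_theta=90)
            err = abs(np.angle(np.exp(2j * (t_fft - th[i])))) / 2
            assert math.degrees(err) < 3.0
            assert o_fft == pytest.approx(osi[i], abs=0.1)
            checked += 1
        assert checked >= 3

    def test_margin_enforced(self, std_params, std_wiring):
        _, lam_um = am.moire_geometry(std_params)
        lam_mm = lam_um / 1000.0
        grid = wm.CorticalGrid.square(1.5 * lam_mm, 32.0 / lam_mm)
        small = make_hex_pair(std_params, 0.8 * lam_um)  # no margin
        with pytest.raises(ValueError):
            wm.compute_unfiltered_map(small, grid, std_wiring)


class TestThresholdAndSmooth:
    def test_identity_limit(self, small_map):
        out = wm.threshold_and_smooth(small_map, osi_threshold=0.0,
                                      kernel_sd_mm=0.0)
        assert np.allclose(out.z, small_map.z, atol=1e-12)

    def test_threshold_masks_weak_pixels(self, small_map):
        out = wm.threshold_and_smooth(small_map, osi_threshold=0.25,
                                      kernel_sd_mm=0.0)
        weak = small_map.osi <= 0.25
        assert np.all(out.z[weak] == 0.0)

    def test_smoothing_reduces_high_frequency_power(self, small_map,
                                                    std_params):
        _, lam_um = am.moire_geometry(std_params)
        lam_mm = lam_um / 1000.0
        sm = wm.threshold_and_smooth(small_map, 0.25,
                                     kernel_sd_mm=0.15 * lam_mm)
        thr = wm.threshold_and_smooth(small_map, 0.25, kernel_sd_mm=0.0)
        f_sm = np.abs(np.fft.fft2(sm.z))
        f_thr = np.abs(np.fft.fft2(thr.z))
        ny, nx = f_sm.shape
        hi = np.zeros((ny, nx), bool)
        hi[ny // 4: 3 * ny // 4, nx // 4: 3 * nx // 4] = True  # high |k|
        assert f_sm[hi].sum() < 0.2 * f_thr[hi].sum()

    def test_requires_unfiltered_stage(self, small_map):
        out = wm.threshold_and_smooth(small_map, 0.25, kernel_sd_mm=0.0)
        with pytest.raises(ValueError):
            wm.threshold_and_smooth(out, 0.25, kernel_sd_mm=0.0)

    def test_negative_kernel_rejected(self, small_map):
        with pytest.raises(ValueError):
            wm.threshold_and_smooth(small_map, 0.25, kernel_sd_mm=-1.0)

    def test_strongly_tuned_pixels_sit_between_opposite_polarities(
            self, std_params, std_wiring, small_map):
        """Surviving high-OSI pixels lie between ON-OFF cell pairs."""
        _, lam_um = am.moire_geometry(std_params)
        mosaic = make_hex_pair(std_params,
                               lam_um + wm.required_margin_um(std_wiring))
        y_ret = small_map.grid.retinal_positions_um(std_wiring)
        osi = small_map.osi.ravel()
        strong = np.flatnonzero(osi > 0.25)
        sign = np.where(mosaic.polarity == mo.ON, 1.0, -1.0)
        good = 0
        for i in strong:
            w = np.exp(-np.sum((mosaic.positions - y_ret[i]) ** 2, axis=1)
                       / (2 * std_wiring.sigma_s**2))
            top2 = np.argsort(w)[-2:]
            good += sign[top2[0]] * sign[top2[1]] < 0
        assert good / len(strong) > 0.9


def test_map_hdf5_round_trip(tmp_path, small_map):
    path = tmp_path / "map.h5"
    save_map(small_map, path)
    back = load_map(path)
    assert np.allclose(back.osi, small_map.osi)
    finite = np.isfinite(small_map.theta)
    assert np.array_equal(np.isfinite(back.theta), finite)
    assert np.allclose(back.theta[finite], small_map.theta[finite])
    assert back.stage == small_map.stage
    assert back.grid.pixel_size_mm == pytest.approx(
        small_map.grid.pixel_size_mm)
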