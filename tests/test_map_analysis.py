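"""Spectra, wavelets, pinwheel detection and layout statistics."""

import math

import numpy as np
import pytest

from moiremap import analytic_moire as am
from moiremap import map_analysis as ma


def plane_wave(k0, n=256, extent=10.0):
    px = extent / n
    xs = (np.arange(n) - n / 2) * px
    xg, yg = np.meshgrid(xs, xs)
    return np.exp(1j * (k0[0] * xg + k0[1] * yg)), px


def planted_zero_field(zeros, charges, n=128):
    """Product field with zeros of prescribed position (px) and charge.

    Charge +½ contributes a factor (w − w0), charge −½ its conjugate.
    """
    xs = np.arange(n)
    xg, yg = np.meshgrid(xs, xs)
    w = xg + 1j * yg
    z = np.ones((n, n), complex)
    for (x0, y0), q in zip(zeros, charges):
        factor = (w - (x0 + 1j * y0)) / n
        z = z * (factor if q > 0 else np.conj(factor))
    return z


# ---------------------------------------------------------------------------
# spectra

class TestSpectra:
    def test_plane_wave_single_peak(self):
        k0 = (2 * math.pi / 1.25, 0.0)
        z, px = plane_wave(k0)
        spec, kx, ky = ma.amplitude_spectrum(z, px)
        iy, ix = np.unravel_index(np.argmax(spec), spec.shape)
        assert kx[ix] == pytest.approx(k0[0], abs=2 * math.pi / 10.0)
        assert ky[iy] == pytest.approx(k0[1], abs=2 * math.pi / 10.0)

    def test_marginal_normalized_to_unit_max(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=(64, 64)) + 1j * rng.normal(size=(64, 64))
        spec, kx, ky = ma.amplitude_spectrum(z, 0.1)
        _, f = ma.marginal_spectrum(spec, kx, ky)
        assert f.max() == pytest.approx(1.0)

    def test_six_mode_layout_ring_peaks(self, std_params):
        field = am.six_mode_field(std_params)
        lam = field.lambda_c / 1000.0  # mm
        n = 256
        px = 8 * lam / n
        xs = (np.arange(n) - n / 2) * px * 1000.0
        grid = np.stack(np.meshgrid(xs, xs), axis=-1)
        z = field.evaluate(grid)
        spec, kx, ky = ma.amplitude_spectrum(z, px)
        kk = np.hypot(kx[None, :], ky[:, None])
        kc = 2 * math.pi / lam
        ring = np.abs(kk - kc) < 0.1 * kc
        outside = kk > 1.5 * kc
        assert spec[ring].max() > 20 * spec[outside].max()


class TestFermiBandpass:
    def test_passband_and_stopband_gains(self):
        for lam0, lo_gain in [(0.7, 0.95), (0.1, None)]:
            z, px = plane_wave((2 * math.pi / lam0, 0.0), n=512, extent=20.0)
            out = ma.fermi_bandpass(z, px, 0.3, 1.2)
            gain = np.abs(out).mean() / np.abs(z).mean()
            if lo_gain:
                assert gain >= lo_gain
            else:
                assert gain <= 0.05

    def test_constant_image_zeroed(self):
        img = np.full((128, 128), 3.7)
        out = ma.fermi_bandpass(img, 0.05, 0.3, 1.2)
        assert np.max(np.abs(out)) < 1e-10

    def test_invalid_cutoffs(self):
        img = np.zeros((64, 64))
        with pytest.raises(ValueError):
            ma.fermi_bandpass(img, 0.05, 1.2, 0.3)
        with pytest.raises(ValueError):
            ma.fermi_bandpass(img, 0.5, 0.3, 1.2)  # below Nyquist


# ---------------------------------------------------------------------------
# wavelet column spacing

class TestColumnSpacing:
    def test_plane_wave_recovery(self):
        lam0 = 1.3
        z, px = plane_wave((2 * math.pi / lam0 * math.cos(0.4),
                            2 * math.pi / lam0 * math.sin(0.4)),
                           n=400, extent=16.0)
        cfg = ma.WaveletConfig.around(1.2, n_scales=16, span=2.0)
        _, lam = ma.local_column_spacing(z, px, cfg)
        assert lam == pytest.approx(lam0, rel=0.03)

    def test_rotation_invariance(self):
        lam0 = 1.1
        cfg = ma.WaveletConfig.around(1.2, n_scales=16, span=2.0)
        ests = []
        for ang in (0.1, 1.0, 2.3):
            z, px = plane_wave((2 * math.pi / lam0 * math.cos(ang),
                                2 * math.pi / lam0 * math.sin(ang)),
                               n=400, extent=16.0)
            _, lam = ma.local_column_spacing(z, px, cfg)
            ests.append(lam)
        # 16 discrete wavelet orientations leave a small angular ripple
        assert np.ptp(ests) < 0.05 * lam0

    @pytest.mark.parametrize("dalpha_deg", [4.0, 7.0, 10.0])
    def test_six_mode_layout_recovers_lambda_c(self, dalpha_deg):
        d = math.radians(dalpha_deg)
        params = am.MoireParams(alpha=-d / 2, alpha_prime=d / 2)
        field = am.six_mode_field(params)
        lam_mm = field.lambda_c / 1000.0
        n = 320
        px = 10 * lam_mm / n
        xs = (np.arange(n) - n / 2) * px * 1000.0
        grid = np.stack(np.meshgrid(xs, xs), axis=-1)
        z = field.evaluate(grid)
        cfg = ma.WaveletConfig.around(lam_mm, n_scales=14, span=2.0)
        _, lam = ma.local_column_spacing(z, px, cfg)
        assert lam == pytest.approx(lam_mm, rel=0.05)

    def test_narrow_grid_warns(self):
        z, px = plane_wave((2 * math.pi / 2.2, 0.0), n=400, extent=16.0)
        cfg = ma.WaveletConfig(scales=np.geomspace(0.8, 1.2, 6))
        with pytest.warns(UserWarning):
            ma.local_column_spacing(z, px, cfg)


# ---------------------------------------------------------------------------
# pinwheel detection

class TestFindPinwheels:
    def test_single_positive_half_charge(self):
        n = 64
        xs = np.arange(n) - n / 2
        xg, yg = np.meshgrid(xs, xs)
        z = xg + 1j * yg
        pws = ma.find_pinwheels(z)
        assert len(pws) == 1
        assert pws.charges[0] == 0.5
        assert np.allclose(pws.positions[0], [n / 2, n / 2], atol=0.51)

    def test_conjugate_flips_charge(self):
        n = 64
        xs = np.arange(n) - n / 2
        xg, yg = np.meshgrid(xs, xs)
        pws = ma.find_pinwheels(np.conj(xg + 1j * yg))
        assert len(pws) == 1
        assert pws.charges[0] == -0.5

    @pytest.mark.parametrize("k", [1, 2, 10])
    def test_planted_zeros_recovered(self, k):
        rng = np.random.default_rng(k)
        n = 128
        zeros = rng.uniform(10, n - 10, (k, 2))
        # enforce pairwise separation so zeros stay resolvable
        while True:
            d = np.linalg.norm(zeros[None] - zeros[:, None], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() > 8:
                break
            zeros = rng.uniform(10, n - 10, (k, 2))
        charges = rng.choice([-0.5, 0.5], k)
        z = planted_zero_field(zeros, charges, n)
        pws = ma.find_pinwheels(z, merge_radius_px=0.0)
        assert len(pws) == k
        for (x0, y0), q in zip(zeros, charges):
            i = np.argmin(np.linalg.norm(pws.positions - [x0, y0], axis=1))
            assert np.linalg.norm(pws.positions[i] - [x0, y0]) <= 0.5
            assert pws.charges[i] == q

    def test_double_zero_merged_to_unit_charge(self):
        zeros = [(40.0, 40.0), (40.6, 40.4)]
        z = planted_zero_field(zeros, [0.5, 0.5], 96)
        pws = ma.find_pinwheels(z, merge_radius_px=2.0)
        assert len(pws) == 1
        assert pws.charges[0] == 1.0
        assert pws.low_confidence[0]

    def test_density_resolution_stable(self, std_params):
        """Crystalline-layout density changes < 1% from 32 to 128 px/Λ."""
        from moiremap import reproduce

        rhos = []
        for n_x in (128, 512):  # 32 and 128 px per Λ on the 4Λ-wide box
            rho, _ = reproduce.crystal_pinwheel_density(n_px=n_x)
            rhos.append(rho)
        assert abs(rhos[1] - rhos[0]) < 0.01 * rhos[0]

    def test_total_charge_zero_on_periodic_field(self, std_params):
        field = am.six_mode_field(std_params)
        lam = field.lambda_c
        lx, ly = 2 * lam, 2 * lam / math.sqrt(3.0)
        nx, ny = 192, 112
        xs = np.arange(nx) / nx * lx
        ys = np.arange(ny) / ny * ly
        z = field.evaluate(np.stack(np.meshgrid(xs, ys), axis=-1))
        pws = ma.find_pinwheels(z, pixel_size=(lx / nx, ly / ny),
                                periodic=True, spacing=lam)
        assert pws.charges.sum() == 0.0


# ---------------------------------------------------------------------------
# densities and statistics

def poisson_pinwheels(intensity, extent, seed):
    rng = np.random.default_rng(seed)
    n = rng.poisson(intensity * extent * extent)
    pos = rng.uniform(0, extent, (n, 2))
    charges = rng.choice([-0.5, 0.5], n)
    return ma.PinwheelSet(pos, charges, extent**2, 1.0)


class TestDensity:
    def test_poisson_density(self):
        lam_int = 3.0
        pws = poisson_pinwheels(lam_int, 40.0, seed=5)
        assert ma.pinwheel_density(pws) == pytest.approx(
            lam_int, abs=3 * math.sqrt(lam_int * 1600) / 1600)

    def test_rescaling_invariance(self):
        pws = poisson_pinwheels(3.0, 30.0, seed=7)
        scaled = ma.PinwheelSet(pws.positions * 2.5, pws.charges,
                                pws.region_area * 2.5**2,
                                pws.spacing * 2.5)
        assert ma.pinwheel_density(scaled) == pytest.approx(
            ma.pinwheel_density(pws))

    def test_unit_charges_count_twice(self):
        pos = np.array([[1.0, 1.0], [3.0, 3.0]])
        a = ma.PinwheelSet(pos, np.array([0.5, -0.5]), 16.0, 1.0)
        b = ma.PinwheelSet(pos, np.array([1.0, -1.0]), 16.0, 1.0)
        assert ma.pinwheel_density(b) == 2 * ma.pinwheel_density(a)

    def test_empty_region_rejected(self):
        pws = ma.PinwheelSet(np.empty((0, 2)), np.empty(0), 0.0, 1.0)
        with pytest.raises(ValueError):
            ma.pinwheel_density(pws)


class TestDensityVariability:
    def test_poisson_exponent_and_coefficient(self):
        """SD(A) = √ρ·A^{−1/2} for Poisson: γ = 0.5, c = 1/√ρ."""
        rho = 3.0
        gammas, cs = [], []
        for seed in range(5):
            pws = poisson_pinwheels(rho, 50.0, seed=seed)
            _, _, g, c = ma.density_variability(
                pws, (0, 50, 0, 50), areas=np.geomspace(1, 64, 12),
                n_samples=200, seed=seed)
            gammas.append(g)
            cs.append(c)
        assert np.mean(gammas) == pytest.approx(0.5, abs=0.05)
        assert np.mean(cs) == pytest.approx(1 / math.sqrt(rho), rel=0.15)

    def test_seeded_sampling_reproducible(self):
        pws = poisson_pinwheels(3.0, 40.0, seed=3)
        a = ma.density_variability(pws, (0, 40, 0, 40), n_samples=50, seed=9)
        b = ma.density_variability(pws, (0, 40, 0, 40), n_samples=50, seed=9)
        assert np.array_equal(a[1], b[1])

    def test_oversized_areas_rejected(self):
        pws = poisson_pinwheels(3.0, 10.0, seed=1)
        with pytest.raises(ValueError):
            ma.density_variability(pws, (0, 10, 0, 10),
                                   areas=np.array([1.0, 50.0]))


class TestNNDistances:
    def test_any_is_min_over_classes(self):
        pws = poisson_pinwheels(3.0, 25.0, seed=11)
        d_any = ma.nn_distances(pws, "any")
        d_same = ma.nn_distances(pws, "same")
        d_opp = ma.nn_distances(pws, "opposite")
        assert np.all(d_any <= np.minimum(d_same, d_opp) + 1e-12)

    def test_two_pinwheels_symmetric(self):
        pws = ma.PinwheelSet(np.array([[0.0, 0.0], [3.0, 4.0]]),
                             np.array([0.5, -0.5]), 100.0, 1.0)
        d = ma.nn_distances(pws, "any")
        assert np.allclose(d, 5.0)

    def test_histogram_unit_mass(self):
        pws = poisson_pinwheels(3.0, 25.0, seed=13)
        _, masses = ma.nn_histogram(ma.nn_distances(pws, "any"))
        assert masses.sum() == pytest.approx(1.0)

    def test_insufficient_pinwheels_rejected(self):
        pws = ma.PinwheelSet(np.array([[0.0, 0.0]]), np.array([0.5]),
                             10.0, 1.0)
        with pytest.raises(ValueError):
            ma.nn_distances(pws, "any")


# ---------------------------------------------------------------------------
# map comparison

class TestComparison:
    def test_identical_maps(self):
        rng = np.random.default_rng(17)
        th = rng.uniform(0, math.pi, (32, 32))
        d, frac = ma.circular_difference(th, th)
        assert np.allclose(d, 0.0)
        assert frac == 0.0
        assert ma.theta_cross_correlation(th, th) == pytest.approx(1.0)

    def test_orthogonal_maps(self):
        rng = np.random.default_rng(19)
        th = rng.uniform(0, math.pi, (32, 32))
        shifted = np.mod(th + math.pi / 2, math.pi)
        d, frac = ma.circular_difference(th, shifted)
        assert np.allclose(d, 90.0)
        assert frac == 1.0
        assert ma.theta_cross_correlation(th, shifted) == pytest.approx(-1.0)

    def test_constant_map_rejected(self):
        z = np.ones((16, 16), complex)
        with pytest.raises(ValueError):
            ma.map_cross_correlation(z, z)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ma.circular_difference(np.zeros((8, 8)), np.zeros((9, 9)))
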