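import math

import numpy as np
import pytest

from moiremap import analytic_moire, mosaics, wiring_model


@pytest.fixture(scope="session")
def std_params() -> analytic_moire.MoireParams:
    """Standard geometry: r = r' = 170 μm, Δα = 7° split symmetrically."""
    d = math.radians(7.0)
    return analytic_moire.MoireParams(
        r=170.0, r_prime=170.0, alpha=-d / 2.0, alpha_prime=d / 2.0,
        sigma_r=70.0, sigma_s=20.0,
    )


@pytest.fixture(scope="session")
def std_wiring() -> wiring_model.WiringParams:
    return wiring_model.WiringParams(sigma_r=70.0, sigma_s=20.0)


def make_hex_pair(params, half_extent_um):
    return mosaics.hexagonal_pair(
        params.r, params.r_prime, params.alpha, params.alpha_prime,
        mosaics.Rect.centered(2.0 * half_extent_um),
    )


@pytest.fixture(scope="session")
def small_map(std_params, std_wiring):
    """Unfiltered model map over 2×2 Λ_c at 32 px/Λ, reused across tests."""
    _, lam_um = analytic_moire.moire_geometry(std_params)
    lam_mm = lam_um / 1000.0
    grid = wiring_model.CorticalGrid.square(2.0 * lam_mm, 32.0 / lam_mm)
    half = lam_um + wiring_model.required_margin_um(std_wiring)
    mosaic = make_hex_pair(std_params, half)
    return wiring_model.compute_unfiltered_map(mosaic, grid, std_wiring)


def brute_force_rf(mosaic, y, x_points, sigma_r, sigma_s):
    """Direct evaluation of the wiring-model lattice sum (test oracle)."""
    y = np.asarray(y, float)
    w = np.exp(-np.sum((mosaic.positions - y) ** 2, axis=1)
               / (2.0 * sigma_s**2))
    sign = np.where(mosaic.polarity == mosaics.ON, 1.0, -1.0)
    out = np.zeros(len(x_points))
    for pos, ww, ss in zip(mosaic.positions, w, sign):
        out += ss * ww * np.exp(-np.sum((x_points - pos) ** 2, axis=1)
                                / (2.0 * sigma_r**2))
    return out


def brute_force_spectrum(mosaic, y, k_points, sigma_r, sigma_s):
    """Direct receptive-field Fourier transform (test oracle)."""
    y = np.asarray(y, float)
    w = np.exp(-np.sum((mosaic.positions - y) ** 2, axis=1)
               / (2.0 * sigma_s**2))
    sign = np.where(mosaic.polarity == mosaics.ON, 1.0, -1.0)
    k2 = np.sum(np.asarray(k_points) ** 2, axis=1)
    out = np.zeros(len(k_points), complex)
    for pos, ww, ss in zip(mosaic.positions, w, sign):
        out += ss * ww * np.exp(-1j * (np.asarray(k_points) @ pos))
    return sigma_r**2 * np.exp(-0.5 * sigma_r**2 * k2) * out
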