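"""Gaussian-random-field orientation-map ensembles and band-pass layouts.

Broadband layouts (e.g. from PIPP mosaics) acquire a typical column spacing
only after band-pass filtering.  The flexible filter family used here is

    f(k) = a |k|^β exp(−k²/b),        a, b > 0, β ≥ 0,

a Gaussian low-pass at β = 0 narrowing to a ring spectrum as β grows.  The
filter fixes its own length unit through the double normalization

    ∫₀^∞ f(k) dk = 1   and   k̄ = ∫₀^∞ k f(k) dk = 1
    (equivalently ∫ f(k) d²k = 2π),

so the mean column spacing of a layout with radial spectral profile ``f``
is Λ = 2π/k̄ = 2π in filter units; a physical Λ in mm rescales ``k``.
Both conditions are solved in closed form via Gamma-function moments:
``√b = Γ((β+1)/2) / Γ((β+2)/2)`` and ``a = 2 b^{−(β+1)/2} / Γ((β+1)/2)``.

Complex Gaussian random fields with this spectral profile serve as the
null model for "random" orientation maps; their pinwheel density per Λ²
decreases monotonically with β toward the narrow-band limit π.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from . import map_analysis
from .wiring_model import CorticalGrid, TuningMap

__all__ = [
    "SpectralFilter",
    "make_power_filter",
    "make_fermi_filter",
    "grf_sample",
    "grf_pinwheel_density",
    "grf_density_surface",
    "pipp_layout_bandpass",
    "narrowband_density_limit",
]


@dataclass(frozen=True)
class SpectralFilter:
    """Radially symmetric spectral filter with its normalization contract.

    ``family`` is ``power_gaussian`` (the |k|^β·Gaussian family above) or
    ``fermi_band`` (two Fermi steps in wavelength).  ``lambda_mm`` fixes the
    physical scale: for the power family the filter-unit wavenumber
    ``k̄ = 1`` corresponds to ``2π/lambda_mm`` rad/mm.
    """

    family: str
    lambda_mm: float
    beta: float = 0.0
    a: float = math.nan
    b: float = math.nan
    low_cut_mm: float = math.nan
    high_cut_mm: float = math.nan
    steepness_frac: float = 0.05

    def profile(self, k_filter_units: np.ndarray) -> np.ndarray:
        """Evaluate ``f`` at |k| in filter units (power family only)."""
        if self.family != "power_gaussian":
            raise ValueError("profile() applies to the power_gaussian family")
        k = np.asarray(k_filter_units, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = self.a * k**self.beta * np.exp(-(k**2) / self.b)
        if self.beta == 0:
            return np.where(np.isfinite(out), out, self.a)
        return np.nan_to_num(out)

    def gain_mm(self, k_rad_per_mm: np.ndarray) -> np.ndarray:
        """Filter gain at physical wavenumber |k| (rad/mm)."""
        if self.family == "power_gaussian":
            return self.profile(np.asarray(k_rad_per_mm)
                                * self.lambda_mm / (2.0 * math.pi))
        k = np.asarray(k_rad_per_mm, dtype=float)
        with np.errstate(divide="ignore"):
            lam = np.where(k > 0, 2.0 * math.pi / np.maximum(k, 1e-300),
                           np.inf)
        return (
            1.0 / (1.0 + np.exp((self.low_cut_mm - lam)
                                / (self.steepness_frac * self.low_cut_mm)))
            / (1.0 + np.exp((lam - self.high_cut_mm)
                            / (self.steepness_frac * self.high_cut_mm)))
        )


def make_power_filter(beta: float, lambda_mm: float = 1.0) -> SpectralFilter:
    """Normalized |k|^β·Gaussian filter; see the module docstring.

    The closed-form normalization makes ``∫ f d²k = 2π`` and the mean
    wavenumber ``k̄ = 1`` hold exactly.
    """
    if beta < 0:
        raise ValueError("beta must be >= 0")
    sqrt_b = math.exp(gammaln((beta + 1.0) / 2.0) - gammaln((beta + 2.0) / 2.0))
    b = sqrt_b**2
    a = 2.0 * math.exp(
        -((beta + 1.0) / 2.0) * math.log(b) - gammaln((beta + 1.0) / 2.0)
    )
    return SpectralFilter(family="power_gaussian", lambda_mm=lambda_mm,
                          beta=beta, a=a, b=b)


def make_fermi_filter(low_cut_mm: float = 0.3, high_cut_mm: float = 1.2,
                      lambda_mm: float = 1.0,
                      steepness_frac: float = 0.05) -> SpectralFilter:
    """Fermi band-pass between cutoff wavelengths (mm)."""
    if not 0 < low_cut_mm < high_cut_mm:
        raise ValueError("need 0 < low_cut < high_cut")
    return SpectralFilter(family="fermi_band", lambda_mm=lambda_mm,
                          low_cut_mm=low_cut_mm, high_cut_mm=high_cut_mm,
                          steepness_frac=steepness_frac)


# ---------------------------------------------------------------------------
# sampling

def grf_sample(
    filt: SpectralFilter,
    n_px: int = 512,
    extent_lambda: float = 22.0,
    seed=None,
) -> tuple[np.ndarray, float]:
    """Sample a complex Gaussian random field with spectral power ``f``.

    Independent complex Gaussian Fourier amplitudes are shaped by ``√f(|k|)``
    and inverse-transformed, so the ensemble power spectrum equals the
    filter profile.  Returns ``(z, pixel_size_lambda)`` where the field
    covers ``extent_lambda`` column spacings per axis.
    """
    if filt.family != "power_gaussian":
        raise ValueError("grf_sample draws from the power_gaussian family")
    lam_units = 2.0 * math.pi  # Λ in filter units
    pixel = extent_lambda * lam_units / n_px
    k1 = 2.0 * math.pi * np.fft.fftfreq(n_px, d=pixel)
    kk = np.hypot(k1[None, :], k1[:, None])
    # spectral support: ring at sqrt(beta*b/2) plus a few Gaussian widths
    kmax_support = (math.sqrt(filt.b * filt.beta / 2.0)
                    + 3.5 * math.sqrt(filt.b / 2.0))
    if k1.max() < kmax_support * 0.8:
        raise ValueError("grid Nyquist does not cover the filter support")
    power = filt.profile(kk)
    rng = np.random.default_rng(seed)
    amp = (rng.normal(size=kk.shape) + 1j * rng.normal(size=kk.shape))
    z = np.fft.ifft2(amp * np.sqrt(power))
    rms = np.sqrt(np.mean(np.abs(z) ** 2))
    if rms > 0:
        z = z / rms
    return z, pixel / lam_units


def grf_pinwheel_density(z: np.ndarray, pixel_size_lambda: float) -> float:
    """Pinwheel density per Λ² of a periodic GRF sample."""
    pws = map_analysis.find_pinwheels(
        z, pixel_size=pixel_size_lambda, spacing=1.0, periodic=True,
        merge_radius_px=0.0,
    )
    return map_analysis.pinwheel_density(pws)


def grf_density_surface(
    betas,
    lambdas_mm,
    n_realizations: int = 20,
    seed=None,
    n_px: int = 512,
    extent_lambda: float = 22.0,
) -> pd.DataFrame:
    """Mean ± SEM pinwheel density of GRF layouts over a (β, Λ) grid.

    Densities are measured per Λ² with Λ taken from the filter definition,
    so they are invariant under the physical scale Λ_mm by construction of
    the sampling grid; the Λ column is carried to make that invariance
    checkable.
    """
    betas = np.atleast_1d(np.asarray(betas, dtype=float))
    lambdas_mm = np.atleast_1d(np.asarray(lambdas_mm, dtype=float))
    if betas.size == 0 or lambdas_mm.size == 0:
        raise ValueError("beta and lambda grids must be non-empty")
    ss = np.random.SeedSequence(seed)
    rows = []
    for beta in betas:
        for lam in lambdas_mm:
            filt = make_power_filter(beta, lam)
            dens = np.empty(n_realizations)
            for i, child in enumerate(ss.spawn(n_realizations)):
                z, px = grf_sample(filt, n_px=n_px,
                                   extent_lambda=extent_lambda, seed=child)
                dens[i] = grf_pinwheel_density(z, px)
            rows.append({
                "beta": float(beta),
                "lambda_mm": float(lam),
                "rho_mean": float(dens.mean()),
                "rho_sem": float(dens.std(ddof=1) / math.sqrt(n_realizations))
                if n_realizations > 1 else math.nan,
                "n": n_realizations,
            })
    return pd.DataFrame(rows)


def narrowband_density_limit() -> float:
    """Theoretical pinwheel density of a narrow-ring-spectrum GRF: π."""
    return math.pi


# ---------------------------------------------------------------------------
# band-pass post-processing of broadband model layouts

def _radial_average(values: np.ndarray, kk: np.ndarray,
                    n_bins: int = 64) -> np.ndarray:
    """Annulus-average ``values`` over |k| and broadcast back to the grid."""
    kmax = kk.max()
    idx = np.minimum((kk / kmax * n_bins).astype(int), n_bins - 1)
    sums = np.bincount(idx.ravel(), weights=values.ravel(), minlength=n_bins)
    counts = np.bincount(idx.ravel(), minlength=n_bins)
    prof = sums / np.maximum(counts, 1)
    return prof[idx]


def pipp_layout_bandpass(tmap: TuningMap, filt: SpectralFilter,
                         shaping: str = "match") -> TuningMap:
    """Apply a spectral filter to a broadband (e.g. PIPP-derived) layout.

    The complex field ``z`` of the thresholded stage is multiplied in the
    Fourier domain by the filter gain and renormalized to unit peak
    modulus; the result carries stage ``smoothed``.

    For the power_gaussian family the default ``shaping="match"`` imposes
    the filter as the layout's radial power profile: the input spectrum is
    whitened by its own annulus-averaged power and then shaped by ``√f``,
    so the filtered field carries power spectral profile ``f`` exactly —
    the same convention as :func:`grf_sample`, making filtered-layout and
    GRF pinwheel densities directly comparable (the comparison then probes
    the phase statistics of the layout).  ``shaping="sqrt"`` applies ``√f``
    without whitening (adequate where the input spectrum is flat);
    ``shaping="direct"`` multiplies by the gain itself (appropriate for
    transfer-function filters such as the Fermi band; always used for that
    family).
    """
    if shaping not in ("match", "sqrt", "direct"):
        raise ValueError("shaping must be 'match', 'sqrt' or 'direct'")
    z = tmap.z
    px_mm = tmap.grid.pixel_size_mm
    k1y = 2.0 * math.pi * np.fft.fftfreq(z.shape[0], d=px_mm)
    k1x = 2.0 * math.pi * np.fft.fftfreq(z.shape[1], d=px_mm)
    kk = np.hypot(k1x[None, :], k1y[:, None])
    gain = filt.gain_mm(kk)
    fz = np.fft.fft2(z)
    if filt.family == "power_gaussian":
        if shaping == "match":
            power_in = _radial_average(np.abs(fz) ** 2, kk)
            gain = np.sqrt(gain / np.maximum(power_in, 1e-30))
        elif shaping == "sqrt":
            gain = np.sqrt(gain)
    gain.flat[0] = 0.0
    out = np.fft.ifft2(fz * gain)
    peak = np.abs(out).max()
    if peak > 0:
        out = out / peak
    return TuningMap.from_z(out, tmap.grid, stage="smoothed",
                            meta={**tmap.meta, "bandpass": filt.family,
                                  "bandpass_lambda_mm": filt.lambda_mm,
                                  "bandpass_beta": filt.beta})
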