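"""Numerical statistical-wiring model: receptive fields, tuning, maps.

A model V1 neuron at cortical position ``y`` pools RGC center inputs with
Gaussian synaptic weights ``w_j(y) = exp(−(x_j − y)²/2σ_s²)``; each RGC
contributes a Gaussian receptive field of width ``σ_r`` with its polarity
sign::

    RF_y(x) = Σ_j ± w_j(y) · exp(−(x_j − x)²/2σ_r²)

Under the linear response assumption, the response to a drifting grating is
the receptive-field amplitude spectrum, from which preferred orientation,
preferred spatial frequency and orientation selectivity (OSI) are extracted.
Orientation angles follow the *edge* convention: a neuron dominated by a
single ON–OFF dipole prefers the edge orientation perpendicular to the
dipole axis.

Retinal coordinates are μm; cortical maps are in mm with a configurable
retino-cortical magnification (default 1 mm cortex per mm retina).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .mosaics import ON, Rect, RGCMosaic

__all__ = [
    "WiringParams",
    "CorticalGrid",
    "ReceptiveField",
    "TuningMap",
    "required_margin_um",
    "cortical_rf",
    "rf_tuning",
    "compute_unfiltered_map",
    "threshold_and_smooth",
]


@dataclass(frozen=True)
class WiringParams:
    """Receptive-field width ``σ_r``, sampling range ``σ_s`` (both μm) and
    retino-cortical magnification (mm cortex per mm retina)."""

    sigma_r: float = 70.0
    sigma_s: float = 20.0
    magnification: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_r <= 0 or self.sigma_s <= 0:
            raise ValueError("sigma_r and sigma_s must be positive")
        if self.magnification <= 0:
            raise ValueError("magnification must be positive")


@dataclass(frozen=True)
class CorticalGrid:
    """Regular pixel grid on the cortical sheet.

    ``nx × ny`` pixels of size ``pixel_size_mm``, centered on the origin.
    ``x_mm``/``y_mm`` give pixel-center coordinates; retinal positions are
    obtained through the magnification factor of the wiring parameters.
    """

    nx: int
    ny: int
    pixel_size_mm: float

    def __post_init__(self) -> None:
        if self.nx < 2 or self.ny < 2 or self.pixel_size_mm <= 0:
            raise ValueError("grid needs >= 2 pixels per axis, positive pixel")

    @classmethod
    def square(cls, extent_mm: float, px_per_mm: float) -> "CorticalGrid":
        n = int(round(extent_mm * px_per_mm))
        return cls(nx=n, ny=n, pixel_size_mm=1.0 / px_per_mm)

    @property
    def x_mm(self) -> np.ndarray:
        return (np.arange(self.nx) - (self.nx - 1) / 2.0) * self.pixel_size_mm

    @property
    def y_mm(self) -> np.ndarray:
        return (np.arange(self.ny) - (self.ny - 1) / 2.0) * self.pixel_size_mm

    @property
    def extent_mm(self) -> Rect:
        return Rect(self.x_mm[0], self.x_mm[-1], self.y_mm[0], self.y_mm[-1])

    def pixel_centers_mm(self) -> np.ndarray:
        xg, yg = np.meshgrid(self.x_mm, self.y_mm)
        return np.stack([xg.ravel(), yg.ravel()], axis=-1)

    def retinal_positions_um(self, params: WiringParams) -> np.ndarray:
        return self.pixel_centers_mm() / params.magnification * 1000.0


@dataclass
class ReceptiveField:
    """Signed scalar receptive field on a retinal grid (μm)."""

    values: np.ndarray
    xs_um: np.ndarray
    ys_um: np.ndarray
    center_um: np.ndarray
    params: WiringParams

    @property
    def pixel_um(self) -> float:
        return float(self.xs_um[1] - self.xs_um[0])


@dataclass
class TuningMap:
    """Per-pixel orientation tuning on a cortical grid.

    ``theta`` ∈ [0, π) (NaN where undefined), ``osi`` ∈ [0, 1], ``kpref`` in
    rad/μm (retinal spatial frequency).  ``stage`` is one of ``unfiltered``,
    ``thresholded``, ``smoothed`` (or the ``analytic_*``/``grf`` labels of
    the closed-form and random-field layouts).  The complex view is
    ``z = OSI·e^{2iθ}`` with ``z = 0`` where orientation is undefined.
    """

    theta: np.ndarray
    osi: np.ndarray
    kpref: np.ndarray
    grid: CorticalGrid
    stage: str = "unfiltered"
    valid_mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.theta)
        osi_ok = self.osi[np.isfinite(self.osi)]
        if osi_ok.size and (osi_ok.min() < -1e-9 or osi_ok.max() > 1 + 1e-9):
            raise ValueError("OSI must lie in [0, 1]")

    @property
    def z(self) -> np.ndarray:
        out = self.osi * np.exp(2j * np.where(np.isfinite(self.theta),
                                              self.theta, 0.0))
        return np.where(self.valid_mask, out, 0.0)

    @classmethod
    def from_z(cls, z: np.ndarray, grid: CorticalGrid, stage: str,
               kpref: np.ndarray | None = None, meta: dict | None = None,
               valid_mask: np.ndarray | None = None) -> "TuningMap":
        osi = np.abs(z)
        theta = np.where(osi > 0, np.mod(0.5 * np.angle(z), math.pi), np.nan)
        if kpref is None:
            kpref = np.full(z.shape, np.nan)
        return cls(theta=theta, osi=osi, kpref=kpref, grid=grid, stage=stage,
                   valid_mask=valid_mask, meta=meta or {})

    def interior_mask(self, margin_mm: float) -> np.ndarray:
        """True for pixels at least ``margin_mm`` from the map edge."""
        x = self.grid.x_mm
        y = self.grid.y_mm
        gx = (x >= x[0] + margin_mm) & (x <= x[-1] - margin_mm)
        gy = (y >= y[0] + margin_mm) & (y <= y[-1] - margin_mm)
        return gy[:, None] & gx[None, :]


# ---------------------------------------------------------------------------
# receptive fields

def required_margin_um(params: WiringParams) -> float:
    """Mosaic margin beyond the analysis window: ``4σ_s + 3σ_r``.

    Cells farther than this from a cortical unit contribute weights below
    ~1e-8 relative, bounding truncation error of the lattice sum.
    """
    return 4.0 * params.sigma_s + 3.0 * params.sigma_r


def cortical_rf(
    mosaic: RGCMosaic,
    y_um,
    params: WiringParams,
    window: Rect | None = None,
    n_px: int = 96,
    weight_tol: float = 1e-10,
) -> ReceptiveField:
    """Numerical receptive field of the unit at retinal position ``y_um``.

    The field is evaluated on an ``n_px²`` grid covering ``window`` (default
    a square of half-side ``3σ_r + 5σ_s`` around ``y``, on which the field
    decays below 1e-8 of its peak).  Cells with weight below ``weight_tol``
    are dropped.
    """
    y = np.asarray(y_um, dtype=float)
    half = 3.0 * params.sigma_r + 5.0 * params.sigma_s
    if window is None:
        window = Rect(y[0] - half, y[0] + half, y[1] - half, y[1] + half)
    if window.width < 2 * params.sigma_r or window.height < 2 * params.sigma_r:
        raise ValueError("window too small to contain the receptive field")
    if not mosaic.extent.pad(1e-6).contains(
        np.array([[window.xmin, window.ymin], [window.xmax, window.ymax]])
    ).all():
        raise ValueError(
            "mosaic extent does not cover the receptive-field window; "
            "generate the mosaic with a margin"
        )
    w = np.exp(
        -np.sum((mosaic.positions - y) ** 2, axis=1) / (2 * params.sigma_s**2)
    )
    sign = np.where(mosaic.polarity == ON, 1.0, -1.0)
    keep = w > weight_tol
    xs = np.linspace(window.xmin, window.xmax, n_px)
    ys = np.linspace(window.ymin, window.ymax, n_px)
    xg, yg = np.meshgrid(xs, ys)
    vals = np.zeros((n_px, n_px))
    for pos, ww, ss in zip(mosaic.positions[keep], w[keep], sign[keep]):
        vals += ss * ww * np.exp(
            -((xg - pos[0]) ** 2 + (yg - pos[1]) ** 2) / (2 * params.sigma_r**2)
        )
    return ReceptiveField(values=vals, xs_um=xs, ys_um=ys, center_um=y,
                          params=params)


# ---------------------------------------------------------------------------
# tuning extraction

K_METHODS = ("maximum", "center_of_mass", "cv_max")


def _polar_tc(spec_abs, kx, ky, n_theta: int, n_k: int):
    """Resample |R(k)| to a polar (θ ∈ [0, π), k > 0) tuning-curve grid."""
    kmax = 0.75 * min(kx.max(), ky.max())
    k_r = np.linspace(kmax / n_k, kmax, n_k)
    th = np.arange(n_theta) * math.pi / n_theta
    kxs = k_r[None, :] * np.cos(th)[:, None]
    kys = k_r[None, :] * np.sin(th)[:, None]
    itp = RegularGridInterpolator((ky, kx), spec_abs, bounds_error=False,
                                  fill_value=0.0)
    tc = itp(np.stack([kys.ravel(), kxs.ravel()], axis=-1)).reshape(n_theta, n_k)
    return th, k_r, tc


def _tuning_from_tc(th, k_r, tc, k_method: str):
    """Preferred orientation / frequency / OSI from a polar tuning surface.

    ``tc[m, n] = TC(θ_m, k_n)``; the underlying RF is real so the spectrum
    is inversion symmetric and θ ∈ [0, π) samples the full circle.
    """
    # spectral center of mass of the second angular harmonic (d²k = k dk dθ)
    e2 = np.exp(2j * th)[:, None]
    mu = np.sum(tc * k_r[None, :] ** 2 * e2) / max(np.sum(tc * k_r[None, :]),
                                                   1e-300)
    if k_method == "maximum":
        m_idx, n_idx = np.unravel_index(np.argmax(tc), tc.shape)
        k_pref = k_r[n_idx]
    elif k_method == "center_of_mass":
        k_pref = float(np.abs(mu))
        n_idx = int(np.argmin(np.abs(k_r - k_pref)))
    elif k_method == "cv_max":
        ring_tot = np.sum(tc, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            cv = np.abs(np.sum(tc * e2, axis=0)) / np.maximum(ring_tot,
                                                              1e-300)
        # frequencies with negligible response carry no usable CV
        cv[ring_tot < 1e-4 * ring_tot.max()] = -1.0
        n_idx = int(np.argmax(cv))
        k_pref = k_r[n_idx]
    else:
        raise ValueError(f"unknown k_method {k_method!r}; use one of "
                         f"{K_METHODS}")
    ring = tc[:, n_idx]
    denom = ring.sum()
    osi = float(np.abs(np.sum(ring * e2[:, 0])) / denom) if denom > 0 else 0.0
    theta_pref = math.nan
    if np.abs(mu) > 1e-12 * max(np.max(tc), 1e-300) and osi > 1e-12:
        theta_pref = (0.5 * np.angle(mu) + 0.5 * math.pi) % math.pi
    return theta_pref, float(k_pref), min(osi, 1.0)


def rf_tuning(rf: ReceptiveField, k_method: str = "maximum",
              n_theta: int = 36, n_k: int = 48):
    """Extract ``(θ_pref, k_pref, OSI)`` from a receptive field's spectrum.

    The amplitude spectrum is the |FFT| of the field; the preferred angle is
    half the phase of its second angular harmonic center of mass (plus π/2,
    edge convention), ``k_pref`` by one of three estimators:

    ``maximum``
        location of the spectral maximum (default; invariant under monotone
        output nonlinearities),
    ``cv_max``
        spatial frequency maximizing the circular variance of the tuning
        curve,
    ``center_of_mass``
        modulus of the spectral center of mass (systematically smaller for
        two-lobed spectra).

    OSI is the normalized second angular harmonic of the tuning curve at
    ``k_pref``.  A rotationally symmetric field returns OSI 0 with θ = NaN;
    an all-zero field raises ``ValueError``.
    """
    vals = np.asarray(rf.values, dtype=float)
    if not np.any(vals):
        raise ValueError("tuning undefined for an all-zero receptive field")
    spec = np.abs(np.fft.fftshift(np.fft.fft2(vals)))
    ky = 2 * math.pi * np.fft.fftshift(np.fft.fftfreq(vals.shape[0],
                                                      d=rf.pixel_um))
    kx = 2 * math.pi * np.fft.fftshift(np.fft.fftfreq(vals.shape[1],
                                                      d=rf.pixel_um))
    th, k_r, tc = _polar_tc(spec, kx, ky, n_theta, n_k)
    return _tuning_from_tc(th, k_r, tc, k_method)


# ---------------------------------------------------------------------------
# whole-map computation

def compute_unfiltered_map(
    mosaic: RGCMosaic,
    grid: CorticalGrid,
    params: WiringParams,
    *,
    k_method: str = "maximum",
    n_theta: int = 12,
    n_k: int = 16,
    k_max: float | None = None,
    neighbor_cut_sigmas: float = 5.5,
) -> TuningMap:
    """Per-pixel tuning map of the wiring model (stage ``unfiltered``).

    For every grid pixel the receptive-field amplitude spectrum is evaluated
    in closed form on a polar grid directly from the contributing RGCs
    (cells within ``neighbor_cut_sigmas · σ_s``):  since each RGC field is
    Gaussian, ``|R_y(k)| = σ_r² e^{−k²(σ_r²+σ_s²)/2} |Σ_j ± w_j e^{−i k·x_j}|``
    exactly, so no per-pixel FFT is needed.  Tuning extraction is identical
    to :func:`rf_tuning` (``θ`` from the spectral center of mass, ``k_pref``
    by the chosen estimator, OSI on the preferred ring).

    The mosaic must extend beyond the map's retinal footprint by
    :func:`required_margin_um`.
    """
    y_ret = grid.retinal_positions_um(params)  # (P, 2)
    need = Rect(
        y_ret[:, 0].min(), y_ret[:, 0].max(),
        y_ret[:, 1].min(), y_ret[:, 1].max(),
    ).pad(required_margin_um(params))
    ext = mosaic.extent
    if (ext.xmin > need.xmin or ext.xmax < need.xmax
            or ext.ymin > need.ymin or ext.ymax < need.ymax):
        raise ValueError(
            "mosaic does not cover the cortical window plus the decay margin"
        )
    sig2 = params.sigma_r**2 + params.sigma_s**2
    if k_max is None:
        k_max = 3.5 / math.sqrt(sig2)
    th = np.arange(n_theta) * math.pi / n_theta
    dirs = np.stack([np.cos(th), np.sin(th)], axis=1)  # (n_theta, 2)
    k_r = np.linspace(k_max / n_k, k_max, n_k)
    env = np.exp(-0.5 * k_r**2 * sig2)  # σ_r² prefactor cancels in all ratios

    tree = cKDTree(mosaic.positions)
    r_cut = neighbor_cut_sigmas * params.sigma_s
    neighbors = tree.query_ball_point(y_ret, r_cut)
    counts = np.fromiter((len(nb) for nb in neighbors), int, len(neighbors))
    sign_all = np.where(mosaic.polarity == ON, 1.0, -1.0)

    P = len(y_ret)
    theta_map = np.full(P, np.nan)
    osi_map = np.zeros(P)
    kpref_map = np.full(P, np.nan)
    e2 = np.exp(2j * th)

    for n_nb in np.unique(counts):
        idx = np.flatnonzero(counts == n_nb)
        if n_nb == 0:
            continue
        nb = np.array([neighbors[i] for i in idx])            # (G, n_nb)
        rel = mosaic.positions[nb] - y_ret[idx][:, None, :]    # (G, n_nb, 2)
        w = (np.exp(-np.sum(rel**2, axis=2) / (2 * params.sigma_s**2))
             * sign_all[nb])                                   # (G, n_nb)
        x_abs = mosaic.positions[nb]                           # (G, n_nb, 2)
        phase = np.tensordot(x_abs, dirs, axes=([2], [1]))     # (G, n_nb, n_theta)
        for chunk in np.array_split(np.arange(len(idx)),
                                    max(1, len(idx) * n_nb * n_theta * n_k
                                        // 4_000_000)):
            ph = phase[chunk]                                  # (g, n_nb, n_theta)
            ww = w[chunk]
            # TC(g, θ, k) = env(k) |Σ_j w_j e^{−i k φ_j}|
            arg = ph[..., None] * k_r                          # (g, nb, θ, k)
            amp = np.einsum("gn,gntk->gtk", ww, np.cos(arg)) \
                - 1j * np.einsum("gn,gntk->gtk", ww, np.sin(arg))
            tc = np.abs(amp) * env                             # (g, θ, k)
            tot = np.einsum("gtk,k->g", tc, k_r)
            mu = np.einsum("gtk,k,t->g", tc, k_r**2, e2) / np.maximum(tot,
                                                                      1e-300)
            if k_method == "maximum":
                flat = tc.reshape(len(chunk), -1)
                n_idx = np.argmax(flat, axis=1) % n_k
            elif k_method == "center_of_mass":
                n_idx = np.argmin(np.abs(k_r[None, :] - np.abs(mu)[:, None]),
                                  axis=1)
            elif k_method == "cv_max":
                ring_tot = tc.sum(axis=1)
                cv = np.abs(np.einsum("gtk,t->gk", tc, e2)) / np.maximum(
                    ring_tot, 1e-300)
                cv[ring_tot < 1e-4 * ring_tot.max(axis=1, keepdims=True)] \
                    = -1.0
                n_idx = np.argmax(cv, axis=1)
            else:
                raise ValueError(f"unknown k_method {k_method!r}")
            ring = np.take_along_axis(tc, n_idx[:, None, None], axis=2)[..., 0]
            denom = np.maximum(ring.sum(axis=1), 1e-300)
            osi = np.abs(ring @ e2) / denom
            gi = idx[chunk]
            osi_map[gi] = np.minimum(osi, 1.0)
            kpref_map[gi] = k_r[n_idx]
            ok = (np.abs(mu) > 0) & (osi > 1e-12)
            theta_map[gi[ok]] = (0.5 * np.angle(mu[ok]) + 0.5 * math.pi) \
                % math.pi

    shape = (grid.ny, grid.nx)
    return TuningMap(
        theta=theta_map.reshape(shape),
        osi=osi_map.reshape(shape),
        kpref=kpref_map.reshape(shape),
        grid=grid,
        stage="unfiltered",
        meta={
            "sigma_r_um": params.sigma_r,
            "sigma_s_um": params.sigma_s,
            "magnification": params.magnification,
            "k_method": k_method,
            "n_theta": n_theta,
            "n_k": n_k,
            "mosaic_provenance": mosaic.provenance,
        },
    )


# ---------------------------------------------------------------------------
# thresholding and smoothing

def threshold_and_smooth(
    tmap: TuningMap,
    osi_threshold: float = 0.25,
    kernel_sd_mm: float | None = None,
    *,
    lambda_expected_mm: float | None = None,
    kernel_sd_lambda: float = 0.15,
) -> TuningMap:
    """OSI-threshold then Gaussian low-pass the complex field ``z``.

    Pixels with ``OSI ≤ osi_threshold`` are set to ``z = 0``; the masked
    complex field is convolved with an isotropic Gaussian of SD
    ``kernel_sd_mm`` (or ``kernel_sd_lambda · lambda_expected_mm`` when the
    width is given as a fraction of the expected column spacing).  θ and OSI
    are re-derived from the smoothed field.  In the joint limit of zero
    threshold and vanishing kernel the map is unchanged.
    """
    if tmap.stage != "unfiltered":
        raise ValueError("threshold_and_smooth expects an unfiltered map")
    if kernel_sd_mm is None:
        if lambda_expected_mm is None:
            raise ValueError("provide kernel_sd_mm or lambda_expected_mm")
        kernel_sd_mm = kernel_sd_lambda * lambda_expected_mm
    if kernel_sd_mm < 0:
        raise ValueError("kernel width must be non-negative")
    z = tmap.z.copy()
    z[tmap.osi <= osi_threshold] = 0.0
    if kernel_sd_mm > 0:
        sd_px = kernel_sd_mm / tmap.grid.pixel_size_mm
        z = (gaussian_filter(z.real, sd_px, mode="nearest")
             + 1j * gaussian_filter(z.imag, sd_px, mode="nearest"))
    out = TuningMap.from_z(z, tmap.grid, stage="smoothed",
                           kpref=tmap.kpref.copy(),
                           meta={**tmap.meta,
                                 "osi_threshold": osi_threshold,
                                 "kernel_sd_mm": kernel_sd_mm})
    return out
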