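"""Layout statistics for orientation preference maps.

Operates on the complex orientation field ``z = OSI · e^{2iθ}`` (or
``e^{2iθ}`` for unfiltered maps) sampled on a regular grid:

* amplitude and marginal amplitude spectra,
* Fermi band-pass filtering,
* Morlet-wavelet estimation of the local column spacing Λ,
* phase-singularity (pinwheel) detection with topological charges,
* pinwheel density ρ (per Λ²; ±1 charges counted twice),
* SD(A) density-variability power law (exponent γ, coefficient c),
* nearest-neighbor distance statistics by charge class, and
* map comparison measures (circular difference, cross-correlation).

Distances are normalized by the column spacing Λ wherever the common-design
statistics are reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "WaveletConfig",
    "PinwheelSet",
    "CommonDesignStats",
    "amplitude_spectrum",
    "marginal_spectrum",
    "fermi_bandpass",
    "local_column_spacing",
    "find_pinwheels",
    "pinwheel_density",
    "density_variability",
    "nn_distances",
    "nn_histogram",
    "circular_difference",
    "map_cross_correlation",
    "theta_cross_correlation",
    "common_design_stats",
]


# ---------------------------------------------------------------------------
# containers

@dataclass(frozen=True)
class WaveletConfig:
    """Morlet wavelet bank for column-spacing estimation.

    ``xi`` sets the envelope size (the wavelet carries ≈ ``xi/(2π)`` carrier
    periods, so larger ``xi`` trades spatial for scale resolution);
    ``n_orientations`` plane-wave directions are averaged over [0, π).
    The scale grid (same units as the map pixel size) is log-spaced.
    """

    scales: np.ndarray
    xi: float = 7.0
    n_orientations: int = 16

    def __post_init__(self) -> None:
        s = np.asarray(self.scales, dtype=float)
        if self.xi <= 0:
            raise ValueError("xi must be positive")
        if self.n_orientations < 8:
            raise ValueError("need at least 8 wavelet orientations")
        if s.ndim != 1 or len(s) < 2 or np.any(np.diff(s) <= 0):
            raise ValueError("scales must be a strictly increasing 1D grid")
        object.__setattr__(self, "scales", s)

    @classmethod
    def around(cls, lambda_expected: float, n_scales: int = 24,
               span: float = 3.0, **kw) -> "WaveletConfig":
        scales = np.geomspace(lambda_expected / span, lambda_expected * span,
                              n_scales)
        return cls(scales=scales, **kw)


@dataclass
class PinwheelSet:
    """Located phase singularities of one orientation map.

    ``positions`` are in map length units (same as the region extent),
    ``charges`` in half-integers; ``spacing`` is the column spacing Λ used to
    normalize all downstream distances and densities.  ``low_confidence``
    flags singularities from merged or crowded detections.
    """

    positions: np.ndarray
    charges: np.ndarray
    region_area: float
    spacing: float
    low_confidence: np.ndarray | None = None
    periodic_box: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float).reshape(-1, 2)
        self.charges = np.asarray(self.charges, float).reshape(-1)
        if self.low_confidence is None:
            self.low_confidence = np.zeros(len(self.charges), dtype=bool)
        if self.spacing <= 0:
            raise ValueError("column spacing must be positive")
        if len(self.charges) != len(self.positions):
            raise ValueError("positions / charges length mismatch")

    @property
    def counting_weights(self) -> np.ndarray:
        """Pinwheel counting weight: 1 for |q| = ½, 2 for |q| = 1."""
        return 2.0 * np.abs(self.charges)

    def __len__(self) -> int:
        return len(self.charges)


@dataclass
class CommonDesignStats:
    """The six common-design layout parameters of one map or ensemble."""

    rho: float
    nn_any: float
    nn_same: float
    nn_opposite: float
    gamma: float
    c: float
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "rho": self.rho,
            "nn_any": self.nn_any,
            "nn_same": self.nn_same,
            "nn_opposite": self.nn_opposite,
            "gamma": self.gamma,
            "c": self.c,
        }


# ---------------------------------------------------------------------------
# spectra

def amplitude_spectrum(z: np.ndarray, pixel_size: float = 1.0):
    """|FFT| of the complex orientation field, centered, with k-axes.

    Returns ``(spec, kx, ky)`` where ``spec[i, j]`` is ``|R(k)|`` at
    ``(ky[i], kx[j])`` in rad per map length unit.
    """
    z = np.asarray(z)
    spec = np.abs(np.fft.fftshift(np.fft.fft2(z)))
    ky = 2.0 * math.pi * np.fft.fftshift(np.fft.fftfreq(z.shape[0], d=pixel_size))
    kx = 2.0 * math.pi * np.fft.fftshift(np.fft.fftfreq(z.shape[1], d=pixel_size))
    return spec, kx, ky


def marginal_spectrum(spec: np.ndarray, kx: np.ndarray, ky: np.ndarray,
                      n_bins: int = 64):
    """Radially averaged amplitude spectrum, normalized to max 1.

    Returns ``(k_centers, f)`` with ``max(f) == 1``.
    """
    kk = np.hypot(kx[None, :], ky[:, None]).ravel()
    s = np.asarray(spec, float).ravel()
    kmax = min(np.abs(kx).max(), np.abs(ky).max())
    bins = np.linspace(0.0, kmax, n_bins + 1)
    idx = np.digitize(kk, bins) - 1
    valid = (idx >= 0) & (idx < n_bins)
    sums = np.bincount(idx[valid], weights=s[valid], minlength=n_bins)
    counts = np.bincount(idx[valid], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        f = sums / counts
    f = np.nan_to_num(f)
    if f.max() > 0:
        f = f / f.max()
    centers = 0.5 * (bins[:-1] + bins[1:])
    return centers, f


def fermi_bandpass(image: np.ndarray, pixel_size: float,
                   low_cut: float, high_cut: float,
                   steepness_frac: float = 0.05) -> np.ndarray:
    """Band-pass an image between wavelengths ``low_cut`` and ``high_cut``.

    The radially symmetric transfer function is a product of two Fermi steps
    in wavelength λ = 2π/|k| — ≈1 for λ inside (low_cut, high_cut), →0
    outside — with step widths ``steepness_frac`` of the respective cutoff.
    The DC component is removed.  Works for real or complex images.
    """
    if not 0 < low_cut < high_cut:
        raise ValueError("need 0 < low_cut < high_cut (wavelengths)")
    img = np.asarray(image)
    ny, nx = img.shape
    nyquist_lambda = 2.0 * pixel_size
    if low_cut < nyquist_lambda:
        raise ValueError(
            f"low cutoff {low_cut} below the grid Nyquist wavelength "
            f"{nyquist_lambda}"
        )
    if high_cut > max(nx, ny) * pixel_size:
        raise ValueError("high cutoff exceeds the image size")
    ky = 2.0 * math.pi * np.fft.fftfreq(ny, d=pixel_size)
    kx = 2.0 * math.pi * np.fft.fftfreq(nx, d=pixel_size)
    kk = np.hypot(kx[None, :], ky[:, None])
    with np.errstate(divide="ignore"):
        lam = np.where(kk > 0, 2.0 * math.pi / np.maximum(kk, 1e-300), np.inf)
    gain = (1.0 / (1.0 + np.exp((low_cut - lam) / (steepness_frac * low_cut)))
            / (1.0 + np.exp((lam - high_cut) / (steepness_frac * high_cut))))
    gain.flat[0] = 0.0  # remove DC
    out = np.fft.ifft2(np.fft.fft2(img) * gain)
    return out if np.iscomplexobj(img) else out.real


# ---------------------------------------------------------------------------
# wavelet column spacing

def local_column_spacing(z: np.ndarray, pixel_size: float,
                         cfg: WaveletConfig,
                         valid_mask: np.ndarray | None = None,
                         kernel_norm: str = "peak"):
    """Morlet-wavelet estimate of the local column spacing Λ.

    For each scale Λ in the bank, complex Morlet coefficients (Gaussian
    envelope SD ``σ = ξΛ/2π``, carrier ``|k_φ| = 2π/Λ``) are computed by FFT
    convolution for ``n_orientations`` directions in [0, π) and averaged in
    modulus.  ``Λ_local(y)`` is the scale maximizing the averaged
    coefficient; the mean over the valid region is returned as the global
    estimate.

    ``kernel_norm`` fixes how coefficients are compared across scales:
    ``"peak"`` (default) normalizes every kernel to unit response to a
    matched plane wave, so a locally periodic pattern is assigned its true
    wavelength irrespective of scale; ``"l2"`` keeps constant L2 norm
    (response to a pure tone then grows ∝ σ, biasing the argmax toward
    larger scales on nearly periodic maps).

    Returns ``(lambda_local, lambda_mean)``.
    """
    if kernel_norm not in ("peak", "l2"):
        raise ValueError("kernel_norm must be 'peak' or 'l2'")
    z = np.asarray(z)
    ny, nx = z.shape
    if min(nx, ny) * pixel_size < 4.0 * cfg.scales[-1]:
        raise ValueError("map smaller than 4x the largest wavelet scale")
    ky = 2.0 * math.pi * np.fft.fftfreq(ny, d=pixel_size)
    kx = 2.0 * math.pi * np.fft.fftfreq(nx, d=pixel_size)
    kxg, kyg = np.meshgrid(kx, ky)
    fz = np.fft.fft2(z)
    phis = np.arange(cfg.n_orientations) * math.pi / cfg.n_orientations
    n_s = len(cfg.scales)
    stack = np.empty((n_s, ny, nx))
    for si, lam in enumerate(cfg.scales):
        sigma = cfg.xi * lam / (2.0 * math.pi)
        k0 = 2.0 * math.pi / lam
        acc = np.zeros((ny, nx))
        for phi in phis:
            kcx = k0 * math.cos(phi)
            kcy = k0 * math.sin(phi)
            # FT of the rotated Morlet: Gaussian of width 1/sigma at k_phi
            ker = np.exp(
                -0.5 * sigma**2 * ((kxg - kcx) ** 2 + (kyg - kcy) ** 2)
            )
            if kernel_norm == "l2":
                ker = 2.0 * math.pi * sigma * ker
            acc += np.abs(np.fft.ifft2(fz * ker))
        stack[si] = acc / cfg.n_orientations
    arg = np.argmax(stack, axis=0)
    log_s = np.log(cfg.scales)
    lam_local = cfg.scales[arg]
    # parabolic refinement in log-scale removes grid quantization bias
    inner = (arg > 0) & (arg < n_s - 1)
    iy, ix = np.nonzero(inner)
    a0 = arg[iy, ix]
    ym = stack[a0 - 1, iy, ix]
    y0 = stack[a0, iy, ix]
    yp = stack[a0 + 1, iy, ix]
    denom = ym - 2.0 * y0 + yp
    shift = np.where(np.abs(denom) > 1e-300,
                     0.5 * (ym - yp) / denom, 0.0)
    shift = np.clip(shift, -0.5, 0.5)
    step = np.diff(log_s).mean()
    lam_local = lam_local.astype(float)
    lam_local[iy, ix] = np.exp(log_s[a0] + shift * step)
    sel = np.ones_like(lam_local, bool) if valid_mask is None else valid_mask
    edge_frac = np.mean((arg[sel] == 0) | (arg[sel] == n_s - 1))
    if edge_frac > 0.10:
        warnings.warn(
            f"{edge_frac:.0%} of pixels take their best scale at the edge of "
            "the wavelet scale grid; the grid is probably too narrow",
            stacklevel=2,
        )
    return lam_local, float(lam_local[sel].mean())


# ---------------------------------------------------------------------------
# pinwheel detection

def _wrap(a: np.ndarray) -> np.ndarray:
    return (a + math.pi) % (2.0 * math.pi) - math.pi


def _bilinear_zero(z00, z10, z01, z11):
    """Sub-pixel root of the bilinear interpolant of z on a unit cell.

    Solves Re=Im=0 for ``z(u,v) = z00(1-u)(1-v) + z10 u(1-v) + z01 (1-u)v
    + z11 uv``; returns (u, v) in [0,1]² or the cell center as fallback.
    """
    a = z00
    b = z10 - z00
    c = z01 - z00
    d = z11 - z10 - z01 + z00
    # z(u,v) = a + b u + c v + d u v; eliminating v yields a quadratic in u
    qa = b.real * d.imag - b.imag * d.real
    qb = (a.real * d.imag - a.imag * d.real) + (b.real * c.imag - b.imag * c.real)
    qc = a.real * c.imag - a.imag * c.real
    roots = []
    if abs(qa) < 1e-30:
        if abs(qb) > 1e-30:
            roots = [-qc / qb]
    else:
        disc = qb * qb - 4.0 * qa * qc
        if disc >= 0:
            s = math.sqrt(disc)
            roots = [(-qb + s) / (2 * qa), (-qb - s) / (2 * qa)]
    for u in roots:
        if -0.05 <= u <= 1.05:
            den_r = c.real + d.real * u
            den_i = c.imag + d.imag * u
            if abs(den_r) >= abs(den_i):
                v = -(a.real + b.real * u) / den_r if abs(den_r) > 1e-30 else 0.5
            else:
                v = -(a.imag + b.imag * u) / den_i if abs(den_i) > 1e-30 else 0.5
            if -0.05 <= v <= 1.05:
                return min(max(u, 0.0), 1.0), min(max(v, 0.0), 1.0)
    return 0.5, 0.5


def find_pinwheels(
    z: np.ndarray,
    pixel_size: float = 1.0,
    *,
    spacing: float = 1.0,
    periodic: bool = False,
    margin: float = 0.0,
    origin: tuple[float, float] = (0.0, 0.0),
    merge_radius_px: float = 2.0,
) -> PinwheelSet:
    """Locate phase singularities of a complex orientation field.

    The winding of ``arg z`` is accumulated around every pixel plaquette
    (wrapped phase differences); plaquettes with nonzero winding contain a
    zero of ``z``, localized to sub-pixel precision through the bilinear
    interpolant of the corner values.  Topological charge is the winding
    divided by two: ``z`` winding 2π means the orientation θ = ½ arg z winds
    by π, i.e. charge ±½.  Same-sign detections closer than
    ``merge_radius_px`` are merged into a single pinwheel with summed charge
    — multiplicity-2 zeros (charge ±1) of crystalline layouts are recovered
    this way and flagged low-confidence, as are detections with another
    singularity within one pixel.

    Parameters
    ----------
    z:
        Complex field, shape (ny, nx).
    pixel_size:
        Map length units per pixel; a scalar or an ``(px_x, px_y)`` pair for
        slightly anisotropic grids (e.g. exactly periodic boxes of a
        hexagonal layout).
    spacing:
        Column spacing Λ (same units) stored for normalization.
    periodic:
        Treat the field as periodic (wrap-around plaquettes, no boundary
        loss).
    margin:
        Exclude pinwheels closer than this distance (map units) to the map
        edge (ignored when periodic).
    origin:
        Physical coordinates of the pixel (0, 0) center, ``(x0, y0)``.
    """
    z = np.asarray(z, dtype=complex)
    ny, nx = z.shape
    psx, psy = ((float(pixel_size), float(pixel_size))
                if np.isscalar(pixel_size) else map(float, pixel_size))
    ang = np.angle(z)
    if periodic:
        dx = _wrap(np.roll(ang, -1, axis=1) - ang)          # (ny, nx)
        dy = _wrap(np.roll(ang, -1, axis=0) - ang)
        wind = dx + np.roll(dy, -1, axis=1) - np.roll(dx, -1, axis=0) - dy
        cells_y, cells_x = np.nonzero(np.round(wind / (2 * math.pi)) != 0)
        q2 = np.round(wind[cells_y, cells_x] / (2 * math.pi))

        def corner(dy_, dx_):
            return z[(cells_y + dy_) % ny, (cells_x + dx_) % nx]
    else:
        dx = _wrap(ang[:, 1:] - ang[:, :-1])                # (ny, nx-1)
        dy = _wrap(ang[1:, :] - ang[:-1, :])                # (ny-1, nx)
        wind = dx[:-1, :] + dy[:, 1:] - dx[1:, :] - dy[:, :-1]
        cells_y, cells_x = np.nonzero(np.round(wind / (2 * math.pi)) != 0)
        q2 = np.round(wind[cells_y, cells_x] / (2 * math.pi))

        def corner(dy_, dx_):
            return z[cells_y + dy_, cells_x + dx_]

    region_area = _region_area(nx, ny, psx, psy, margin, periodic)
    box_units = (nx * psx, ny * psy) if periodic else None
    if len(cells_x) == 0:
        return PinwheelSet(np.empty((0, 2)), np.empty(0),
                           region_area=region_area, spacing=spacing,
                           periodic_box=box_units)

    z00, z10 = corner(0, 0), corner(0, 1)
    z01, z11 = corner(1, 0), corner(1, 1)
    uv = np.array([
        _bilinear_zero(z00[i], z10[i], z01[i], z11[i]) for i in range(len(q2))
    ])
    pos_px = np.stack([cells_x + uv[:, 0], cells_y + uv[:, 1]], axis=1)
    box_px = np.array([nx, ny], float) if periodic else None
    if periodic:
        pos_px = np.mod(pos_px, box_px)

    def _tree(points):
        return cKDTree(points, boxsize=box_px) if periodic else cKDTree(points)

    # merge same-sign detections within merge_radius (degenerate zeros)
    merged_pos, merged_q, low_conf = [], [], []
    used = np.zeros(len(q2), bool)
    if merge_radius_px > 0 and len(q2) > 1:
        pairs = _tree(pos_px).query_pairs(merge_radius_px,
                                          output_type="ndarray")
    else:
        pairs = np.empty((0, 2), int)
    adj: dict[int, list[int]] = {}
    for i, j in pairs:
        if q2[i] * q2[j] > 0:
            adj.setdefault(int(i), []).append(int(j))
            adj.setdefault(int(j), []).append(int(i))
    for i in range(len(q2)):
        if used[i]:
            continue
        stack, comp = [i], []
        while stack:
            k = stack.pop()
            if used[k]:
                continue
            used[k] = True
            comp.append(k)
            stack.extend(adj.get(k, []))
        w = np.abs(q2[comp])
        ref = pos_px[comp[0]]
        rel = pos_px[comp] - ref
        if periodic:  # cluster may straddle the periodic boundary
            rel = rel - np.round(rel / box_px) * box_px
        center = ref + np.average(rel, axis=0, weights=w)
        if periodic:
            center = np.mod(center, box_px)
        merged_pos.append(center)
        merged_q.append(q2[comp].sum())
        low_conf.append(len(comp) > 1)
    pos_px = np.asarray(merged_pos)
    q2 = np.asarray(merged_q)
    low_conf = np.asarray(low_conf)

    # crowded detections (another singularity within ~1 px) -> low confidence
    if len(pos_px) > 1:
        d, _ = _tree(pos_px).query(pos_px, k=2)
        low_conf |= d[:, 1] < 1.0

    pos = pos_px * np.array([psx, psy]) + np.asarray(origin, float)[None, :]
    charges = q2 / 2.0
    if not periodic and margin > 0:
        x0, y0 = origin
        keep = (
            (pos[:, 0] >= x0 + margin)
            & (pos[:, 0] <= x0 + (nx - 1) * psx - margin)
            & (pos[:, 1] >= y0 + margin)
            & (pos[:, 1] <= y0 + (ny - 1) * psy - margin)
        )
        pos, charges, low_conf = pos[keep], charges[keep], low_conf[keep]
    return PinwheelSet(pos, charges, region_area=region_area,
                       spacing=spacing, low_confidence=low_conf,
                       periodic_box=box_units)


def _region_area(nx, ny, psx, psy, margin, periodic):
    if periodic:
        return nx * ny * psx * psy
    w = (nx - 1) * psx - 2 * margin
    h = (ny - 1) * psy - 2 * margin
    return max(w, 0.0) * max(h, 0.0)


# ---------------------------------------------------------------------------
# layout statistics

def pinwheel_density(pws: PinwheelSet) -> float:
    """Pinwheels per square column spacing; |charge| = 1 counts twice."""
    if pws.region_area <= 0:
        raise ValueError("empty analysis region")
    n_hypercolumns = pws.region_area / pws.spacing**2
    return float(pws.counting_weights.sum() / n_hypercolumns)


def density_variability(
    pws: PinwheelSet,
    region_extent: tuple[float, float, float, float],
    areas: np.ndarray | None = None,
    n_samples: int = 100,
    seed=None,
):
    """Power-law fit ``SD(A) = c·ρ·A^(−γ)`` of pinwheel-density variability.

    For each area ``A`` (in units Λ²), ``n_samples`` circular subregions are
    placed uniformly at random with their full disk inside
    ``region_extent = (xmin, xmax, ymin, ymax)``; the SD of the weighted
    pinwheel count divided by the area (both in Λ units) is recorded and
    ``log SD = log(cρ) − γ log A`` fitted by least squares.

    Returns ``(areas, sd_curve, gamma, c)``.
    """
    lam = pws.spacing
    xmin, xmax, ymin, ymax = region_extent
    if areas is None:
        areas = np.geomspace(1.0, 64.0, 12)
    areas = np.asarray(areas, float)
    region_area_lam2 = (xmax - xmin) * (ymax - ymin) / lam**2
    if areas.max() > 0.25 * region_area_lam2:
        raise ValueError(
            "largest subregion area exceeds a quarter of the analysis region"
        )
    if n_samples < 30:
        warnings.warn("fewer than 30 subregion samples; SD estimates noisy",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    rho = pinwheel_density(pws)
    pos = pws.positions
    w = pws.counting_weights
    sds = np.empty(len(areas))
    for i, a_lam in enumerate(areas):
        radius = math.sqrt(a_lam / math.pi) * lam
        cx = rng.uniform(xmin + radius, xmax - radius, n_samples)
        cy = rng.uniform(ymin + radius, ymax - radius, n_samples)
        d2 = ((pos[None, :, 0] - cx[:, None]) ** 2
              + (pos[None, :, 1] - cy[:, None]) ** 2)
        counts = (w[None, :] * (d2 <= radius**2)).sum(axis=1)
        sds[i] = np.std(counts / a_lam, ddof=1)
    ok = sds > 0
    slope, intercept = np.polyfit(np.log(areas[ok]), np.log(sds[ok]), 1)
    gamma = -slope
    c = math.exp(intercept) / rho
    return areas, sds, float(gamma), float(c)


def nn_distances(pws: PinwheelSet, mode: str = "any") -> np.ndarray:
    """Nearest-neighbor distances in units of Λ for a charge class.

    ``mode``:  ``"any"`` — nearest pinwheel of either charge sign;
    ``"same"`` / ``"opposite"`` — nearest of the same / opposite sign.
    """
    if mode not in ("any", "same", "opposite"):
        raise ValueError(f"unknown mode {mode!r}")
    pos, q = pws.positions, pws.charges
    if len(pos) < 2:
        raise ValueError("need at least two pinwheels")
    box = None
    if pws.periodic_box is not None:
        box = np.asarray(pws.periodic_box, float)
        pos = np.mod(pos, box)

    def _tree(points):
        return cKDTree(points, boxsize=box) if box is not None \
            else cKDTree(points)

    signs = np.sign(q)
    out = np.empty(len(pos))
    for s in (-1.0, 1.0):
        src = np.flatnonzero(signs == s)
        if len(src) == 0:
            continue
        if mode == "any":
            tgt = np.arange(len(pos))
        elif mode == "same":
            tgt = src
        else:
            tgt = np.flatnonzero(signs == -s)
        if mode == "opposite":
            if len(tgt) < 1:
                raise ValueError("no pinwheels of opposite charge")
            d, _ = _tree(pos[tgt]).query(pos[src], k=1)
        else:
            if len(tgt) < 2:
                raise ValueError("not enough pinwheels in the charge class")
            d, _ = _tree(pos[tgt]).query(pos[src], k=2)
            d = d[:, 1]
        out[src] = d
    return out / pws.spacing


def nn_histogram(distances_lam, bin_width: float = 0.05, d_max: float = 1.5):
    """Unit-mass histogram of NN distances with fixed binning.

    Returns ``(edges, masses)`` with masses summing to one.
    """
    edges = np.arange(0.0, d_max + bin_width / 2, bin_width)
    hist, _ = np.histogram(np.asarray(distances_lam), bins=edges)
    total = hist.sum()
    masses = hist / total if total > 0 else hist.astype(float)
    return edges, masses


# ---------------------------------------------------------------------------
# map comparison

def circular_difference(theta1: np.ndarray, theta2: np.ndarray,
                        threshold_deg: float = 45.0):
    """Pixelwise circular orientation difference in degrees.

    ``d = ½ |arg e^{2iΔ}|`` with ``Δ = θ1 − θ2`` lies in [0°, 90°].  Returns
    ``(d_deg, fraction_above_threshold)``; NaN pixels are ignored in the
    fraction.
    """
    t1 = np.asarray(theta1, float)
    t2 = np.asarray(theta2, float)
    if t1.shape != t2.shape:
        raise ValueError("maps must share a grid")
    d = 0.5 * np.abs(np.angle(np.exp(2j * (t1 - t2))))
    d_deg = np.degrees(d)
    valid = np.isfinite(d_deg)
    frac = float(np.mean(d_deg[valid] > threshold_deg)) if valid.any() else math.nan
    return d_deg, frac


def map_cross_correlation(z1: np.ndarray, z2: np.ndarray,
                          valid: np.ndarray | None = None) -> float:
    """Correlation of two complex orientation fields on a shared grid.

    Pearson correlation of the concatenated real and imaginary parts of the
    mean-removed fields over valid pixels.  Equals 1 for identical maps and
    −1 when every orientation differs by 90°.
    """
    a = np.asarray(z1, complex)
    b = np.asarray(z2, complex)
    if a.shape != b.shape:
        raise ValueError("maps must share a grid")
    if valid is None:
        valid = np.isfinite(a) & np.isfinite(b)
    av = a[valid]
    bv = b[valid]
    av = av - av.mean()
    bv = bv - bv.mean()
    x = np.concatenate([av.real, av.imag])
    y = np.concatenate([bv.real, bv.imag])
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("cross-correlation undefined for a constant map")
    return float(np.dot(x, y) / (nx * ny))


def theta_cross_correlation(theta1, theta2, valid=None) -> float:
    """Alternative comparison: correlation of ``e^{2iθ}`` ignoring OSI."""
    return map_cross_correlation(
        np.exp(2j * np.asarray(theta1, float)),
        np.exp(2j * np.asarray(theta2, float)),
        valid,
    )


# ---------------------------------------------------------------------------
# one-stop statistics

def common_design_stats(
    pws: PinwheelSet,
    region_extent: tuple[float, float, float, float],
    sd_areas: np.ndarray | None = None,
    n_samples: int = 100,
    seed=None,
) -> CommonDesignStats:
    """Compute all six common-design parameters from a pinwheel set."""
    rho = pinwheel_density(pws)
    nn_any = float(np.mean(nn_distances(pws, "any")))
    nn_same = float(np.mean(nn_distances(pws, "same")))
    nn_opp = float(np.mean(nn_distances(pws, "opposite")))
    areas, sds, gamma, c = density_variability(
        pws, region_extent, areas=sd_areas, n_samples=n_samples, seed=seed
    )
    return CommonDesignStats(
        rho=rho, nn_any=nn_any, nn_same=nn_same, nn_opposite=nn_opp,
        gamma=gamma, c=c,
        extras={"sd_areas": areas.tolist(), "sd_curve": sds.tolist(),
                "n_pinwheels": len(pws)},
    )
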