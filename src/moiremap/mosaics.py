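"""Retinal ganglion cell (RGC) mosaic generators.

The wiring model consumes planar point patterns of ON- and OFF-center RGC
receptive-field positions.  Four families are provided:

* perfect hexagonal lattices (the crystalline Moiré-interference case),
* hexagonal lattices with spatially *uncorrelated* Gaussian position jitter,
* hexagonal lattices with spatially *correlated* jitter drawn from a Gaussian
  random displacement field, and
* semi-regular mosaics from a pairwise-interacting point process (PIPP) with
  a hard exclusion zone and a soft pairwise interaction.

Coordinates are retinal micrometers with the origin at the window center.
Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Rect",
    "RGCMosaic",
    "DisorderSpec",
    "PIPPParams",
    "DisplacementField",
    "hexagonal_mosaic",
    "hexagonal_pair",
    "apply_uncorrelated_jitter",
    "sample_displacement_field",
    "apply_correlated_jitter",
    "jacobian_determinant",
    "pipp_mosaic",
    "regularity_index",
    "nearest_neighbor_distances",
]

ON, OFF = "ON", "OFF"


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle (μm), typically centered on the origin."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float

    @classmethod
    def centered(cls, width: float, height: float | None = None) -> "Rect":
        height = width if height is None else height
        return cls(-width / 2.0, width / 2.0, -height / 2.0, height / 2.0)

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area(self) -> float:
        return self.width * self.height

    def pad(self, margin: float) -> "Rect":
        return Rect(self.xmin - margin, self.xmax + margin,
                    self.ymin - margin, self.ymax + margin)

    def contains(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points)
        return (
            (p[..., 0] >= self.xmin)
            & (p[..., 0] <= self.xmax)
            & (p[..., 1] >= self.ymin)
            & (p[..., 1] <= self.ymax)
        )


@dataclass
class RGCMosaic:
    """Labeled planar point set of RGC receptive-field centers.

    ``positions`` is (N, 2) in μm, ``polarity`` an (N,) array of ``"ON"`` /
    ``"OFF"`` labels, ``extent`` the generation window and ``provenance`` a
    JSON-serializable record of how the mosaic was made.
    """

    positions: np.ndarray
    polarity: np.ndarray
    extent: Rect
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        self.polarity = np.asarray(self.polarity, dtype=object)
        if len(self.polarity) != len(self.positions):
            raise ValueError("positions and polarity must have equal length")
        if not np.all(self.extent.contains(self.positions)):
            raise ValueError("all mosaic positions must lie within the extent")

    def subset(self, polarity: str) -> np.ndarray:
        return self.positions[self.polarity == polarity]

    @property
    def n_cells(self) -> int:
        return len(self.positions)

    def merged_with(self, other: "RGCMosaic") -> "RGCMosaic":
        ext = Rect(
            min(self.extent.xmin, other.extent.xmin),
            max(self.extent.xmax, other.extent.xmax),
            min(self.extent.ymin, other.extent.ymin),
            max(self.extent.ymax, other.extent.ymax),
        )
        return RGCMosaic(
            np.concatenate([self.positions, other.positions]),
            np.concatenate([self.polarity, other.polarity]),
            ext,
            {"merge": [self.provenance, other.provenance]},
        )


@dataclass(frozen=True)
class DisorderSpec:
    """Positional disorder: strength ``eta`` and optional correlation length.

    Both are expressed in units of the lattice constant ``r``:  uncorrelated
    jitter displaces each cell by an isotropic Gaussian offset of
    per-component SD ``eta * r``;  when ``correlation_length`` is set, the
    displacement is instead read from a smooth Gaussian random field of that
    correlation length (in units of ``r``), scaled by ``eta * r``.
    """

    eta: float
    correlation_length: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError("disorder strength eta must be >= 0")
        if self.correlation_length is not None and self.correlation_length <= 0:
            raise ValueError("correlation_length must be positive when given")


@dataclass(frozen=True)
class PIPPParams:
    """Pairwise-interacting point process parameters (per polarity).

    ``h(d) = 0`` for ``d < delta`` (hard exclusion) and
    ``1 − exp(−((d − delta)/phi)^alpha)`` otherwise.  The published fits that
    introduced this construction for cat beta-cell mosaics do not transfer a
    single canonical parameter set, so the defaults below are a documented,
    configurable choice producing regularly-spaced mosaics at roughly
    hexagonal-equivalent density.
    """

    delta_um: float = 80.0
    phi_um: float = 60.0
    alpha: float = 2.0
    density_per_mm2: float = 40.0
    sweeps: int = 20
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.delta_um, self.phi_um, self.alpha, self.density_per_mm2) <= 0:
            raise ValueError("all PIPP parameters must be positive")

    def interaction(self, d: np.ndarray) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        h = 1.0 - np.exp(-(((np.maximum(d, self.delta_um) - self.delta_um)
                            / self.phi_um) ** self.alpha))
        return np.where(d < self.delta_um, 0.0, h)


@dataclass
class DisplacementField:
    """Two independent unit-variance Gaussian random fields on a grid.

    ``y1``, ``y2`` are (ny, nx) dimensionless displacement components (units
    of the lattice constant before scaling by ``eta * r``); ``xs``, ``ys``
    are the grid coordinates (μm).  The summed autocorrelation is
    ``⟨y(x1)·y(x2)⟩ = 2 exp(−|x1−x2|²/(2σ²))``.
    """

    y1: np.ndarray
    y2: np.ndarray
    xs: np.ndarray
    ys: np.ndarray
    correlation_length_um: float

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Bilinear interpolation of (y1, y2) at (N, 2) positions (μm)."""
        from scipy.interpolate import RegularGridInterpolator

        pts = np.asarray(points, dtype=float)[:, ::-1]  # (y, x) ordering
        out = np.empty((len(pts), 2))
        for i, comp in enumerate((self.y1, self.y2)):
            itp = RegularGridInterpolator(
                (self.ys, self.xs), comp, method="linear", bounds_error=True
            )
            out[:, i] = itp(pts)
        return out


# ---------------------------------------------------------------------------
# hexagonal lattices

def hexagonal_mosaic(
    lattice_constant_um: float,
    rotation: float,
    extent: Rect,
    polarity: str = ON,
) -> RGCMosaic:
    """All points of a rotated hexagonal lattice falling inside ``extent``.

    The lattice is generated by ``a1 = r(1, 0)`` and ``a2 = r(1/2, √3/2)``
    rotated by ``rotation`` (radians) about the origin; the origin is always
    a lattice point.  Interior points have six nearest neighbors at exactly
    the lattice constant.
    """
    r = float(lattice_constant_um)
    if r <= 0:
        raise ValueError("lattice constant must be positive")
    if extent.area <= 0:
        raise ValueError("degenerate extent: generation window has zero area")
    if polarity not in (ON, OFF):
        raise ValueError(f"polarity must be 'ON' or 'OFF', got {polarity!r}")
    rad = math.hypot(
        max(abs(extent.xmin), abs(extent.xmax)),
        max(abs(extent.ymin), abs(extent.ymax)),
    )
    span = int(math.ceil(2.0 * rad / r)) + 2
    k, l = np.meshgrid(np.arange(-span, span + 1), np.arange(-span, span + 1))
    a1 = np.array([1.0, 0.0])
    a2 = np.array([0.5, math.sqrt(3.0) / 2.0])
    pts = r * (k.ravel()[:, None] * a1 + l.ravel()[:, None] * a2)
    ca, sa = math.cos(rotation), math.sin(rotation)
    rot = np.array([[ca, -sa], [sa, ca]])
    pts = pts @ rot.T
    pts = pts[extent.contains(pts)]
    pol = np.full(len(pts), polarity, dtype=object)
    return RGCMosaic(
        pts,
        pol,
        extent,
        {
            "generator": "hexagonal",
            "lattice_constant_um": r,
            "rotation_rad": float(rotation),
            "polarity": polarity,
        },
    )


def hexagonal_pair(
    r_um: float,
    r_prime_um: float,
    alpha: float,
    alpha_prime: float,
    extent: Rect,
) -> RGCMosaic:
    """Convenience: superposed ON (``r``, ``alpha``) and OFF (``r'``,
    ``alpha'``) hexagonal mosaics on a common window."""
    on = hexagonal_mosaic(r_um, alpha, extent, ON)
    off = hexagonal_mosaic(r_prime_um, alpha_prime, extent, OFF)
    return on.merged_with(off)


# ---------------------------------------------------------------------------
# jitter

def apply_uncorrelated_jitter(
    mosaic: RGCMosaic, disorder: DisorderSpec, lattice_constant_um: float
) -> RGCMosaic:
    """Displace every cell by an independent 2D Gaussian offset.

    Per-component SD is ``eta * r`` (μm).  ON and OFF cells receive
    independent draws.  The extent is enlarged to keep displaced cells
    inside the window invariant of the mosaic container.
    """
    if disorder.correlation_length is not None:
        raise ValueError("DisorderSpec with correlation_length given; use "
                         "apply_correlated_jitter")
    sd = disorder.eta * lattice_constant_um
    rng = np.random.default_rng(disorder.seed)
    offsets = rng.normal(0.0, sd, size=mosaic.positions.shape) if sd > 0 else 0.0
    new_pos = mosaic.positions + offsets
    pad = 0.0 if sd == 0 else float(np.max(np.abs(offsets))) + 1e-9
    return RGCMosaic(
        new_pos,
        mosaic.polarity.copy(),
        mosaic.extent.pad(pad),
        {
            "generator": "uncorrelated_jitter",
            "parent": mosaic.provenance,
            "eta": disorder.eta,
            "lattice_constant_um": lattice_constant_um,
            "seed": disorder.seed,
        },
    )


def sample_displacement_field(
    extent: Rect,
    correlation_length_um: float,
    seed=None,
    *,
    grid_step_um: float | None = None,
) -> DisplacementField:
    """Sample a complex Gaussian random displacement field spectrally.

    Complex white-noise Fourier amplitudes are shaped by a Gaussian power
    spectrum of width ``1/σ`` and inverse-transformed; real and imaginary
    parts give two independent real fields, each normalized in expectation
    to unit variance with Gaussian spatial autocorrelation
    ``exp(−d²/(2σ²))``.
    """
    sigma = float(correlation_length_um)
    if sigma <= 0:
        raise ValueError("correlation_length must be positive")
    if sigma > min(extent.width, extent.height):
        warnings.warn(
            "correlation length exceeds the field extent; the sampled field "
            "is under-resolved and its statistics unreliable",
            stacklevel=2,
        )
    step = grid_step_um if grid_step_um is not None else sigma / 8.0
    nx = max(int(math.ceil(extent.width / step)) + 1, 16)
    ny = max(int(math.ceil(extent.height / step)) + 1, 16)
    xs = np.linspace(extent.xmin, extent.xmax, nx)
    ys = np.linspace(extent.ymin, extent.ymax, ny)
    dx = xs[1] - xs[0]
    dy = ys[1] - ys[0]
    kx = 2.0 * math.pi * np.fft.fftfreq(nx, d=dx)
    ky = 2.0 * math.pi * np.fft.fftfreq(ny, d=dy)
    k2 = kx[None, :] ** 2 + ky[:, None] ** 2
    power = np.exp(-0.5 * sigma**2 * k2)  # FT of the Gaussian autocorrelation
    rng = np.random.default_rng(seed)
    white = rng.normal(size=(ny, nx)) + 1j * rng.normal(size=(ny, nx))
    zfield = np.fft.ifft2(white * np.sqrt(power))
    # normalize so each real component has expected variance exactly 1
    var = power.sum() / (nx * ny) ** 2  # per-component variance of ifft2
    zfield /= math.sqrt(var)
    return DisplacementField(
        y1=zfield.real.copy(),
        y2=zfield.imag.copy(),
        xs=xs,
        ys=ys,
        correlation_length_um=sigma,
    )


def apply_correlated_jitter(
    mosaic: RGCMosaic,
    disorder: DisorderSpec,
    lattice_constant_um: float,
    fields: dict[str, DisplacementField] | None = None,
) -> RGCMosaic:
    """Displace cells coherently by a smooth Gaussian random field.

    Each cell moves by ``eta * r`` times the (bilinearly interpolated) field
    value at its undistorted position; ON and OFF mosaics use two
    *independent* field realizations, drawn here when ``fields`` is None.
    """
    if disorder.correlation_length is None:
        raise ValueError("DisorderSpec.correlation_length required for "
                         "correlated jitter")
    r = lattice_constant_um
    sigma_um = disorder.correlation_length * r
    if fields is None:
        ss = disorder.seed if isinstance(disorder.seed, np.random.SeedSequence) \
            else np.random.SeedSequence(disorder.seed)
        s_on, s_off = ss.spawn(2)
        fields = {
            ON: sample_displacement_field(mosaic.extent, sigma_um, s_on),
            OFF: sample_displacement_field(mosaic.extent, sigma_um, s_off),
        }
    new_pos = mosaic.positions.copy()
    max_shift = 0.0
    for pol in (ON, OFF):
        idx = np.flatnonzero(mosaic.polarity == pol)
        if len(idx) == 0:
            continue
        f = fields[pol]
        ext = mosaic.extent
        if (f.xs[0] > ext.xmin or f.xs[-1] < ext.xmax
                or f.ys[0] > ext.ymin or f.ys[-1] < ext.ymax):
            raise ValueError("displacement field does not cover mosaic extent")
        disp = disorder.eta * r * f.interpolate(mosaic.positions[idx])
        new_pos[idx] += disp
        if disorder.eta > 0:
            max_shift = max(max_shift, float(np.max(np.abs(disp))))
    return RGCMosaic(
        new_pos,
        mosaic.polarity.copy(),
        mosaic.extent.pad(max_shift + 1e-9 if max_shift else 0.0),
        {
            "generator": "correlated_jitter",
            "parent": mosaic.provenance,
            "eta": disorder.eta,
            "correlation_length_r": disorder.correlation_length,
            "lattice_constant_um": r,
            "seed": disorder.seed,
        },
    )


def jacobian_determinant(fld: DisplacementField) -> np.ndarray:
    """``det ∂(y1, y2)/∂(x1, x2)`` by central finite differences.

    Positive values mark local dilation of the distorted lattice (cells
    further apart), negative values local compression.
    """
    d1y, d1x = np.gradient(fld.y1, fld.ys, fld.xs)
    d2y, d2x = np.gradient(fld.y2, fld.ys, fld.xs)
    return d1x * d2y - d1y * d2x


# ---------------------------------------------------------------------------
# pairwise interacting point process

def _pipp_single(
    n: int, extent: Rect, params: PIPPParams, rng: np.random.Generator
) -> np.ndarray:
    """Metropolis birth-death sampling of one fixed-count PIPP polarity."""
    # start from a sequential hard-core packing so the initial state is valid
    pos = np.empty((n, 0)).reshape(0, 2)
    attempts = 0
    pts: list[np.ndarray] = []
    while len(pts) < n:
        cand = np.array(
            [rng.uniform(extent.xmin, extent.xmax),
             rng.uniform(extent.ymin, extent.ymax)]
        )
        if pts:
            d = np.linalg.norm(np.asarray(pts) - cand, axis=1)
            if d.min() < params.delta_um:
                attempts += 1
                if attempts > 200 * n:
                    raise RuntimeError(
                        "PIPP initialisation failed: requested density is "
                        "infeasible for the exclusion distance delta"
                    )
                continue
        pts.append(cand)
    pos = np.asarray(pts)

    accepted = 0
    total = params.sweeps * n
    for it in range(total):
        i = rng.integers(n)
        cand = np.array(
            [rng.uniform(extent.xmin, extent.xmax),
             rng.uniform(extent.ymin, extent.ymax)]
        )
        others = np.delete(pos, i, axis=0)
        d_new = np.linalg.norm(others - cand, axis=1)
        if d_new.min() < params.delta_um:
            continue
        d_old = np.linalg.norm(others - pos[i], axis=1)
        # only pairs within interaction range contribute to the ratio
        rng_cut = params.delta_um + 6.0 * params.phi_um
        ln_new = np.sum(np.log(params.interaction(d_new[d_new < rng_cut])))
        ln_old = np.sum(np.log(params.interaction(d_old[d_old < rng_cut])))
        if ln_new >= ln_old or math.log(rng.uniform()) < ln_new - ln_old:
            pos[i] = cand
            accepted += 1
    if accepted < 0.05 * total:
        warnings.warn(
            "PIPP acceptance rate below 5%; the chain may not have "
            "equilibrated within the iteration budget",
            stacklevel=3,
        )
    return pos


def pipp_mosaic(params: PIPPParams, extent: Rect) -> RGCMosaic:
    """Generate an ON/OFF RGC mosaic from two independent PIPP realizations.

    Cell counts are fixed from the target density and window area
    (conditional simulation); positions are iteratively resampled by
    single-cell Metropolis moves that maximize the product of pairwise
    interactions ``h(d)`` among same-polarity neighbors.  ON and OFF are
    fully independent; no same-polarity pair is ever closer than ``delta``.
    """
    n = int(round(params.density_per_mm2 * extent.area / 1e6))
    if n < 2:
        raise ValueError("window too small: fewer than 2 cells per polarity")
    # feasibility: disks of radius delta/2 at the target count must fit loosely
    packing = n * math.pi * (params.delta_um / 2.0) ** 2 / extent.area
    if packing > 0.65:
        raise ValueError(
            f"infeasible PIPP parameters: exclusion packing fraction "
            f"{packing:.2f} exceeds 0.65"
        )
    rng = np.random.default_rng(params.seed)
    pos_on = _pipp_single(n, extent, params, rng)
    pos_off = _pipp_single(n, extent, params, rng)
    positions = np.concatenate([pos_on, pos_off])
    polarity = np.array([ON] * n + [OFF] * n, dtype=object)
    return RGCMosaic(
        positions,
        polarity,
        extent,
        {
            "generator": "pipp",
            "delta_um": params.delta_um,
            "phi_um": params.phi_um,
            "alpha": params.alpha,
            "density_per_mm2": params.density_per_mm2,
            "sweeps": params.sweeps,
            "seed": params.seed,
        },
    )


# ---------------------------------------------------------------------------
# mosaic statistics

def nearest_neighbor_distances(points: np.ndarray) -> np.ndarray:
    """Distance of every point to its nearest neighbor in the same set."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ValueError("need at least two points")
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    return d[:, 1]


def regularity_index(points: np.ndarray) -> float:
    """Mean nearest-neighbor distance divided by its standard deviation.

    Values above ~3 are conventionally called "regularly spaced"; a Poisson
    process gives ≈1.91.
    """
    nn = nearest_neighbor_distances(points)
    return float(nn.mean() / nn.std(ddof=1))
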