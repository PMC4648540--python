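"""Closed-form solutions of the Moiré-interference wiring model on perfect
hexagonal mosaics.

For ON and OFF retinal ganglion cells placed on perfect hexagonal lattices
(lattice constants ``r``, ``r_prime``, rotations ``alpha``, ``alpha_prime``),
the Gaussian lattice sums that define cortical receptive fields can be
evaluated exactly with Jacobi theta functions: every hexagonal lattice is the
union of two rectangular sublattices, and a Gaussian sum over a rectangular
lattice factorizes into a product of one-dimensional theta series.

This module provides

* truncated-series Jacobi ``theta3`` / ``theta4`` (complex first argument,
  real nome),
* the Moiré geometry (scaling factor ``S``, critical wavenumber ``k_c``,
  column spacing ``Lambda_c``),
* the closed-form receptive field and its Fourier transform,
* the Hessian-based preferred-orientation layout (the unfiltered analytic
  map), and
* the six-planar-wave low-frequency field whose phase is the smoothed
  analytic orientation map, together with its crystalline pinwheel pattern.

All lengths are in retinal micrometers and all angles in radians unless
stated otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MoireParams",
    "SixModeField",
    "theta3",
    "theta4",
    "scaling_factor",
    "critical_wavenumber",
    "moire_geometry",
    "lattice_e_r",
    "lattice_e_phi",
    "analytic_rf",
    "analytic_spectrum",
    "structure_factor",
    "hessian_orientation",
    "six_mode_field",
    "moire_superlattice",
    "crystalline_pinwheels",
]


# ---------------------------------------------------------------------------
# parameters

@dataclass(frozen=True)
class MoireParams:
    """Geometry and receptive-field widths of the two-lattice model.

    Parameters
    ----------
    r, r_prime:
        ON / OFF lattice constants (μm).  ``r_prime = (1 + beta) * r`` defines
        the detuning ``beta``.
    alpha, alpha_prime:
        Rotation of the ON / OFF lattice (radians).
    sigma_r:
        Width of the Gaussian RGC receptive field (μm).
    sigma_s:
        Range of the Gaussian synaptic-weight (input-sampling) profile (μm).
    """

    r: float = 170.0
    r_prime: float = 170.0
    alpha: float = 0.0
    alpha_prime: float = math.radians(7.0)
    sigma_r: float = 70.0
    sigma_s: float = 20.0

    def __post_init__(self) -> None:
        if self.r <= 0 or self.r_prime <= 0:
            raise ValueError("lattice constants must be positive")
        if self.sigma_r <= 0 or self.sigma_s <= 0:
            raise ValueError("sigma_r and sigma_s must be positive")
        if self.beta_detune == 0.0 and self.delta_alpha % (2 * math.pi) == 0.0:
            raise ValueError(
                "degenerate Moiré geometry: equal lattices with zero relative "
                "angle have a diverging interference scale"
            )

    @property
    def delta_alpha(self) -> float:
        return self.alpha_prime - self.alpha

    @property
    def beta_detune(self) -> float:
        return self.r_prime / self.r - 1.0


# ---------------------------------------------------------------------------
# Jacobi theta functions

def _theta_terms(nome: float, im_max: float, tol: float = 1e-15) -> int:
    """Number of series terms so that q**(n*n) * exp(2*n*im_max) < tol."""
    if nome == 0.0:
        return 0
    lq = math.log(nome)
    n = 1
    while n * n * lq + 2.0 * n * im_max > math.log(tol):
        n += 1
        if n > 512:  # nome very close to 1 -- refuse rather than stall
            raise ValueError(f"theta series does not truncate (nome={nome!r})")
    return n


def _check_nome(nome: float) -> None:
    if not 0.0 <= nome < 1.0:
        raise ValueError(f"theta nome must lie in [0, 1), got {nome!r}")


def theta3(zarg, nome: float):
    """Jacobi ``Θ3(z, q) = 1 + 2 Σ_{n≥1} q^{n²} cos(2nz)``, truncated.

    ``zarg`` may be real or complex, scalar or array; ``nome`` must be a real
    number in ``[0, 1)``.  Terms are truncated when they fall below 1e-15 of
    unity (accounting for growth of ``cos`` along the imaginary direction).
    """
    _check_nome(nome)
    z = np.asarray(zarg)
    im_max = float(np.max(np.abs(z.imag))) if np.iscomplexobj(z) else 0.0
    out = np.ones_like(z, dtype=complex if np.iscomplexobj(z) else float)
    for n in range(1, _theta_terms(nome, im_max) + 1):
        out = out + 2.0 * nome ** (n * n) * np.cos(2.0 * n * z)
    return out if out.shape else out[()]


def theta4(zarg, nome: float):
    """Jacobi ``Θ4(z, q) = 1 + 2 Σ_{n≥1} (-1)^n q^{n²} cos(2nz)``, truncated."""
    _check_nome(nome)
    z = np.asarray(zarg)
    im_max = float(np.max(np.abs(z.imag))) if np.iscomplexobj(z) else 0.0
    out = np.ones_like(z, dtype=complex if np.iscomplexobj(z) else float)
    for n in range(1, _theta_terms(nome, im_max) + 1):
        out = out + 2.0 * (-1.0) ** n * nome ** (n * n) * np.cos(2.0 * n * z)
    return out if out.shape else out[()]


# ---------------------------------------------------------------------------
# Moiré geometry

def scaling_factor(beta_detune: float, delta_alpha: float) -> float:
    """Moiré scaling factor ``S = (1+β) / sqrt(β² + 2(1-cos Δα)(1+β))``.

    ``S·r`` is the distance between two vertices of the Moiré superlattice in
    units of the base lattice constant.  Diverges (returns ``inf``) when both
    the detuning and the relative angle vanish.
    """
    denom = beta_detune**2 + 2.0 * (1.0 - math.cos(delta_alpha)) * (1.0 + beta_detune)
    if denom <= 0.0:
        return math.inf
    return (1.0 + beta_detune) / math.sqrt(denom)


def critical_wavenumber(params: MoireParams) -> float:
    """Wavenumber ``k_c`` of the six dominant Moiré modes (rad/μm).

    ``k_c = 4π / (√3 r r′) · sqrt(r² + r′² − 2 r r′ cos Δα)``.
    """
    r, rp = params.r, params.r_prime
    return (
        4.0
        * math.pi
        / (math.sqrt(3.0) * r * rp)
        * math.sqrt(r**2 + rp**2 - 2.0 * r * rp * math.cos(params.delta_alpha))
    )


def moire_geometry(params: MoireParams) -> tuple[float, float]:
    """Return ``(k_c, Lambda_c)``; ``Lambda_c = 2π/k_c = (√3/2)·S·r′/(1+β)·(1+β)``.

    The column spacing is equivalently ``(√3/2)·S·r`` with the scaling factor
    ``S`` of :func:`scaling_factor`; both routes agree to machine precision.
    """
    kc = critical_wavenumber(params)
    if kc == 0.0:
        return 0.0, math.inf
    return kc, 2.0 * math.pi / kc


# ---------------------------------------------------------------------------
# lattice reciprocal half-vectors (the theta-function arguments)

def lattice_e_r(alpha: float, r: float) -> np.ndarray:
    """Vector ``e_r = -(π/r)(cos α, sin α)`` of the rotated lattice."""
    return -(math.pi / r) * np.array([math.cos(alpha), math.sin(alpha)])


def lattice_e_phi(alpha: float, r: float) -> np.ndarray:
    """Vector ``e_φ = -(π/(√3 r))(-sin α, cos α)`` of the rotated lattice."""
    return -(math.pi / (math.sqrt(3.0) * r)) * np.array(
        [-math.sin(alpha), math.cos(alpha)]
    )


# ---------------------------------------------------------------------------
# closed-form receptive field (spatial side)

def _sublattice_rf(x, y, alpha, r, sigma_r, sigma_s):
    """Gaussian lattice sum for one hexagonal sublattice via theta products.

    ``x``: (..., 2) retinal positions; ``y``: (2,) cortical/retinal center.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    s2 = sigma_r**2 * sigma_s**2 / (sigma_r**2 + sigma_s**2)
    ssum = sigma_r**2 + sigma_s**2
    b = (x * sigma_s**2 + y * sigma_r**2) / ssum
    er = lattice_e_r(alpha, r)
    ephi = lattice_e_phi(alpha, r)
    kappa = math.exp(-2.0 * math.pi**2 * s2 / r**2)
    tau = math.exp(-2.0 * math.pi**2 * s2 / (3.0 * r**2))
    t_pref = (
        2.0
        * math.pi
        * s2
        / (math.sqrt(3.0) * r**2)
        * np.exp(-np.sum((x - y) ** 2, axis=-1) / (2.0 * ssum))
    )
    z_r = b @ er
    z_phi = b @ ephi
    return t_pref * (
        theta3(z_phi, tau) * theta3(z_r, kappa)
        + theta4(z_phi, tau) * theta4(z_r, kappa)
    )


def analytic_rf(y, x, params: MoireParams) -> np.ndarray:
    """Closed-form cortical receptive field ``RF_y(x)`` (ON minus OFF sum).

    Parameters
    ----------
    y:
        Cortical unit position, shape (2,), μm (retinal frame,
        unit magnification).
    x:
        Retinal evaluation points, shape (..., 2), μm.

    Returns
    -------
    RF values with shape ``x.shape[:-1]``.  The result equals the infinite
    Gaussian lattice sum of the wiring model to truncation accuracy.
    """
    on = _sublattice_rf(x, y, params.alpha, params.r, params.sigma_r, params.sigma_s)
    off = _sublattice_rf(
        x, y, params.alpha_prime, params.r_prime, params.sigma_r, params.sigma_s
    )
    return on - off


# ---------------------------------------------------------------------------
# closed-form amplitude spectrum (Fourier side)

def _sublattice_spectrum(k, y, alpha, r, sigma_r, sigma_s):
    """Fourier transform of one sublattice RF term, convention
    ``R(k) = (1/2π) ∫ RF(x) e^{-i k·x} d²x``.

    ``k``: (..., 2) spatial-frequency points (rad/μm); ``y``: (2,).
    """
    k = np.asarray(k, dtype=float)
    y = np.asarray(y, dtype=float)
    nu = math.exp(-2.0 * math.pi**2 * sigma_s**2 / (3.0 * r**2))
    zeta = math.exp(-2.0 * math.pi**2 * sigma_s**2 / r**2)
    er = lattice_e_r(alpha, r)
    ephi = lattice_e_phi(alpha, r)
    c = y - 1j * sigma_s**2 * k  # (..., 2) complex
    k2 = np.sum(k**2, axis=-1)
    u_pref = (
        2.0
        * math.pi
        * sigma_r**2
        * sigma_s**2
        / (math.sqrt(3.0) * r**2)
        * np.exp(-1j * (k @ y) - 0.5 * k2 * (sigma_s**2 + sigma_r**2))
    )
    z_r = c @ er
    z_phi = c @ ephi
    return u_pref * (
        theta3(z_phi, nu) * theta3(z_r, zeta)
        + theta4(z_phi, nu) * theta4(z_r, zeta)
    )


def analytic_spectrum(y, k, params: MoireParams) -> np.ndarray:
    """Closed-form receptive-field Fourier transform ``R_y(k)`` (ON − OFF)."""
    on = _sublattice_spectrum(
        k, y, params.alpha, params.r, params.sigma_r, params.sigma_s
    )
    off = _sublattice_spectrum(
        k, y, params.alpha_prime, params.r_prime, params.sigma_r, params.sigma_s
    )
    return on - off


def structure_factor(y, k, params: MoireParams) -> np.ndarray:
    """Non-rotationally-symmetric part ``G_y(k)`` of the amplitude spectrum.

    ``|R_y(k)|² ∝ exp(−k²(σ_s²+σ_r²)) · |G_y(k)|²`` where the envelope is
    rotationally symmetric; preferred orientation is carried entirely by
    ``G``.  Each sublattice term carries its ``1/r²`` lattice-density weight.
    """
    k = np.asarray(k, dtype=float)
    y = np.asarray(y, dtype=float)

    def sub(alpha, r):
        nu = math.exp(-2.0 * math.pi**2 * params.sigma_s**2 / (3.0 * r**2))
        zeta = math.exp(-2.0 * math.pi**2 * params.sigma_s**2 / r**2)
        c = y - 1j * params.sigma_s**2 * k
        z_r = c @ lattice_e_r(alpha, r)
        z_phi = c @ lattice_e_phi(alpha, r)
        return (
            theta3(z_phi, nu) * theta3(z_r, zeta)
            + theta4(z_phi, nu) * theta4(z_r, zeta)
        ) / r**2

    return sub(params.alpha, params.r) - sub(params.alpha_prime, params.r_prime)


def hessian_orientation(y, params: MoireParams, *, step_frac: float = 1e-3,
                        convention: str = "edge"):
    """Preferred orientation of the unfiltered analytic layout at ``y``.

    The squared amplitude spectrum is expanded to quadratic order around
    ``k = 0``; the direction of largest increase of the quadratic form (the
    principal axis of its Hessian) is the preferred *wave-vector* direction::

        θ_wave = ½ · atan2(2 b, a − c)

    where ``(a, b; b, c)`` is the Hessian of ``|G_y(k)|²`` at ``k = 0``,
    evaluated by central finite differences with step ``step_frac · k_c``.
    With the default ``convention="edge"`` the returned angle is the
    preferred *edge* orientation ``θ_wave + π/2`` (a grating's stripes run
    perpendicular to its wave vector), matching the tuning extraction of the
    numerical pipeline; ``convention="wave"`` returns ``θ_wave`` itself.
    Both are folded to [0, π).

    ``y`` may be a single position (2,) or an array (..., 2); returns θ of
    shape ``y.shape[:-1]``.  Isotropic (degenerate) points return NaN.
    """
    if convention not in ("edge", "wave"):
        raise ValueError("convention must be 'edge' or 'wave'")
    y = np.asarray(y, dtype=float)
    single = y.ndim == 1
    ys = y[None, :] if single else y.reshape(-1, 2)
    kc = critical_wavenumber(params)
    h = step_frac * kc

    def g2(kvec):
        k = np.asarray(kvec, float)
        return np.abs(structure_factor(ys, k, params)) ** 2

    # second partials of |G|^2 at k=0 by 2nd-order central differences
    f0 = g2((0.0, 0.0))
    fxp, fxm = g2((h, 0.0)), g2((-h, 0.0))
    fyp, fym = g2((0.0, h)), g2((0.0, -h))
    fpp, fpm = g2((h, h)), g2((h, -h))
    fmp, fmm = g2((-h, h)), g2((-h, -h))
    a = (fxp - 2.0 * f0 + fxm) / h**2
    c = (fyp - 2.0 * f0 + fym) / h**2
    b = (fpp - fpm - fmp + fmm) / (4.0 * h**2)

    scale = np.maximum(np.abs(a) + np.abs(c), 1e-300)
    degenerate = (np.abs(a - c) + 2.0 * np.abs(b)) / scale < 1e-9
    theta = 0.5 * np.arctan2(2.0 * b, a - c)
    if convention == "edge":
        theta = theta + 0.5 * math.pi
    theta = np.mod(theta, math.pi)
    theta[degenerate] = np.nan
    if single:
        return float(theta[0])
    return theta.reshape(y.shape[:-1])


# ---------------------------------------------------------------------------
# six-planar-wave low-frequency field (the smoothed analytic layout)

@dataclass(frozen=True)
class SixModeField:
    """The six lowest-frequency Moiré modes and their phase factors.

    ``z(y) = Σ_j exp(i k_j · y) u_j`` with all ``|k_j| = k_c`` and
    ``|u_j| = 1``; the smoothed analytic orientation map is ``θ = ½ arg z``.
    """

    kvecs: np.ndarray  # (6, 2)
    phases: np.ndarray  # (6,) complex, unit modulus
    u0: complex
    k_c: float
    lambda_c: float
    params: MoireParams = field(repr=False)

    def evaluate(self, y, convention: str = "edge") -> np.ndarray:
        """Evaluate ``z`` at positions ``y`` of shape (..., 2) (μm).

        The mode sum is derived from the spectral center of mass of the
        receptive field, i.e. in the *wave-vector* angle convention; with
        the default ``convention="edge"`` it is negated so that
        ``θ = ½ arg z`` is the preferred edge orientation, consistent with
        the rest of the package.  Zeros, charges and layout statistics are
        identical in both conventions.
        """
        if convention not in ("edge", "wave"):
            raise ValueError("convention must be 'edge' or 'wave'")
        y = np.asarray(y, dtype=float)
        phase = np.tensordot(y, self.kvecs, axes=([-1], [1]))  # (..., 6)
        z = np.exp(1j * phase) @ self.phases
        return -z if convention == "edge" else z

    def orientation(self, y, convention: str = "edge") -> np.ndarray:
        """Preferred orientation ``½ arg z`` folded to [0, π)."""
        return np.mod(0.5 * np.angle(self.evaluate(y, convention)), math.pi)


def six_mode_field(params: MoireParams) -> SixModeField:
    """Construct the six-mode low-frequency field of the Moiré layout.

    Wave vectors are built from the differences of the two lattices'
    reciprocal half-vectors (``d_r = e_r − e_r'``, ``d_φ = e_φ − e_φ'``):
    ``±2(d_r + d_φ)``, ``±2(d_r − d_φ)`` and ``±4 d_φ``, with phase factors
    ``u0·e^{i4π/3}``, ``u0·e^{i2π/3}`` and ``u0``.  The higher ``√3·k_c``
    modes are excluded.
    """
    a, ap = params.alpha, params.alpha_prime
    r, rp = params.r, params.r_prime
    d_r = lattice_e_r(a, r) - lattice_e_r(ap, rp)
    d_phi = lattice_e_phi(a, r) - lattice_e_phi(ap, rp)
    kvecs = np.array(
        [
            2.0 * (d_r + d_phi),
            -2.0 * (d_r + d_phi),
            2.0 * (d_r - d_phi),
            -2.0 * (d_r - d_phi),
            4.0 * d_phi,
            -4.0 * d_phi,
        ]
    )
    u0 = (
        np.exp(1j * (a + ap))
        * (np.exp(1j * ap) * r + np.exp(1j * a) * rp)
        / (np.exp(1j * a) * r + np.exp(1j * ap) * rp)
    )
    phases = u0 * np.array(
        [
            np.exp(4j * math.pi / 3.0),
            np.exp(4j * math.pi / 3.0),
            np.exp(2j * math.pi / 3.0),
            np.exp(2j * math.pi / 3.0),
            1.0,
            1.0,
        ]
    )
    kc, lam = moire_geometry(params)
    return SixModeField(
        kvecs=kvecs, phases=phases, u0=complex(u0), k_c=kc, lambda_c=lam,
        params=params,
    )


def moire_superlattice(params: MoireParams) -> np.ndarray:
    """Primitive vectors (columns) of the Moiré superlattice in μm.

    Obtained by inverting the reciprocal basis ``{2(d_r − d_φ), 4 d_φ}`` of
    the six-mode star; ``z`` is exactly periodic under both vectors.
    """
    f = six_mode_field(params)
    b = np.stack([f.kvecs[2], f.kvecs[4]])  # (2, 2), rows are basis k-vectors
    return 2.0 * math.pi * np.linalg.inv(b)  # columns A1, A2 (k_i·A_j = 2πδ)


def crystalline_pinwheels(
    params: MoireParams, half_extent_um: float
) -> tuple[np.ndarray, np.ndarray]:
    """The perfect crystalline pinwheel pattern of the six-mode layout.

    One charge-+1 (double) pinwheel sits at every superlattice site and two
    charge−½ pinwheels at the two triangle centers of each unit cell.
    Returns ``(positions (N, 2) μm, charges (N,))`` for all pinwheels inside
    the centered square of half-side ``half_extent_um``.
    """
    basis = moire_superlattice(params)  # columns A1, A2
    a1, a2 = basis[:, 0], basis[:, 1]
    span = int(math.ceil(2.2 * half_extent_um / min(np.linalg.norm(a1), np.linalg.norm(a2)))) + 2
    m, n = np.meshgrid(np.arange(-span, span + 1), np.arange(-span, span + 1))
    frac = np.stack([m.ravel(), n.ravel()], axis=-1).astype(float)
    offsets = np.array([[0.0, 0.0], [1.0 / 3, 1.0 / 3], [2.0 / 3, 2.0 / 3]])
    charge_of = np.array([1.0, -0.5, -0.5])
    pos_list, q_list = [], []
    for off, q in zip(offsets, charge_of):
        p = (frac + off) @ basis.T
        pos_list.append(p)
        q_list.append(np.full(len(p), q))
    pos = np.concatenate(pos_list)
    q = np.concatenate(q_list)
    keep = (np.abs(pos[:, 0]) <= half_extent_um) & (np.abs(pos[:, 1]) <= half_extent_um)
    return pos[keep], q[keep]
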