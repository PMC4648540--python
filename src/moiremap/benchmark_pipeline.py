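"""Common-design reference constants, consistency verdicts and sweeps.

The experimentally measured, species-invariant layout statistics of V1
iso-orientation domains ("common design") serve as the benchmark the wiring
model is tested against.  Two nested interval sets are embedded as
reference constants for each of the six layout parameters (pinwheel density
ρ, the three mean NN distances in Λ units, variability exponent γ and
coefficient c):

* *one-species consistency range* — the union of the per-species 95%
  confidence intervals; a model outside it is rejected by every species;
* *common-design consistency range* — the 95% bootstrap interval of the
  pooled data; the stricter test of the universal design.

The sweep driver runs the full pipeline (mosaic → map → threshold/smooth →
wavelet Λ → pinwheel statistics → verdicts) over grids of disorder
parameters, with all randomness derived from one master seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import analytic_moire, map_analysis, mosaics, wiring_model

__all__ = [
    "ConsistencyRanges",
    "TABLE_REFERENCE",
    "SweepConfig",
    "assess_consistency",
    "overall_verdict",
    "squared_histogram_deviation",
    "simulate_disordered_map",
    "map_common_design_stats",
    "run_disorder_sweep",
]

PARAMETERS = ("rho", "nn_any", "nn_same", "nn_opposite", "gamma", "c")


@dataclass(frozen=True)
class ConsistencyRanges:
    """Ensemble averages with nested consistency intervals per parameter.

    ``common_design[p] ⊆ one_species[p]`` holds for every parameter; both
    intervals are closed (endpoint values count as inside).
    """

    ensemble_average: dict
    common_design: dict
    one_species: dict

    def __post_init__(self) -> None:
        for p in PARAMETERS:
            lo_cd, hi_cd = self.common_design[p]
            lo_os, hi_os = self.one_species[p]
            if not (lo_os <= lo_cd <= hi_cd <= hi_os):
                raise ValueError(
                    f"common-design interval for {p} not nested in the "
                    f"one-species interval"
                )


#: Reference layout statistics of the five-hemisphere-set analysis
#: (ferret, dark-reared ferret, cat, tree shrew, galago): grand ensemble
#: average, common-design consistency range and one-species consistency
#: range for each of the six layout parameters.  These are embedded
#: experimental constants, not recomputed by this package.
TABLE_REFERENCE = ConsistencyRanges(
    ensemble_average={
        "rho": 3.14, "nn_any": 0.359, "nn_same": 0.525,
        "nn_opposite": 0.396, "gamma": 0.40, "c": 1.05,
    },
    common_design={
        "rho": (3.09, 3.19), "nn_any": (0.344, 0.357),
        "nn_same": (0.506, 0.522), "nn_opposite": (0.387, 0.399),
        "gamma": (0.37, 0.42), "c": (0.99, 1.11),
    },
    one_species={
        "rho": (2.93, 3.42), "nn_any": (0.334, 0.381),
        "nn_same": (0.499, 0.556), "nn_opposite": (0.366, 0.428),
        "gamma": (0.34, 0.58), "c": (0.68, 1.19),
    },
)

VERDICTS = ("common_design", "one_species_only", "inconsistent")


def assess_consistency(
    stats: map_analysis.CommonDesignStats,
    ranges: ConsistencyRanges = TABLE_REFERENCE,
) -> dict:
    """Interval-membership verdict per layout parameter.

    ``common_design`` if the value lies in the common-design range,
    ``one_species_only`` if only in the one-species range, else
    ``inconsistent``.  Intervals are closed.  A missing (NaN) parameter
    raises ``ValueError`` naming it.
    """
    values = stats.as_dict()
    out = {}
    for p in PARAMETERS:
        v = values[p]
        if v is None or not math.isfinite(v):
            raise ValueError(f"missing layout parameter: {p}")
        lo_cd, hi_cd = ranges.common_design[p]
        lo_os, hi_os = ranges.one_species[p]
        if lo_cd <= v <= hi_cd:
            out[p] = "common_design"
        elif lo_os <= v <= hi_os:
            out[p] = "one_species_only"
        else:
            out[p] = "inconsistent"
    return out


def overall_verdict(per_parameter: dict) -> str:
    """Weakest per-parameter verdict."""
    order = {v: i for i, v in enumerate(VERDICTS)}
    return max(per_parameter.values(), key=lambda v: order[v])


def squared_histogram_deviation(model_hist, reference_hist) -> float:
    """Σ over bins of (model − reference)² for unit-mass histograms."""
    m = np.asarray(model_hist, dtype=float)
    r = np.asarray(reference_hist, dtype=float)
    if m.shape != r.shape:
        raise ValueError("histograms must share binning")
    m = m / m.sum() if m.sum() > 0 else m
    r = r / r.sum() if r.sum() > 0 else r
    return float(np.sum((m - r) ** 2))


# ---------------------------------------------------------------------------
# end-to-end simulation of one disordered-mosaic layout

@dataclass(frozen=True)
class SweepConfig:
    """Parameter grids and numerical settings of a disorder sweep.

    ``etas`` are disorder strengths; ``correlation_lengths`` (units of the
    lattice constant) empty/None for uncorrelated jitter.  Map size and
    resolution are expressed in expected column spacings Λ_c.
    """

    etas: tuple = (0.02, 0.05, 0.1, 0.2, 0.3)
    correlation_lengths: tuple | None = None
    n_realizations: int = 5
    seed: int = 0
    r_um: float = 170.0
    delta_alpha_deg: float = 7.0
    sigma_r_um: float = 70.0
    sigma_s_um: float = 20.0
    extent_lambda: float = 10.0
    px_per_lambda: int = 32
    osi_threshold: float = 0.25
    smooth_sd_lambda: float = 0.15
    boundary_margin_lambda: float = 0.5
    fermi_low_lambda: float = 0.5
    fermi_high_lambda: float = 2.0
    wavelet_margin_lambda: float = 1.0
    n_wavelet_scales: int = 14
    sd_areas: tuple = tuple(np.geomspace(1.0, 16.0, 10))
    sd_samples: int = 100

    def __post_init__(self) -> None:
        if self.n_realizations < 1:
            raise ValueError("need at least one realization per grid point")
        if len(self.etas) == 0:
            raise ValueError("empty disorder grid")

    def moire_params(self) -> analytic_moire.MoireParams:
        d = math.radians(self.delta_alpha_deg)
        return analytic_moire.MoireParams(
            r=self.r_um, r_prime=self.r_um,
            alpha=-d / 2.0, alpha_prime=d / 2.0,
            sigma_r=self.sigma_r_um, sigma_s=self.sigma_s_um,
        )


def simulate_disordered_map(
    cfg: SweepConfig,
    eta: float,
    correlation_length: float | None,
    seed,
) -> tuple[wiring_model.TuningMap, wiring_model.TuningMap, float]:
    """One realization: mosaic → unfiltered map → thresholded/smoothed map.

    Returns ``(unfiltered, smoothed, lambda_c_mm)``.
    """
    params = cfg.moire_params()
    _, lam_um = analytic_moire.moire_geometry(params)
    lam_mm = lam_um / 1000.0
    wparams = wiring_model.WiringParams(sigma_r=cfg.sigma_r_um,
                                        sigma_s=cfg.sigma_s_um)
    grid = wiring_model.CorticalGrid.square(
        extent_mm=cfg.extent_lambda * lam_mm,
        px_per_mm=cfg.px_per_lambda / lam_mm,
    )
    margin = wiring_model.required_margin_um(wparams)
    # extra jitter headroom so displaced cells still cover the window
    jitter_pad = 6.0 * eta * cfg.r_um
    half = cfg.extent_lambda * lam_um / 2.0 + margin + jitter_pad
    window = mosaics.Rect.centered(2.0 * half)
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    s_on, s_off = ss.spawn(2)
    mosaic = mosaics.hexagonal_pair(
        params.r, params.r_prime, params.alpha, params.alpha_prime, window
    )
    if eta > 0:
        if correlation_length is None:
            spec = mosaics.DisorderSpec(eta=eta, seed=s_on)
            mosaic = mosaics.apply_uncorrelated_jitter(mosaic, spec, cfg.r_um)
        else:
            spec = mosaics.DisorderSpec(eta=eta,
                                        correlation_length=correlation_length,
                                        seed=s_on)
            mosaic = mosaics.apply_correlated_jitter(mosaic, spec, cfg.r_um)
    unf = wiring_model.compute_unfiltered_map(mosaic, grid, wparams)
    sm = wiring_model.threshold_and_smooth(
        unf, osi_threshold=cfg.osi_threshold,
        lambda_expected_mm=lam_mm, kernel_sd_lambda=cfg.smooth_sd_lambda,
    )
    return unf, sm, lam_mm


def map_common_design_stats(
    smoothed: wiring_model.TuningMap,
    lambda_expected_mm: float,
    cfg: SweepConfig,
    seed,
) -> tuple[map_analysis.CommonDesignStats, float]:
    """Wavelet Λ plus full common-design statistics of one smoothed map.

    Mirroring the analysis of experimental maps, the field is first Fermi
    band-passed with cutoff wavelengths adapted to the expected column
    spacing (``fermi_low_lambda·Λ`` to ``fermi_high_lambda·Λ``) so that
    structure on the columnar scale is weakly attenuated while the
    large-scale magnitude envelope of the thresholded field — which carries
    no columnar information — is removed.  The wavelet spacing estimate and
    the pinwheel detection both operate on the band-passed field; pixels
    within ``boundary_margin_lambda · Λ`` of the edge are excluded from the
    pinwheel statistics.  Returns ``(stats, lambda_measured_mm)``.
    """
    px = smoothed.grid.pixel_size_mm
    z_an = map_analysis.fermi_bandpass(
        smoothed.z, px,
        cfg.fermi_low_lambda * lambda_expected_mm,
        cfg.fermi_high_lambda * lambda_expected_mm,
    )
    span = min(cfg.fermi_high_lambda, cfg.extent_lambda / 4.0)
    wcfg = map_analysis.WaveletConfig.around(
        lambda_expected_mm, n_scales=cfg.n_wavelet_scales, span=span
    )
    interior = smoothed.interior_mask(cfg.wavelet_margin_lambda
                                      * lambda_expected_mm)
    _, lam_meas = map_analysis.local_column_spacing(
        z_an, px, wcfg, valid_mask=interior
    )
    margin_mm = cfg.boundary_margin_lambda * lam_meas
    x0 = smoothed.grid.x_mm[0]
    y0 = smoothed.grid.y_mm[0]
    pws = map_analysis.find_pinwheels(
        z_an, pixel_size=px, spacing=lam_meas,
        margin=margin_mm, origin=(x0, y0),
    )
    ext = (x0 + margin_mm, smoothed.grid.x_mm[-1] - margin_mm,
           y0 + margin_mm, smoothed.grid.y_mm[-1] - margin_mm)
    region_lam2 = (ext[1] - ext[0]) * (ext[3] - ext[2]) / lam_meas**2
    sd_areas = np.asarray(cfg.sd_areas, float)
    # cap subregion areas at a quarter of the (measured-Λ) analysis region
    cap = region_lam2 / 4.0
    sd_areas = np.geomspace(sd_areas.min(), min(sd_areas.max(), cap),
                            len(sd_areas))
    stats = map_analysis.common_design_stats(
        pws, ext, sd_areas=sd_areas,
        n_samples=cfg.sd_samples, seed=seed,
    )
    return stats, lam_meas


def plot_sweep_summary(df: pd.DataFrame, path,
                       ranges: ConsistencyRanges = TABLE_REFERENCE) -> None:
    """Panel figure of the six layout parameters vs disorder strength.

    Means ± SD over realizations per grid point, one line per correlation
    length, with the consistency ranges shaded.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ok = df[df["error"] == ""]
    fig, axes = plt.subplots(2, 3, figsize=(12, 7), sharex=True)
    for ax, p in zip(axes.ravel(), PARAMETERS):
        lo_os, hi_os = ranges.one_species[p]
        lo_cd, hi_cd = ranges.common_design[p]
        ax.axhspan(lo_os, hi_os, color="lightgreen", alpha=0.4, lw=0)
        ax.axhspan(lo_cd, hi_cd, color="green", alpha=0.35, lw=0)
        for xi, grp in ok.groupby("xi", dropna=False):
            agg = grp.groupby("eta")[p].agg(["mean", "std"])
            label = "uncorrelated" if pd.isna(xi) else f"ξ = {xi:g} r"
            ax.errorbar(agg.index, agg["mean"], yerr=agg["std"],
                        marker="o", capsize=2, label=label)
        ax.set_title(p)
        ax.set_xlabel("disorder strength η")
    axes[0, 0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_disorder_sweep(cfg: SweepConfig) -> pd.DataFrame:
    """Run the full pipeline over the disorder grid.

    One row per (η, correlation length, realization) with the six layout
    parameters, the measured column spacing, pinwheels per mm², the
    per-parameter verdicts and the realization seed.  Failures at single
    grid points are recorded (``error`` column) and the sweep continues.
    """
    xis: tuple = (None,) if not cfg.correlation_lengths \
        else tuple(cfg.correlation_lengths)
    rows = []
    for i_eta, eta in enumerate(cfg.etas):
        for i_xi, xi in enumerate(xis):
            for real in range(cfg.n_realizations):
                # deterministic per-task key: grid indices + realization
                child = np.random.SeedSequence(
                    entropy=cfg.seed, spawn_key=(i_eta, i_xi, real),
                )
                s_map, s_stats = child.spawn(2)
                row = {"eta": eta, "xi": np.nan if xi is None else xi,
                       "realization": real,
                       "seed_key": str(child.spawn_key), "error": ""}
                try:
                    _, sm, lam_mm = simulate_disordered_map(cfg, eta, xi,
                                                            s_map)
                    stats, lam_meas = map_common_design_stats(
                        sm, lam_mm, cfg, s_stats
                    )
                    verdicts = assess_consistency(stats)
                    row.update(stats.as_dict())
                    row["lambda_c_mm"] = lam_mm
                    row["lambda_measured_mm"] = lam_meas
                    n_hc = stats.extras["n_pinwheels"]
                    row["n_pinwheels"] = n_hc
                    row["pinwheels_per_mm2"] = (
                        stats.rho / lam_meas**2 if lam_meas > 0 else np.nan
                    )
                    for p, v in verdicts.items():
                        row[f"verdict_{p}"] = v
                    row["verdict_overall"] = overall_verdict(verdicts)
                except Exception as exc:  # noqa: BLE001 - sweep continues
                    row["error"] = f"{type(exc).__name__}: {exc}"
                rows.append(row)
    return pd.DataFrame(rows)
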