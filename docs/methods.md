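# Methods

`moiremap` implements a statistical (random feedforward) wiring model of
orientation preference maps in primary visual cortex, together with the
full "common design" pinwheel-statistics pipeline used to test such models
against the species-invariant layout laws of V1 iso-orientation domains.
This note records the model, the numerical choices, and what the synthetic
data do and do not establish.

## The model

ON- and OFF-center retinal ganglion cells (RGCs) are point patterns in the
retinal plane (coordinates in μm, origin at the window center). A model V1
neuron at cortical position **y** (magnification 1 mm cortex / mm retina by
default) pools RGC inputs with Gaussian synaptic weights and each RGC
contributes a Gaussian receptive field of width σ_r with its polarity sign:

    RF_y(x) = Σ_j ± w_j(y) exp(−|x_j − x|²/2σ_r²),
    w_j(y)  = exp(−|x_j − y|²/2σ_s²).

With σ_s (20 μm) well below the RGC spacing (170 μm), most units are
dominated by one adjacent ON–OFF pair and prefer the edge orientation
perpendicular to that dipole. Responses are linear (no output
nonlinearity); tuning is read from the receptive-field amplitude spectrum
|R_y(k)|: preferred orientation from the spectral center of mass of the
second angular harmonic, preferred spatial frequency by the spectral
maximum (default; center-of-mass and CV-maximization estimators are also
provided), and OSI as the normalized second harmonic of the tuning curve on
the preferred ring.

Angle convention: θ is the preferred *edge* orientation throughout
(perpendicular to the preferred wave vector), folded to [0, π). The complex
map view is z = OSI·e^{2iθ}. The closed-form layouts are phase-shifted
accordingly; all comparison statistics are invariant under this global
choice.

### Closed forms for perfect lattices

For ON/OFF cells on perfect hexagonal lattices (constants r, r′, rotations
α, α′) every receptive field is an infinite Gaussian lattice sum, evaluated
exactly by splitting each hexagonal lattice into two rectangular
sublattices and factorizing each into products of Jacobi Θ₃/Θ₄ series
(truncated at 1e-15, complex arguments supported). The same factorization
on the Fourier side gives the exact amplitude spectrum. Both forms are
validated against brute-force lattice sums to ~1e-15 relative error; that
cross-check (plus an mpmath theta oracle in the tests) resolved the
typography of the published prefactors.

Moiré interference of the two lattices produces a superlattice of scaling
factor S = (1+β)/√(β² + 2(1−cos Δα)(1+β)) (β = r′/r − 1) and column
spacing Λ_c = (√3/2)·S·r; at the standard parameters (r = r′ = 170 μm,
Δα = 7°) S = 8.19 and Λ_c = 1.206 mm. Two analytic layouts are provided:

* the **unfiltered** layout: principal axis of the Hessian of |G(k)|² at
  k = 0 (G is the non-rotationally-symmetric structure factor; Hessian by
  central differences with step 1e-3·k_c, degenerate points → NaN);
* the **smoothed** layout: the six lowest Moiré modes (all |k| = k_c) with
  their exact phase factors u_j built from u₀. Its pinwheel crystal has a
  double (charge +1) zero on each superlattice site and two charge −½
  zeros at the triangle centers: 2√3 ≈ 3.46 pinwheels per Λ_c². The √3·k_c
  modes have undetermined phases and are excluded.

The exact Hessian layout is only quasi-periodic (two lattices at generic
relative angle share no finite period); the six-mode field is exactly
periodic, which the analysis exploits for boundary-free pinwheel counting
on commensurate rectangles.

## Synthetic mosaics

* Perfect hexagonal lattices (origin always a lattice point).
* Uncorrelated jitter: i.i.d. Gaussian offsets, per-component SD η·r; ON
  and OFF displaced independently.
* Correlated jitter: displacements read from two independent complex
  Gaussian random fields (spectral synthesis; Gaussian autocorrelation of
  length σ_corr·r, unit variance per component in expectation, bilinear
  interpolation at cell positions on a grid of step ≤ σ_corr/8).
* PIPP: fixed-count Metropolis sampling of a pairwise-interaction density
  with hard exclusion δ and soft interaction h(d) = 1 − exp(−((d−δ)/φ)^α)
  per polarity; ON and OFF fully independent. The source construction's
  parameter values are not published; the defaults (δ = 80 μm, φ = 60 μm,
  α = 2, 40 cells/mm², 20 sweeps) give regularity indices ≈ 6
  ("regularly spaced") at hexagonal-equivalent density and are exposed for
  refitting.

Mosaics are generated with a margin of 4σ_s + 3σ_r beyond the cortical
window (plus jitter headroom), bounding lattice-sum truncation below 1e-8.

What the generators emulate: positional statistics of semi-regular RGC
mosaics and their coarse disorder. What they do not: soma/RF size
correlations, ON/OFF density asymmetries, eccentricity gradients,
photoreceptor or LGN stages, cross-polarity interactions. Passing tests
therefore validate the model pipeline, not retinal realism.

## Map computation

Because each RGC field is Gaussian, |R_y(k)| is evaluated in closed form
per pixel directly from the contributing cells (those within 5.5σ_s) on a
polar grid (defaults 12 orientations × 16 frequencies up to
3.5/√(σ_r²+σ_s²)); no per-pixel FFT is needed, and a windowed-FFT route
(`cortical_rf` + `rf_tuning`) is kept and cross-validated against it.
Tuning quantities are insensitive to refining the polar grid (checked to
48×48). Default resolution is ≥ 32 px/Λ; quantities are reported at the
resolution where they are stable (see "Known limitations").

The smoothed stage masks z at OSI ≤ 0.25 and convolves the masked complex
field with an isotropic Gaussian. The smoothing width is not published; the
default 0.15·Λ_c is the smallest width at which the smoothed crystalline
map's spectrum is dominated by the six k_c modes in a documented scan
(√3k_c-to-k_c peak ratio 0.8 → 0.4 over widths 0.05–0.25 Λ). Smoothing the
masked complex field (rather than θ or a binary mask) is the only
self-consistent choice for circular data with a selectivity magnitude.

## Analysis pipeline

Model maps are analyzed like experimental ones:

1. **Fermi band-pass** with cutoff wavelengths adapted to the expected
   spacing ([0.5Λ, 2Λ] by default; steepness 5% of each cutoff; DC
   removed). This removes the large-scale magnitude envelope of the
   sparse thresholded field, which carries no columnar information but
   otherwise contaminates scale estimation.
2. **Column spacing** by complex Morlet wavelets (envelope σ = ξΛ/2π,
   ξ = 7, 16 orientations over [0, π)): per pixel the scale with the
   largest orientation-averaged coefficient modulus, with parabolic
   sub-scale interpolation; mean over the interior (1Λ margin). Kernels
   are compared across scales at unit plane-wave gain: the printed 1/σ
   spatial prefactor makes the family L2-normalized, under which a pure
   tone's response grows ∝ σ and the argmax is biased toward large scales
   on nearly periodic maps; the unit-gain convention is calibrated on
   plane waves (exact recovery) and the crystalline layout (within 2%).
   An "l2" option retains the literal normalization.
3. **Pinwheels** as phase singularities: plaquette winding of arg z
   (wrap-around when periodic), sub-pixel localization by solving the
   bilinear interpolant, charge = winding/2. Same-sign detections within
   2 px merge into degenerate (±1) pinwheels, flagged low-confidence, as
   are detections with another singularity within 1 px; counting weight is
   2|charge|. Pinwheels within 0.5Λ of a non-periodic map edge are
   excluded.
4. **Statistics**: density ρ per Λ²; NN distances by charge class in Λ
   units (periodic boxes use toroidal metrics; histograms at 0.05Λ bins
   over [0, 1.5Λ]); SD(A) from uniformly placed circular subregions
   (seeded), fitted as log SD = log(cρ) − γ log A. The crystal's SD(A)
   oscillates around its A^{−3/4} law on few-cell scales, so γ is fitted
   over two decades ([1, 256] Λ² on a ≥64Λ pattern); narrower ranges bias
   γ low by ~0.05.
5. **Comparisons**: circular difference d = ½|arg e^{2iΔ}| ∈ [0°, 90°];
   cross-correlation as Pearson correlation of the concatenated real and
   imaginary parts of the mean-removed complex fields (phase-only variant
   `theta_cross_correlation` provided; the definition behind the published
   coefficients is not stated).

## Gaussian random field ensembles

The band-pass family f(k) = a|k|^β e^{−k²/b} is normalized by
∫₀∞ f dk = 1 and k̄ = ∫₀∞ k f dk = 1 (equivalently ∫f d²k = 2π), solved in
closed form: √b = Γ((β+1)/2)/Γ((β+2)/2). The two printed normalization
conditions are mutually inconsistent as rendered; this reading is the
unique one that reproduces the published consistency threshold β* = 17
through the Gaussian zero-density law ρ(β) = π·∫k³f/∫kf (monotone in β,
→ π in the narrow-band limit; π² at β = 0). GRF samples shape complex
white amplitudes by √f so the sample power spectrum equals f; densities
are measured per filter-defined Λ = 2π/k̄ on periodic 512² grids spanning
22Λ.

Broadband (PIPP-derived) layouts are band-passed by whitening the
thresholded field's annulus-averaged power and imposing √f, so the result
carries exactly the filter's power profile ("matched marginal spectra");
the comparison with GRF densities then probes the layout's phase
statistics. In the band-pass regime (β ≳ 5) filtered-PIPP and GRF
densities agree within a few percent; at β ≈ 0 the filtered field remains
strongly non-Gaussian (the Gaussian low-pass mixes only ~80 μm of the
sparse inter-dipole bands; excess kurtosis ≈ 4.6) and its zero density
falls well below the Gaussian prediction — the GRF equivalence is a
band-pass statement here.

## Reference constants and sweeps

The six common-design layout parameters (ρ, three mean NN distances in Λ
units, γ, c) are embedded with their grand averages, common-design 95%
ranges and one-species consistency ranges; they are reference constants
of the five-species imaging analysis, not recomputed. Verdicts use closed
intervals; the overall verdict is the weakest per-parameter one.

Sweeps derive every task's randomness from one master seed via
SeedSequence spawn keys indexed by grid position and realization, so
partial reruns reproduce bit-identically. Default problem sizes (10×10 Λ
maps at 32 px/Λ, 5 realizations per grid point, 512² GRF grids with 20
realizations per β) were chosen as the smallest at which the reported
statistics are stable at the few-percent level.

## Results the pipeline reproduces

At the standard parameters: S = 8.2; crystalline ρ = 2√3 (exact on
periodic grids) with all NN distances (2/3)Λ_c; crystal γ = 0.75 ± 0.01;
one fifth of positions differ by > 45° between unfiltered and smoothed
analytic layouts; GRF densities fall to the one-species bound only at
β ≈ 17; the correlated-disorder grid (η ∈ [0.05, 0.4] × σ_corr ∈ {2, 5,
10} r) shows a density plateau of ≈ 3.3–3.6 per measured Λ² rising with
disorder, an approximately constant absolute pinwheel count, and no grid
point that is common-design consistent — the central negative result.

## Known limitations

* The converged numerical-vs-analytic agreement is *stronger* than the
  published coefficients: the unfiltered map correlates ≈ 0.96 with the
  Hessian layout (published 0.9) and the smoothed map ≈ 0.89 with the
  six-mode layout at 64 px/Λ (published 0.6). The values are stable under
  refinement of the tuning grids, map extent and metric variant; a
  windowed-FFT tuning route reproduces lower coefficients at coarse
  windows and converges to the direct route, and the smoothed-map
  coefficient passes through 0.6 only at 32 px/Λ. We therefore attribute
  the published values to discretization details of the original
  implementation that are not recorded, and report the converged numbers.
* The residual wavelet Λ bias at weak disorder is ≈ −1 to −3%, deflating
  plateau densities by ≈ 2–5% (3.3–3.6 measured vs 3.46 ideal).
* Pinwheel counts of thresholded-and-smoothed maps converge slowly with
  map resolution (the high-OSI bands are thin); per-Λ_c² counts are exact
  for the analytic layouts and stable for the band-passed analysis stage,
  but raw smoothed-stage counts at 32 px/Λ run a few percent high.
* The PIPP sampler is a conditional (fixed-count) Metropolis scheme with a
  finite sweep budget; an acceptance-rate warning flags
  under-equilibration but no formal convergence diagnostic is run.
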