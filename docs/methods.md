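# Methods

This note records the models behind each module, the defaults that
matter, the choices made where the design was genuinely open, and what
the synthetic tests do and do not demonstrate.

## Whispering-gallery modes (`dsli.wgm`)

A dielectric sphere of diameter d, internal index n₁ and surrounding
index n₂ supports whispering-gallery resonances where the internal field
(regular Riccati–Bessel function ψ_l) matches an evanescent external
field across the surface.  Matching tangential fields gives one
characteristic equation per polarization and angular order l:

- TE: n₁ ψ′_l(x₁) χ_l(x₂) − n₂ ψ_l(x₁) χ′_l(x₂) = 0
- TM: n₂ ψ′_l(x₁) χ_l(x₂) − n₁ ψ_l(x₁) χ′_l(x₂) = 0

with x₁ = πdn₁/λ, x₂ = πdn₂/λ and χ_l the Riccati–Neumann function.
Using χ in place of the outgoing Hankel function is the standard high-Q
approximation: it makes the eigenvalue problem real, with an error of
order the resonance linewidth (≪ 1 pm at Q ≳ 10⁴, and far below the
0.023 nm spectrometer resolution for every mode considered here).  The
cross-multiplied form above is pole-free, so sign changes in λ are
exactly the eigenmodes.

**Radial-order labelling.**  For each l the scan starts at the
angular-momentum cutoff x₁ = l + ½ (above which no confined mode exists,
and below which the residual provably has no sign change until the first
root) and proceeds downward in λ with a 0.05 nm bracketing grid — safe
against the ≈3.6 nm free spectral range — followed by Brent polishing to
below 10⁻⁶ nm.  The q-th sign change is the q-th radial mode.  Default
`max_radial_order = 2`: higher orders have low Q and are not observed in
measured peak lists.  Scan economics: the angular-order loop terminates
once the Airy-zero estimate of the deepest requested radial order rises
above the window.

**Multilayer spheres.**  Coated beads are solved by a transfer matrix:
the field in each layer is b·ψ + c·χ in that layer's optical coordinate,
coefficients propagated outward by matching ψ/χ amplitudes and
η-weighted derivatives (η = n for TE, 1/n for TM) at every interface,
with per-interface renormalization against overflow.  A confined mode
has no ψ component outside, so the outer b coefficient is the residual.
Both degenerate limits (coating index equal to the surroundings, coating
index equal to the core) reduce to the bare solver to 10⁻⁶ nm.

**Dispersion.**  Indices are treated as wavelength-independent over the
~40 nm analysis window; the polystyrene default is n = 1.59.  Fit
accuracy statements are defined on synthetic data generated with the
same convention, so the treatment is self-consistent; absolute accuracy
against a dispersive instrument would require the instrument's own
dispersion model.  All wavelengths are vacuum wavelengths in nm.

**FSR sizing.**  Adjacent modes of one family are equally spaced in 1/λ
with spacing FSR = 1/(πn₁d) to leading order; at the size parameters
used here (x ≈ 140) the curvature correction from the Airy-zero
expansion is ~2.3%, so `size_from_fsr` refines the analytic inversion
against the spacing of exactly computed modes.  Residual error is then
dominated by which family the comb belongs to (TE is assumed; a TM comb
costs ~4×10⁻⁴ relative).  With a handful of teeth this sizing carries a
~6 nm class accuracy — the documented fallback when a comb is too sparse
for the full fit.

**(d, n_ext) fitting.**  The measured comb is overlapped with
theoretical positions over a search region by a coarse grid
(Δd = 5 nm, Δn = 5×10⁻⁴) followed by Nelder–Mead refinement, with mean
absolute mismatch over a greedy one-to-one nearest assignment as the
metric (ties to the shorter wavelength).  Two implementation points:

1. *Seeding.*  The residual landscape in d is multimodal with a period of
   one comb tooth (~105 nm in d), so the diameter is first pinned by a
   mixed-comb FSR estimator: all pairwise 1/λ differences are scored
   against integer multiples of candidate spacings, weighted by the
   inverse multiple so sub-harmonics cannot win.  The ±30 nm seeded
   region excludes the aliases.
2. *Speed.*  Mode positions scale exactly linearly with d at fixed
   indices, so a single reference-diameter table of mode wavelengths
   versus n_ext (cubic splines over 13 grid points) serves the whole
   coarse grid; only the final polish evaluates the exact characteristic
   equation, via vectorized bisection at the already-assigned (l, q)
   labels.

Identifiability: d and n_ext move the comb in nearly the same way
(correlation −0.99); what breaks the degeneracy is the differential
TE/TM and q = 1/2 response.  For a 500–540 nm comb with peak noise of
0.01 nm the resulting least-squares bound is ~0.3 nm in d and ~3.6×10⁻⁴
in n_ext; the fit operates within a factor ~1.5 of that bound.  A fit
with residual > 0.1 nm or fewer than 4 peaks reports
`status="underdetermined"` and falls back to FSR-only sizing.

## Spectral unmixing (`dsli.unmix`)

The fluorescence background (the dye emission common to all beads) is
estimated by asymmetric least squares — a smoothness-penalized baseline
in which points above the baseline get weight 10⁻³ — solved with a
banded Cholesky factorization so a 1600-sample spectrum costs well under
a millisecond, and whole cubes can be processed per pixel.  No
non-negativity clipping is applied.

Peaks are local maxima above a prominence threshold, each refined by a
Lorentzian + offset fit over ±5 grid points (peaks are ~3 points wide at
Q ≈ 7000 and 0.023 nm sampling); non-convergence keeps the raw maximum,
flagged.  Comb assignment follows the propagation rule: for each peak i
and each partner j within the physically plausible FSR range (from the
8–22 μm diameter range), the spacing |1/λᵢ − 1/λⱼ| is propagated across
the spectrum and scored by the number of observed peaks reproduced
within the matching tolerance; the best-supported spacing wins, ties to
the smaller FSR, and support below `min_support = 4` leaves the peak
unassigned.  The matching tolerance defaults to half the spectrometer
resolution expressed in 1/λ; it presumes peak-centering jitter below
that scale (at jitter equal to the tolerance, comb identification
degrades for any tolerance choice — an identifiability limit, not an
algorithmic one).

Groups are formed by transitive clustering of assigned peaks that agree
in FSR and comb phase, then refined: the cluster's comb model (anchor
and spacing) is re-estimated by least squares over its members, because
pairwise spacing estimates are quantized and an anchored comb drifts at
the window edges.  A final sweep claims every peak consistent with the
refined comb — membership is deliberately non-exclusive, since combs
genuinely share coincident teeth.  Merged combs whose generating
diameters differ by less than the peak width in wavelength (~3 nm in
diameter) are flagged `unresolvable` when the member scatter betrays a
blend.  TE/TM pairing merges two groups with essentially equal FSR but
offset phase; among candidates the closest FSR wins (the two
polarization families of one sphere share the FSR essentially exactly,
chance alignments only within tolerance), with an optional
characteristic-equation verification (`verify_n_internal`) that rejects
pairs whose joint comb does not fit one sphere.  Missing teeth inside
the window are predicted from the comb model (`fill_missing_peaks`).

## Hyperspectral localization (`dsli.hsi`)

Cubes are (y, x, λ) arrays with pixel-center coordinates in μm (x right,
y down, origin at the first pixel), readable/writable as HDF5
(`/cube`, `/axes/*`) and ENVI (text header + BSQ/BIL raw, lossless for
integer counts).  `bin_cube` emulates the fast-scan acquisition by
integer binning; binning commutes with localization within a pixel.

An intensity map at one resonance is the background-subtracted cube
integrated over a band of 3 spectral samples (~0.07 nm, matching the
linewidth at Q ≈ 7000).  On top of the per-pixel baseline removal, a
*sideband* correction subtracts the per-pixel median of up to six
flanking off-resonance bands — skipping any band that overlaps a known
detected peak — which removes residual smooth light from the other
emitters without biasing the footprint shape (a bead's own Lorentzian
tails are proportional to its own footprint).

Localization fits a rotated 2D Gaussian.  For footprint slices the
offset is fixed at zero: the baseline genuinely is zero after
subtraction, and on a footprint wider than the field a free offset is
nearly degenerate with the width and lets noise pull the center.  Fit
quality is the rms residual relative to the rms of the fitted blob;
above 0.2 the fit is flagged `poor` (a two-blob map at 3σ separation
scores ~0.27, noisy single blobs ≤ 0.15).  Per-peak centers are combined
by amplitude-weighted averaging after a median/MAD rejection of
contaminated slices; the center scatter is the reported uncertainty.
Multi-peak averaging measurably beats any single-peak fit on noisy
fixtures (factor ~5 in the shipped test scene).

**Width and depth.**  Three width metrics are supported and must be used
consistently between calibration and query: Gaussian σ averaged over
four directions through the center (default), its FWHM variant, and
`gauss2d` — the mean σ of the offset-free 2D Gaussian model fit.  The
direction-profile metrics match how widths are naturally measured on
centered calibration maps; `gauss2d` is the right choice when footprints
sit off-center in a finite field, where edge padding inflates 1D
profiles but a truncated model fit stays unbiased.  The 1D profile fits
are bounded (width ≤ twice the field half-extent, offset within the data
range): on truncated noisy profiles an unconstrained width/offset pair
can run away together.  Depth is read off a strictly monotone
(depth, width) calibration curve by shape-preserving PCHIP
interpolation; out-of-range queries clamp with a warning.

## Photon transport (`dsli.mc`)

Standard photon-packet Monte Carlo in a laterally infinite layer:
exponential free paths with μ_t = μ_s + μ_a, absorption by weight with
survival roulette (threshold 10⁻⁴, survival 0.1), Henyey–Greenstein
scattering by closed-form inverse CDF (or inverse-CDF sampling of a
Mie-tabulated phase function), and unpolarized Fresnel
reflection/refraction at the index-mismatched top (air, n = 1.0) and
bottom (mounting polymer, n = 1.34) boundaries.  The kernel is a numba
routine; a million photons in the standard phantom take tens of seconds
on one core.  Tallies: a binned surface map of top-exiting photons
(5 μm bins, matched to the camera pixel scale; optionally restricted to
a collection NA), total top/bottom exit weights, absorbed weight, and
ballistic bottom transmittance.  Energy closes to 10⁻⁹ by construction,
and identical seeds reproduce identical tallies.

Geometries: `slab_overlayer` (isotropic source at the bottom face of a
finite slab, transparent beneath — the bead-under-phantom arrangement)
and `embedded` (the medium continues below the source, so backscattered
light returns).  The embedded footprint at 2.3 l* comes out ~28% wider
than the overlayer footprint at equal optical depth under converged
settings: surface-map half-extent 1500 μm (the heavy diffuse tails bias
a Gaussian width low at smaller extents; widths change < 1–2% on further
growth), bottom margin 5 l* below the source (4–8 l* agree within
counting noise), 10⁶ photons.  The σ and FWHM metrics give the same
ratio.

Mie optics: a_n/b_n coefficients by downward logarithmic-derivative
recurrence with Wiscombe truncation; scattering cross-section, asymmetry
parameter g, and the tabulated cumulative phase function all agree
internally to < 1%.  The standard phantom (0.51 μm polystyrene in PDMS,
n = 1.60/1.41 at 532 nm) gives g = 0.875; μ_s follows from the number
density under the independent-scattering assumption (warned above 10%
volume fraction).  Default μ_a = 0.2 mm⁻¹.

The integrating-sphere simulation (collimated pencil beam, Fresnel faces
against air) reproduces the thin-slab limit (incoherent double-interface
reflectance) and conserves energy; inversion of measured (R, T) over a
(μ_s, g) grid recovers the transport-identifiable combination μ_s(1−g)
tightly while leaving the documented flat valley along it — the full
residual map is returned so the valley is visible.  One caution from
this implementation: with Fresnel/TIR boundaries, R and T react
substantially to μ_a even at small values (total internal reflection
multiplies path lengths), so absorption should be fixed from independent
knowledge rather than assumed negligible.

## Synthetic scenes (`dsli.synth`)

The generator emulates what the instrument records: bead diameters
~N(15 μm, (0.14·15)²) truncated at zero; external index by environment —
growth medium N(1.340, 0.001²) (stable well within 0.002 RIU), cytoplasm
N(1.370, 0.007²) (the spread consistent with a < 5% chance of two
separate cells agreeing within 0.0006), interstitial N(1.350, 0.003²)
(chosen between the two; no measured center is available); per-bead Q
uniform in 5000–10000; comb wavelengths from the exact solver
(`max_radial_order = 1` by default — the q = 2 modes are rarely
prominent in measured lists); Lorentzian lines with per-tooth amplitude
variation under a smooth dye envelope (Gaussian at 515 nm, 25 nm width);
footprints either full Monte Carlo maps or unit-peak Gaussians whose σ
comes from a calibration curve (fallback σ = 0.55·depth); a shared
smooth background proportional to the summed footprints; Poisson noise.
`peak_counts = 3000` sets the brightest tooth's per-pixel amplitude at
the footprint center — the quantity exposure time controls.

What the generator does **not** emulate: speckle and spatial
correlations of real diffuse light, tissue inhomogeneity (the medium is
laterally uniform), camera read noise and fixed-pattern artifacts, comb
amplitude structure from excitation geometry, and any bead-to-bead
variation of the internal index.  Passing tests on synthetic scenes
therefore demonstrate algorithmic correctness and noise robustness under
the stated statistical model, not instrument-level accuracy.

## Pipeline (`dsli.pipeline`)

`run_dsli` chains: per-pixel background subtraction → summed spectrum →
peak detection (prominence default: 6× the robust noise of the summed
spectrum; peaks below Q = 2000 are discarded — they overlap their
neighbours and carry too little wavelength precision) → FSR unmixing →
record gate → per-comb localization → depth → sizing → classification.

The record gate accepts combs largest-first when they have at least
`min_peaks_record = 6` teeth of which at least `min_exclusive_peaks = 4`
are not claimed by an already-accepted comb.  This rejects chance
alignments and harmonics (whose teeth are subsets of a denser parent
comb) without penalizing the parent, and implements the "good spectrum"
criterion behind recovery-rate statements: rates are reported relative
to this gate.  Localization prefers teeth exclusive to the comb (shared
teeth carry superposed footprints); depth uses the median width over all
per-peak fits when the calibration metric is `gauss2d`, else the
strongest-five slices.  Sizing walks the ladder full fit → FSR-only
(6 nm class) → unsized, each flagged.

Classification is nearest-class-center (defaults 1.340 / 1.370) with a
±0.002 dead band around the midpoint boundary — the stability scale of
the medium itself — returning `undetermined` inside it.  Same-cell
inference flags |Δn| < 0.003 and reports 1 − erf(|Δn|/2σ) as the
probability the pair is not a chance agreement of separate cells
(σ = 0.007 cell-to-cell).  Spatial proximity is logged but not used in
the default rule.  Tracking solves optimal bipartite assignment on
|Δdiameter| with links above 3 nm forbidden; a link with any competing
partner within tolerance is flagged ambiguous (greedy matching fails
exactly the designed collision fixture that motivates this).  Sensor
readout pairs comb teeth across conditions by nearest wavelength and
maps the mean shift through a linear calibration (e.g. −1.6 nm over
pH 2.8→6.6, or 44 pm/°C at 37 °C).

## Problem sizes in the shipped tests

Monte Carlo tests run 2×10⁴–2.5×10⁵ photons (the acceptance script runs
10⁶); calibration curves use 4–5 depths at 0.6–1.5×10⁵ photons; the
end-to-end scene is 5 beads in a 640 μm field (129×129×1305 cube) beneath
a uniform 1.9 l* phantom — the reference benchmark geometry — with depths
read against a `gauss2d` calibration built at the matching 320 μm map
half-extent.  Statistical cross-checks (pair indistinguishability,
same-cell probability) sample 10⁶–10⁷ draws.
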