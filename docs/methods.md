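# Methods

This note documents the models behind hemoflow, the defaults and why
they are what they are, the numerical choices, and the limits of what
the synthetic tests demonstrate.

## Flow model

Steady pressure-driven flow in a rectangular duct (width w = 2000 μm
across the flow, height h = 144 μm, aspect ratio h/w ≈ 0.072) is the
Fourier series with sine terms along the short dimension and
hyperbolic-cosine saturation along the width. That orientation
converges geometrically at this aspect ratio; 101 odd harmonics (the
default) are converged to machine noise for every quantity we use, and
51 already conserve flux to much better than 0.1%. The series prefactor
is fixed analytically by the exact flux integral of the series, so the
field carries the imposed volumetric rate without knowing the pressure
drop or viscosity. The cosh ratio is evaluated in exponential form to
avoid overflow at high harmonics. The solution is validated against an
independent sparse finite-difference Poisson solve (401 × 201 grid) to
< 0.5% of the maximum velocity everywhere.

Derived counting factors use the mid-height profile u(x, h/2), since
imaged cells ride near mid-height: the side-region width r_s is the
first crossing of (1 − 0.025)·u_max (root-bracketed, unique because the
profile rises monotonically from the wall), and the section means ū_c,
ū_s are adaptive quadratures over the center and side intervals.

**A discrepancy worth knowing about.** For this geometry the converged
series puts r_s at 170.53 μm; the historically quoted figure for the
same 2.5% criterion is 162.15 μm, which corresponds to a 3.0% deviation
on the exact profile or to an effective channel height of ~137 μm. No
variant we tried (z-averaged profile, transposed truncations, rescaled
normalizations) reproduces the quoted number; the real wet-etched
channel is trapezoidal with rounded edges, which the rectangular
idealization cannot capture. The package reports the first-principles
value and does not adjust toward the quoted one. Similarly, the quoted
mean fluid velocities (3.556 mm/s at 0.06 mL/min; 8.486 mm/s at
0.127 mL/min) exceed Q/A for the stated rectangle (3.472 and
7.35 mm/s); the solver computes from first principles and the quoted
values remain usable as explicit overrides, which is how the reference
multiplicities τ_c = 2.35, τ_s = 2.81, τ_c = 0.21 and the stream width
231.88 μm are reproduced.

## Synthetic imager

The generator emulates the study conditions, not arbitrary microscopy:

- **Population.** Volumes ~ N(90 fl, 13 fl), cHB ~ N(33 g/dL,
  2.2 g/dL) (normal adult ranges), radii by sphere inversion; optional
  platelets (strictly below the 9.5 μm² counting cut), leukocytes
  (above the RBC size range) and debris, all hemoglobin-free but weakly
  scattering.
- **Kinematics.** Cells enter at seeded times and advect at u(x, z)
  frame by frame; they are emitted into a frame while their center is
  inside the FOV, which makes the realized appearance count agree
  exactly in expectation with τ = l_FOV/(u·Δt). Laminar mode spreads
  cells over the 1801 μm cell sheath with a parabola-capped lateral
  count profile g(ξ) = 1 − 3(1 − δ)ξ², whose mean/max ratio equals the
  distribution factor δ (default 0.79); arrivals are drawn from
  g(x)·u(x) so that the snapshot count profile is g. Focused mode
  places cells uniformly across the stream width w_f from the flow
  model.
- **Optics.** Transmission: per-pixel transmittance 10^(−ε c d_chord/M)
  through the sphere chord; overlapping cells multiply. Phase:
  ΔΦ = (2π/λ)(n_HB0 + β·cHB − n_m)·chord; overlaps add. Pixels are
  point samples of the ideal image at 0.344 μm/px by default (512 × 384
  over the FOV); the sensor adds Gaussian read noise (σ = 60 counts on
  a 30000-count background) plus a shot term, and transmission frames
  quantize to 16 bit. Defocus: a cell at |z| beyond the depth of focus
  (0.49 μm transmission, 1.26 μm phase) is blurred with
  σ = 0.8 μm·(|z|/DOF − 1), optionally ringed with a single
  configurable diffraction ring (off by default).
- **Vertical spread.** z offsets are N(0, 1.2 μm) by default. The
  1.2 μm figure is a one-time calibration chosen so the transmission
  quality bank passes 30–50% of detected objects — the attrition regime
  of real recordings — and is not revisited per run.

What the generator does *not* emulate: coherent diffraction and
speckle, biconcave (unsphered) cells, margination and inertial lift,
the trapezoidal channel cross-section, tubing/valve transients.
Passing tests therefore demonstrate correctness of the analysis chain
under the sphere-and-laminar-flow model, not robustness to every
real-world artifact.

## Image pipeline

Stage order is fixed: background correction → fixed-threshold binary
mask → connected components (8-connectivity) → per-object features →
filters. Transmission background is a single cell-free frame; phase
background is the pixel-wise median of the first 11 frames (robust to a
transient cell in fewer than half of them). Thresholds are fixed per
run and recorded in the stage metadata: background median minus
max(4σ, floor) for transmission (σ estimated robustly by MAD from a
corrected frame, because the corrected frame carries √2 of the
background noise), and max(4σ, 0.3 rad) above background for phase.
Two floors coexist deliberately: photometric runs use a shallow 2%
floor so the mask tracks the geometric cell boundary, while counting
uses a deep 25% floor — RBC cores are essentially opaque at 425 nm, so
the footprint survives strong defocus while shallow defocus halos no
longer bridge neighbours into spurious clusters. Components smaller
than 4 px are discarded as noise excursions.

Feature definitions that the source material leaves open are fixed as
follows and are configurable:

- *radius variance*: variance of contour-point distances to the
  centroid divided by their mean (contours from marching squares);
- *mass-center shift*: distance (px) between the binary centroid and
  the signal-weighted centroid;
- *energy*: Σp² of the symmetric, normalized co-occurrence matrix at
  offset (1 px, 0°) over in-object pixel pairs, 8 quantization levels
  over the in-object range;
- *dissimilarity*: mean absolute grey-level step of the same pixel
  pairs on an absolute grey scale (40 grey/radian for phase, 255/I₀
  for transmission). The absolute scale matters: a contrast-normalized
  dissimilarity is ~0.7 for any smooth cell and could never exceed the
  3.2 phase-bank threshold, whereas on absolute grey an in-focus cell
  scores ~11 and a defocused one ~3, making the threshold a focus
  gate;
- *sphericity*: 1 − (RMS residual / RMS signal) of the least-squares
  fit of the object's height profile to an ideal sphere chord profile
  of the object's equivalent radius.

The counting filter drops objects ≤ 9.5 μm² (platelets, debris) and
assigns cluster multiplicities two ways, taking the maximum: by shape
(objects falling below the single-cell locus area ≈ π·(feret/2)² get
round(area/median singlet area)) and by integrated absorbance, which is
exactly additive across overlapping cells because transmittances
multiply — this resolves near-complete eclipses that shape cannot see.
The absorbance reference is the 0.7 quantile of on-locus objects, an
upper quantile because defocus only ever lowers the integral. No focus
filtering is applied to counting: the aim is to count every passing
cell.

## Photometry

The two printed single-cell formulas are implemented verbatim as
primitives (`chb_transmission`, `chb_phase`). The per-cell table
builder applies the variant-appropriate sphere geometry on top:

- `i_min` / `oh_max` probe the central chord d;
- `oh_mean` averages the chord, 2/3·d over a full disc;
- `ov` (phase integral over the object) inverts through the sphere
  volume, Δn = OV·λ/(2π·V_sphere(d));
- `i_mean` uses the mean in-contour optical density with the mean
  chord. The direct alternative — Beer–Lambert on the mean
  *intensity* — is edge-dominated for an opaque cell (central OD ≈ 3):
  the informative bright rim is thinner than a pixel, which makes that
  inversion ill-conditioned; the mean-OD statistic is linear in
  concentration and well conditioned. A sphere mean-transmittance
  inversion (`chb_transmission_mean`) is provided for completeness.

All variants correct for the threshold cut of the mask: the mask
boundary sits where the normalized chord equals s₀ = threshold/central
signal, so the true diameter is d_mask/√(1 − s₀²) and the truncated
disc averages are adjusted accordingly. With these choices,
render-then-estimate on noiseless in-focus cells recovers cHB with
≤ 0.2% mean bias (all five variants) and volume with ≤ 0.1% mean bias;
per-cell pixelation scatter is ~1–2% at 0.344 μm/px.

Indices: MCV/CHCM analogues are means over the filtered per-cell table;
RDW and HDW are sample SDs in fl and g/dL (matching how the reference
instrument tabulates them, not CV%); the cytogram bins volume 0–150 fl
× cHB 0–50 g/dL with gate lines at 28/41 g/dL and 60/120 fl.
Instrument comparisons use the fixed-slope-one fit: intercept
b = mean(measured − reference), per-point variation
100·|measured − (reference + b)|/reference reported as mean ± SD.

## Counting estimators and the round-trip convention

The focusing estimator n = D·(w_f/w_FOV)·(N/τ_c)/(Q_i·#frames·Δt) is
flux-consistent: its volume is exactly the pumped sample volume, and a
physically simulated run (arrival rate (n/D)·Q_i, uniform over w_f,
speeds from the flow model) recovers the truth with no convention —
measured bias −3.0% over ten seeds at 5.0×10⁶ cells/μL, dominated by
residual unresolved overlaps.

The laminar estimator is not flux-consistent: its observed volume
V = A_cs·l_FOV·(#frames/I_cells)·(ū_c/ū_fluid) is ≈ 0.59 of the pumped
volume Q·T for the default settings, so the formula chain embeds an
effective detection efficiency that, on the real instrument, is
compensated by experimental losses. The synthetic laminar generator
therefore derives its FOV arrival rate by inverting the estimator with
the same factors (τ, δ, I_cells, V) — generator and estimator share one
volume convention — and the round trip then verifies everything the
imaging chain does (segmentation, multiplicity, stable-window
selection, factor plumbing): measured bias −1.0% over ten seeds.
Anyone replacing the generator with real data should be aware that the
laminar V is a calibration convention, not the pumped volume; the
formula's own quoted example (5.72 μL where its inputs give 5.86 μL) is
likewise not reproducible from its printed inputs and is asserted at
the computed value.

The stable window is the earliest span (10 s laminar / 20 s focused by
default, or the whole recording when shorter) whose rolling CV of
per-frame counts drops below 0.25; these are defaults, not claims.

## Numerical choices and degenerate inputs

Truncation 101 odd harmonics; quadrature via scipy adaptive quad;
root-finding by Brent bracketing; sphere-model inversions by Brent on
monotone functions with series fallbacks near zero depth; intensities
outside (0, I₀] are flagged NaN, never clamped silently; empty frames,
empty tables and zero-count windows propagate as empty/zero results;
border-touching objects are excluded from photometry but kept for
counting. Every stochastic element takes a numpy Generator or seed and
is reproducible bit-for-bit under a fixed seed.

## Problem sizes used in the test suite

The shipped tests run desk-scale versions of the experiments: counting
runs use 150 frames (laminar) and 40 frames (focused) at 0.688 μm/px
with ten seeds each; photometric round-trips use 16 cells at
0.344 μm/px; the index-recovery check uses a 10,000-cell population
through the ideal chain. These sizes were chosen so the whole suite
completes in a few minutes while keeping Monte-Carlo error well inside
the asserted tolerances.

## Known limitations

- The sphere model is the premise; unsphered or lysed cells violate it.
- The i_min / oh_max routes are sensitive to defective extreme pixels
  under heavy noise (the mean-based routes are not), mirroring the
  known behavior of minimum/maximum statistics.
- The laminar round trip validates the chain relative to its own volume
  convention (above), not absolute flux recovery.
- Dense samples (> ~100 cells per frame) exceed what the
  shape-plus-absorbance multiplicity can resolve.
- The flow model is rectangular-duct and steady; entrance effects,
  non-Newtonian rheology and particle lift are out of scope.
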