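# Methods

This note documents the models, estimators and design choices behind
`astrotopo`, in the spirit of the methods documentation of simulation and
statistics packages.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate conventions

All point coordinates are micrometres.  +x is mediolateral (the tonotopic
axis of the LSO), +y dorsoventral (isofrequency bands).  Raster images map
pixel `(row, col)` to `(x, y) = origin + (col, row) · pixel_size`, with the
origin stored alongside the TIFF in a JSON sidecar.  Orientations are
degrees counter-clockwise from +x, reduced to [0°, 180°) because a network
axis is undirected.

## The anisotropy statistic

For a network with patched cell **p** and coupled cells **c**ᵢ, the vectors
**v**ᵢ = **c**ᵢ − **p** are assigned by polar angle (after rotating the
frame by θ) to four 90° sectors: 1A = [45°, 135°), 1B = [225°, 315°),
2A = [315°, 45°), 2B = [135°, 225°), half-open so every angle lands in
exactly one sector.  The ratio R(θ) is the count-normalised quotient of
sum-vector magnitudes of the y-sectors over the x-sectors.  Conventions:

* the patched cell contributes no vector;
* an empty sector contributes 0 to its side; R is undefined (flagged NaN,
  excluded from the fit) only when the whole denominator vanishes;
* a cell coincident with the patched cell has polar angle 0 and counts in
  sector 2A with a zero-length vector.

R is invariant under translation and uniform scaling and satisfies
R(θ) = R(θ + 180°) exactly, since rotating by a half turn swaps 1A↔1B and
2A↔2B.  The scan covers the full turn (24 angles at the default 15° step)
even though the statistic is 180°-periodic; the redundancy stabilises the
fit.

### Sinusoidal fit

R(θ) = A₀ + A·sin(ωθ + φ + ¾π) is fitted by bounded nonlinear least
squares (A ≥ 0; ω ∈ [0.5, 6] cycles/turn; trust-region reflective, ftol =
xtol = 1e−14) with A₀ = mean(R), A = (max−min)/2, ω = 2 and eight phase
starts equally spaced in [0, 2π); the lowest-cost solution wins.  ω is a
free parameter rather than pinned at 2 because near-spherical networks
oscillate at visibly higher frequency, and the fitted ω is a useful
diagnostic.  The orientation of maximal tracer extent is computed
analytically from the fit: R is maximal at frame rotations
θ* = (π/2 − φ − ¾π + 2πk)/ω, where the rotated y-axis points along
θ* + 90° in network coordinates; the smallest non-negative θ* is used and
α = (θ* + 90°) mod 180°.  For ω = 2 all maxima agree modulo 180°, so the
choice of k is immaterial; for ω ≠ 2 the convention is documented here.
A constant scan fits A ≈ 0; α is then reported as 0 by convention and the
network is classified isotropic regardless.

### Classification

Class 2 (isotropic) iff R_max = A₀ + A ≤ 1.1; otherwise class 1
(orthogonal to the tonotopic axis) iff 45° < α ≤ 135°, else class 3
(parallel).  Boundaries follow the printed intervals: R_max = 1.1 is
isotropic, α = 45° is parallel, α = 135° orthogonal.  α exactly at 45°
therefore goes to class 3 — the interval endpoints are a documented
convention, not a biological claim.  Classification uses R_max and α only;
ω is carried as a diagnostic.

### Network metrics

Cell count includes the patched cell (n = coupled + 1).  Network area is
the convex hull of all cells — the study never defines its area measure,
and the hull is the parameter-free, reproducible choice — converted to
mm²; density = n/area.  Collinear configurations get a flagged undefined
area and no density.

## Synthetic networks

Coupled-cell positions are Gaussian about the patched cell with principal
standard deviations (σ_major, σ_minor) rotated by α_true.  A Gaussian (not
a uniform ellipse) is used because both tracer brightness and cell density
decline with distance from the patched cell; the distribution family is an
assumption of this package, not an observation.  Positions are thinned to
a 10 µm hard core — soma diameters are ≈ 10 µm, so closer centres would
be physically overlapping cells, and they would also be unresolvable by
any peak-separation detector.  Defaults (63 coupled cells + 1 patched,
σ = 75/37.5 µm) were calibrated once by simulation so that count and
convex-hull density match the wild-type scale (64 cells,
≈ 1.5 · 10³ cells/mm²).

Rendering: every cell becomes a Gaussian spot (σ = 3 µm, FWHM ≈ 7 µm)
whose peak above background is `peak_intensity · exp(−r/decay_length)`
with r the distance from the patched cell (decay_length default 200 µm, so
the dimmest cells of a default network stay comfortably above the 1.75×
detection threshold, as in usable recordings); images are float
internally and written as 16-bit grayscale TIFF.  Additive Gaussian noise
is optional and seeded.

What the generator does *not* emulate: out-of-focus light, vignetting and
shading, anisotropic PSFs, tracer spill along processes, cut cells at the
slice surface, and LSO-border effects on coupling.  Passing tests
therefore demonstrate correctness of the estimators under the stated
statistical model, not robustness to every real-world artefact.

## Cell detection

Candidates are local maxima of the Gaussian-smoothed image (σ = 2 µm
default); a greedy pass keeps maxima brightest-first subject to a
Euclidean minimum separation (8 µm default, approximate somatic spacing).
The peak intensity entering the 1.75× background threshold is read from
the **raw** image at the located maximum: reading it from the smoothed
image would make the acceptance threshold depend on the smoothing
bandwidth (a 2× background spot smoothed at 2 µm falls to ≈ 1.7× and
would be silently rejected), whereas the raw-peak rule keeps "1.75 ×
background" meaningful in recorded units.  Smoothing still provides the
noise robustness it was introduced for, since only localisation uses it.
Background is the mean over a user-drawn background ROI, or over the
outer 5% border band when no ROI is supplied.  A user-supplied seed list
can replace maxima finding (the semi-automated workflow); the threshold
filter is applied regardless.  Detections carry their raw peak values, so
the threshold can be re-checked post hoc.

## Voltage-step generator and passive-property estimators

The passive circuit is R_S in series with (R_M ∥ C_M); the membrane
reversal is set equal to the −85 mV holding potential so the baseline
passive current is zero.  A step ΔU jumps the current to ΔU/R_S, relaxing
with τ = R_S·R_M·C_M/(R_S+R_M) to ΔU/(R_S+R_M).  C_M defaults to 1 nF:
the patched astrocyte is electrically continuous with a ~60-cell coupled
syncytium, so the effective capacitance is far above the tens of pF of an
isolated cell.  Non-passive astrocytes add a delayed-rectifier K⁺ current
g_max·a(V,t)·(V−E_K) with Boltzmann steady-state activation (V½ = −20 mV,
k = 10 mV), first-order kinetics (τ_act = 5 ms) and E_K = −100 mV — a
generic delayed-rectifier shape, all parameters configurable.  Gating is
driven by the command potential (ideal-clamp approximation).  The
recording chain's online 2.9 kHz single-pole low-pass is emulated on an
internal ≥ 500 kHz grid *before* decimating to the protocol's sampling
rate, as an analog filter acts before digitisation; discretising the
filter at the output rate would spuriously under-filter slow sampling.

Estimators: I₁ = mean baseline current; I₂ = mean over the final 10% of
the step ("end of step" without a printed window); I_peak = the sample
farthest from I₁ within the first 20% of the step (raw extremum — the
transient is not refitted).  R_In, R_S, R_M follow the quotient formulas
above; R_In = R_S + R_M holds by construction.  QC passes iff
R_S ≤ 15 MΩ.  With the default circuit the filter attenuates the peak by
a few percent, so recovered R_S carries a small positive bias — visible in
the acceptance report and shrinking with sampling rate.

The I/V curve takes steady-state currents per step; linearity is the R²
of a straight-line fit, and the rectification index is the chord
conductance over the two most depolarised steps divided by that over the
two most hyperpolarised.  The nPA/PA boundary ("mainly showing outward
currents") is quantified as rectification index > 1.2, a configurable
threshold; the boundary value itself classifies as PA (strict >).  No
liquid-junction-potential correction is applied anywhere.

## Immunofluorescence quantification

Mean grey value = average over pixels whose centres fall inside the ROI
polygon (pixel-centre test; unambiguous discretisation).  Background
correction subtracts a pooled per-nucleus negative-control mean; negative
corrected values are kept and flagged, not clipped.  Areas use the
shoelace formula (via shapely) and reject self-intersecting polygons.
The punctate-field generator draws Poisson counts at the stated inside/
outside densities with uniform placement, rendered as small Gaussian
spots (σ = 0.6 µm) over a uniform background.

## Statistics

The normality gate runs a one-sample KS test against a normal with the
sample's own mean and SD on *both* groups at level 0.05; fitting the
parameters makes the nominal p-values conservative (Lilliefors caveat),
which is accepted here because the gate merely selects between tests.
Both-pass → two-tailed unpaired t-test (equal variances); otherwise
two-sided Mann–Whitney U.  χ² is Pearson's on the 2×k table without
continuity correction (configurable); zero expected counts raise.  Šidák
correction: α_corr = 1 − (1−α)^(1/m), strictly decreasing in m with the
family-wise bound exact by construction; for m = 2 the corrected 0.05 /
0.01 / 0.001 levels round to 0.025 / 0.005 / 0.0005.

## Problem sizes and tolerances

The test suite and acceptance script run at study-like but desk-friendly
sizes chosen as the package's own defaults: 200 networks of 64 cells for
orientation recovery, 100 replicates of 500-cell isotropic controls
(σ = 108 µm, calibrated once to hold the wild-type density at n = 500),
1000 random point sets for oracle agreement, 2000-cell noiseless patterns
for equivariance checks.  Numerical tolerances: sector-ratio oracle
agreement to 1e−9 (float accumulation order differs between the
vectorised and looped paths); sinusoid self-consistency to 1e−6; fit
convergence tolerances 1e−14.

## Known limitations

* The statistic presumes the image axes are already anatomically aligned;
  no slice-to-atlas registration is provided.
* α from fits with ω far from 2 depends on the documented smallest-θ*
  convention.
* Detection assumes roughly isotropic, soma-sized spots; it does not
  segment cell bodies or handle strongly elongated profiles.
* The ephys generator's ideal-clamp gating approximation slightly
  overestimates the driving force of the outward current at large
  depolarisations; estimators are unaffected since they never invert the
  gating model.
* The nPA/PA threshold (1.2) is a package convention for a qualitative
  published criterion; cohort phenotype fractions shift with it.
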