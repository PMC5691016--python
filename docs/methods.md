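# Methods

`protondosim` is a desk-scale model of the dosimetric evaluation of a
small-volume silicon diode in radiosurgical proton fields. It replaces the
two expensive components of such a study — a Monte Carlo nozzle model and
water-tank measurements — with a parametric beam generator and an explicit
detector-response model, and implements the full analysis chain (profile
metrics, microdosimetric moments, detector comparisons, calibration fits) as
tested library code. This note records the models, their assumptions, the
defaults, and what the synthetic data do and do not establish.

## Beam model

**Pristine peak.** The depth-dose primitive is the Bragg–Kleeman power-law
stopping power of a monoenergetic proton, dD/dz ∝ (R − z)^(1/p − 1) with
p = 1.77, convolved with a Gaussian range-straggling kernel of width σ. The
integrable singularity at z = R is handled exactly by cell-averaging the
antiderivative on the internal 0.01 mm grid before convolution. Rather than
converting a nominal energy to a range (which cannot reproduce a real
nozzle's upstream energy loss), the model is parameterized directly by the
two measured quantities: the distal 50% depth D50 and the distal 80→20%
falloff width. An internal fixed-point loop adjusts (R, σ) until both are
reproduced to < 0.01 mm; the loop converges in a handful of iterations
because D50 responds essentially one-to-one to R and the falloff width
linearly to σ.

Defaults: D50 = 99.5 mm WED with 4.0 mm falloff for the 127 MeV beam and
153.1 mm with 5.5 mm for 157 MeV — straggling of roughly 1.2% of range plus
the source spectrum of a single-stage scattering system. The resulting
peak-to-entrance ratio is ≈ 4.3, typical of scattered clinical beams.

**SOBP synthesis.** A spread-out Bragg peak is a nonnegative-weighted sum of
range-shifted copies of the pristine curve (pullback step 2 mm, the
modulator-wheel stand-in). Weights are solved by NNLS against a flat target.
Three structural choices matter and were each forced by the geometry of the
component curves:

* the flat-target region ends at the *pristine peak position*, not at D50 —
  demanding flatness into the distal falloff forces an overshoot bump;
* only components whose shifted peak lies inside the plateau are admitted
  (plus one fractional pullback landing exactly at the plateau start) — a
  component peaking proximal of the plateau raises a shoulder hump above the
  plateau level; and
* because every pulled-back component carries the full-energy straggling
  smear, the proximal 90% crossing of the sum falls several mm shallower than
  the designed plateau start, so the start is iterated (damped, ~5
  iterations) until the measured 90–90 extent equals the requested
  modulation.

Modulation width is *defined* as the proximal-90% to distal-90% extent.
Plateau flatness (max deviation from the mean over the designed plateau) is
≤ 2% for every study configuration; a pullback too coarse to reach that
raises a diagnostic error rather than returning a rippled curve. The flatness
is quoted over the designed plateau because the closed 90–90 interval ends,
by definition, at points where the dose is exactly 90% of maximum — no curve
can be "flat to 2%" on that closed interval.

**Lateral profile and 3-D grid.** The lateral model is a uniform disc
aperture with an error-function edge, σ(z) = σ₀ + k·z, defaults σ₀ = 0.7 mm
and k = 0.004, calibrated so the 20 mm aperture's FW90M at 33 mm WED falls
within 0.5 mm of the study's simulated widths (FWHM = 2·aperture radius
exactly, by the erf-edge midpoint property). The 3-D grid is the separable
product of the depth curve and the radial edge factor on a 0.5 mm isotropic
grid, centered so the beam axis meets the corner of the four central voxel
columns; central-axis depth dose is extracted as the mean of those four
columns. Separability is exact by construction and is verified against the
1-D generator to 1%.

**Single-event generator.** Per scoring slice (20×20 voxels of
0.02 × 0.05 × 0.05 mm; mean chord = the 0.02 mm thickness), per-voxel event
counts are Poisson with rate n_primaries·Φ(z)/400, where the relative
fluence Φ(z) combines linear nuclear removal (to 80% of entrance at the
distal peak) with an erfc range-straggling survival term. Event energies are
a two-component mixture: a primary component Gamma(shape 4) with mean
L(z)·l̄, where L(z) = 0.5·((R+δ)/(R+δ−z))^0.65 keV/µm is a depth-increasing
stopping-power stand-in (δ = the falloff width, capping the on-peak value
near 4–5 keV/µm), and an exponential secondary tail with mean 10× the
primary mean, whose mixture weight rises smoothly (logistic, width
falloff/4) from 2% at entrance to 15% beyond the distal 90% depth. The tail
parameters were chosen once to reproduce the qualitative sharp distal rise
of the dose-mean lineal energy; no claim of spectral fidelity is made.
`expected_lineal_mean` exposes the analytic mixture mean so sampling can be
validated against the configured model (the mixture mean at entrance is
1.18× the primary L because of the 2% tail). All sampling flows through one
`numpy` Generator seeded explicitly; there is no global random state.

## Detector models

The diode presents a 1 mm² disc (r = 0.564 mm) axially and a
0.02 × 1.128 mm rectangle edge-on; the chamber a 2.65 mm-radius disc (axial
only). Volume averaging is the field convolved with the uniform normalized
footprint; 1-D scans project the footprint onto the scan direction (chord
weighting for discs), with quadrature step 0.01 mm. Depth scans place the
sensitive volume at stage depth + window WET (1.33 mm diode, 1.06 mm
chamber); positions are reported as effective depths by default, or as raw
stage depths on request — the uncorrected convention is what makes the
0.27 mm window-WET difference visible between detectors scanning the same
field. On-axis depth readings average the radial edge factor over the disc
footprint, which reproduces the chamber's partial-volume under-reading of
sub-centimetre beams. The edge-on sensitive volume is centered at the stated
scan depth (no edge-on window WET is specified by the manufacturer).

The charge model is affine in dose: charge = S·D·(1 − λ·D_acc)·(orientation
factor if edge-on)·(optional LET factor)·(1 + ε) + offset, with S = 2.5
nC/Gy, offset 100 pC, λ = 10⁻⁴/Gy, orientation factor 0.994, and
multiplicative Gaussian noise ε (σ 0.5% default) on the dose-dependent term
only, so a zero-dose reading returns the offset exactly. Dose rate enters no
term — uniformity is by construction, and the dose-rate analysis verifies
the pipeline recovers it. The LET over-response factor
(1 + c·max(0, y − y₀)) is disabled by default, since the study concludes the
diode's LET dependence is negligible until the very distal SOBP; the toggle
exists to generate distal-ratio-rise scenarios.

The detector-size rule reports 0.5·r for axial discs, rounded to 0.1 mm
(0.3 mm for the diode), and the rounded axial estimate × 0.03 for edge-on
(0.009 mm). The 0.5·r slope-1 rule presumes a detector-dominated edge; the
package's tests exercise it at penumbra σ ≈ r/3, where numerical convolution
confirms it within 20%. On softer edges (σ ≳ r) the true broadening is well
below 0.5·r, so the rule is an upper expectation there.

## Profile metrics

Level crossings (D50, 90–90 bounds, FWHM/FW90M, 20–80% penumbra) use linear
interpolation between bracketing samples, taking the outermost crossing when
noise produces several; profiles are smoothed only on explicit request
(3-point median). D50 is the deepest crossing of 50% of the discrete global
maximum distal to it, and is therefore invariant to normalization mode. The
center of modulation is defined as the midpoint of the 90–90 bounds; COM
normalization divides by the dose there. Ratio-at-level readouts
(`interp_at_level`) locate the crossing on the reference curve linearly and
evaluate the target curve by quadratic interpolation through its three
nearest samples (second-order), falling back to linear with a logged warning
below three samples. Extractors were validated against 0.001 mm dense
evaluation on 50 randomized erf-edge profiles; agreement is within one
coarse grid step.

## Comparison and calibration analyses

Ratio curves resample the diode profile onto the reference grid with
quadratic interpolation and clip at the reference's distal 25% crossing.
Misalignment sensitivity assumes a linear dose falloff between the distal
95% and 25% crossings and evaluates the ratio change at the 60% (mid-falloff)
level: Δ = g·s/(0.6 − g·s). For the calibrated 127 MeV pristine curve this
yields ≈ 10% and 24% for 0.4 and 0.9 mm shifts.

The four calibration experiments are simulated at the study's replicate
counts (9 doses 0.6–23 Gy; 14 dose rates 0.7–2.3 cGy/s; 3×2 Gy probe sets
around three 56 Gy accumulations, with probe doses accruing; 4×170 cGy per
orientation) and fitted by OLS. The orientation estimate follows the
experimental normalization exactly: charge/MU of all eight points normalized
to their maximum, then |mean(edge-on) − mean(axial)|×100. Confidence
intervals are t-based for ≤ 10 points and percentile bootstrap (1000
resamples, seeded) otherwise. Decay responses subtract the known offset
before normalizing (a relative measurement); leaving the offset in would
bias the recovered rate by ≈ 2% of itself.

## What the synthetic data do not show

The generator's beams are separable, axisymmetric, noise-free fields with
exactly known alignment; real water-tank data carry setup uncertainty,
detector positioning error, beam-current fluctuation, and non-separable halo
from the collimation system. Passing the recovery tests demonstrates that
the *analysis chain* is unbiased at the study's statistical design, and that
the geometric/arithmetic rules (volume averaging, window offsets, moment
inequalities) are implemented correctly — not that a physical diode behaves
as modelled. The microdosimetric event spectrum is a two-component stand-in;
absolute yF/yD values are indicative, while their depth trend and the
yD ≥ yF inequality are structural.

## Problem sizes and numerics

The internal depth grid is 0.01 mm; dose grids default to 0.5 mm isotropic
(a guard rejects > 10⁸ voxels); microdosimetric sampling defaults to 10⁵
primaries per slice (Monte Carlo SE on yF ≈ 0.3%); recovery studies use 200
seeded repetitions, which put the standard error of the mean an order of
magnitude below each tolerance. Floating-point ties in level crossings
resolve to the outermost crossing; degenerate inputs (all-zero profiles,
empty event sets, rank-deficient fits, non-overlapping supports) raise typed
errors rather than returning sentinel values.
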