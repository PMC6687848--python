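# Methods

This note documents the models, algorithms, defaults and numerical choices
behind `tendonkit`, and what the synthetic-data generators do and do not
emulate.

## Micromorphology: peak spatial frequency (PSF)

B-mode speckle over a healthy tendon is quasi-periodic along the depth axis,
reflecting the packing of collagen fascicle bundles. The PSF pipeline per
32 × 32-pixel kernel:

1. subtract the kernel mean (suppresses DC leakage; no further window by
   default — an optional Hann window sits behind `hann_window`, default off,
   since windowing is not part of the canonical procedure);
2. zero-pad to 128 × 128 and take the 2D DFT (padding refines the frequency
   sampling to `1/(128 · pixel_size)` per axis, 0.15625 mm⁻¹ at 0.05 mm
   pixels);
3. multiply the magnitude spectrum by a radially symmetric Gaussian-profile
   high-pass `H(f) = 1 − exp(−f²/(2σ²))`, with σ solved from the half-power
   condition `|H|²(1.23 mm⁻¹) = 0.5`. Only the cutoff and radial symmetry
   are canonical; the Gaussian profile is this package's choice (smooth,
   monotone, exact zero at DC) and the family is pluggable;
4. search the maximum-magnitude bin over the non-redundant half-plane
   (conjugate symmetry makes the other half duplicate information), DC
   excluded; ties break toward the lower radial frequency, then row-major;
5. the peak's radial distance in *physical* frequency is the kernel PSF;
   anisotropic pixel calibration is honored by converting each axis to mm⁻¹
   before the radial norm.

Filtering happens on the padded grid rather than before padding: both
evaluate the same continuous response, the padded grid just samples it more
finely. A kernel whose filtered spectrum is identically zero (constant
intensity) has no defined peak; it is excluded from the image mean and
counted separately.

Kernels are enumerated on a stride grid (default 16 px, i.e. 50 % overlap —
"as many kernels as possible" at tractable cost; stride 1 is available)
anchored at the ROI interior's top-left pixel; a kernel counts only if its
entire footprint lies inside the polygon. ROI containment is pixel-center,
strict interior (boundary excluded), the same rule used for Doppler.

## Geometry

* **Line of action**: total-least-squares 3D line through the slice-polygon
  centroids (first principal axis of the centroid cloud), sign fixed
  proximal → distal.
* **CSA reorientation**: a planar section area times `cos θ` (tilt between
  slice normal and line direction). This is area projection, valid for thin
  slices of a near-prismatic body; no 3D surface reconstruction is
  attempted because 3-mm-slice planar segmentations carry no more
  information.
* **Regional means**: tendon length is measured along the line of action
  between the projections of the first and last slice centroids; the
  proximal/distal regions are the first/last 40 % of that length.
* **Circle fit**: Kåsa algebraic fit (linear least squares on
  `2cx·x + 2cy·y + c = x² + y²`) followed by Gauss–Newton refinement of the
  geometric distance. A `condition_flag` marks poorly constrained fits:
  data arc span < 30° or normal-equation condition number > 1e8.
* **Moment arm**: common-perpendicular distance
  `|(p₂−p₁)·(d₁×d₂)|/|d₁×d₂|` between tendon line and condyle axis;
  point-to-line distance for parallel lines; intersecting lines yield 0 with
  a warning. The measurement knee angle (default 10° flexion) travels with
  the result so the mechanics side can rescale it by an angle profile.

## Mechanics

Reduction defaults: gravity moment fitted as a degree-2 polynomial of knee
angle on the passive trial (the functional form is not canonical; order is
configurable); antagonist flexion moment predicted from the EMG envelope by
pooled OLS over the flexion calibration trials, added to the extension
moment with negative predictions clamped to zero (a flexor cannot assist
extension); EMG preprocessing (rectification/smoothing) is upstream — the
module consumes an envelope. The moment-arm angle profile is a user-supplied
monotone-interpolated table with identity default; no third-party profile
data are bundled.

Force–elongation curves are averaged at 100 common force levels (linear
interpolation per trial restricted to its rising-force envelope) from 0 to
80 % `TF_max`; trials never reaching 80 % are excluded with a warning. The
80 % elongation is read from the averaged curve (rather than averaging
per-trial 80 % readings — either convention is defensible; this one matches
how the curve itself is defined). `TF_max` is the maximum force over the
participant's ramp trials, i.e. the best maximum-effort trial wins.

Derived outcomes: `ε₈₀ = 100·e(0.8 TF_max)/L₀`; normalized stiffness
`k·L₀/1000` (kN per unit strain); regional stress `TF_max/CSA` (MPa with N
and mm²); modulus from the 50–80 % stress–strain band using the full-tendon
mean CSA — since stress and strain are affine transforms of force and
elongation, `E = k·L₀/CSA_full` exactly, an identity the tests assert;
extrapolated maximum strain `ε₈₀ + 100·(0.2·TF_max/k)/L₀` (linear
continuation of the curve beyond the common-force range).

## Doppler

A pixel is chromatic when its RGB channel spread `max(|R−G|,|G−B|,|R−B|)`
reaches a threshold, default 30 of 255 — Doppler overlays color on a
grayscale background, so gray pixels have zero spread. The threshold is
config and reported in the result. The outcome is the maximum colored area
over the frame sequence (first frame on ties).

## Statistics

Pearson is used only when *both* variables pass Shapiro–Wilk at α = 0.05
(the gating rule could also be one-variable; both-variables is stricter and
is this package's documented choice), otherwise Spearman (Pearson on
midranks). Two-sided p-values use `t = r√((n−2)/(1−r²))` with n−2 df (n−3
for the single-control partial correlation, computed on OLS residuals).
Shapiro–Wilk and the t distribution come from scipy. No multiple-testing
correction is applied; the cohort report carries the number of tests run.

Maturity offset uses the linear-in-product form
`b0 + b1·(age × sitting height)`; the published recalibrated boys'
coefficients (Moore et al. 2015: −7.999994, 0.0036124) ship as an explicit,
citation-tagged constant that callers must pass — there is no silent
default. Symptom grouping is decided by the follow-up VISA-P score alone
(asymptomatic iff follow-up ≥ 85): this single rule reproduces all grouping
cases — pain-free, recovered-to-threshold, persisting, and developing
within the follow-up window — and avoids the ambiguity of combining
baseline and follow-up rules; the threshold is configurable.

## Synthetic data: what it emulates, what it does not

All generators are deterministic given `(spec, seed)` and record their
ground truth. They emulate the *information content* of the real inputs,
not their physics: no ultrasound wave propagation, no MRI k-space, no
musculoskeletal dynamics.

* **Speckle images**: a cosine band pattern (period = fascicle spacing,
  default conditions 0.5 mm spacing at 0.05 mm pixels) under multiplicative
  Rayleigh speckle scaled by `speckle_contrast` (0 disables, 1 is fully
  developed). The `disorganization` knob d ∈ [0, 1] acts three ways:
  column-wise phase jitter (wavy, broken bands), *focal* mixing toward an
  isotropic smoothed-noise texture via a spatially heterogeneous weight
  field with mean d (degeneration in tissue is focal, and focality is what
  makes the kernel-mean PSF respond smoothly instead of switching), and a
  packing-density relaxation of the effective band frequency by the factor
  (1 − 0.3 d) — disorganized tendon is less compacted, so its dominant
  spatial frequency falls. At d = 0 the spectral peak sits exactly at
  1/spacing; at d = 1 the image is pure isotropic speckle. A pure global
  mixing model was evaluated and rejected: each kernel keeps the band peak
  until the isotropic texture wins outright, so the mean PSF plateaus at
  low d.
* **Doppler sequences**: exact pixel budgeting — `round(area/pixel_area)`
  chromatic pixels grown as a connected blob inside the ROI; conservation
  holds to one pixel quantum.
* **Segmentation stacks**: plane sections of a tilted circular cylinder;
  in-plane ellipse area = true area / cos(tilt) up to polygonization error
  (a 64-gon underestimates an ellipse by `1 − (n/2π)sin(2π/n)` ≈ 0.16 %,
  within the 0.5 % contract).
* **Ramp trials**: elongation follows a closed-form law — power-law toe
  below 50 % `TF_max` joined with continuous value and slope to an exactly
  linear 50–100 % segment (`e₅₀ = p·0.5·TF_max/k`); a helper solves the toe
  exponent for a target 80 % strain. The raw dynamometer moment is
  `true extensor moment + gravity(angle) − antagonist(EMG)`; elongation
  noise is i.i.d. Gaussian added after the law, keeping truth closed-form.
  Default parameters are the cohort-scale reference values (TF_max 4399 N,
  k 1338 N/mm, L₀ 52.9 mm, moment arm 54.1 mm).
* **Cohorts**: the strain and proximal-PSF columns realize a prescribed
  *sample* Pearson correlation exactly (Gram–Schmidt orthogonalization and
  rotation), giving the statistics layer a deterministic acceptance
  surface; sample means/SDs are exact by standardized construction.

Because these are fixtures, passing tests demonstrate correctness of the
*algorithms* under known ground truth — not robustness to probe pressure,
anisotropy artifacts, segmentation ambiguity, out-of-plane motion or other
properties of real recordings.

## Study sizes and numerical choices

The end-to-end association study uses 16-participant cohorts (strain drawn
around 6.6 ± 1.2 %, truncated to [5.0, 9.8] % — the range the toe-law
supports with exponent ≥ 1 — and mapped linearly onto disorganization
[0.1, 0.9]); the power/false-positive rates in the test suite use 100
cohorts per condition and the acceptance script 60, with 96 × 160-pixel
images (45 kernels per image) — sizes chosen to keep a desk-scale run in
minutes while leaving the Monte-Carlo margins wide. Elongation measurement
noise in the simulated participants is 0.05 mm.

Tolerances: orthonormality of slice bases 1e-9; circle-fit conditioning
threshold 1e8; collinearity tests on singular-value ratios at 1e-12;
stiffness/modulus band membership uses a 1e-9-relative cushion so grid
endpoints at exactly 50/80 % are included.

## Known limitations

* The PSF peak search assumes one dominant quasi-periodic component; images
  with two competing periodicities resolve by the documented tie-break but
  the kernel mean then mixes populations.
* Area-projection CSA reorientation degrades for strongly curved tendons
  (the cylinder model is straight); slice-wise tilt beyond ~30° should be
  treated with suspicion.
* The gravity polynomial (order 2) is adequate for the ±15° passive sweeps
  generated here; wider sweeps may need a higher order.
* Welch grouping and the maturity equation assume the adolescent-boys
  context in which the coefficients were published.
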