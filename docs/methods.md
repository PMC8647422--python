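# Methods

## The measurement problem

Mitral regurgitation sends a retrograde systolic jet from the left
ventricle into the left atrium. The quantity of clinical interest is the
regurgitant volume per cardiac cycle (mL), graded none / mild / moderate
/ severe at 10, 30 and 60 mL. The conventional CMR estimate is indirect —
LV stroke volume (from cine contouring) minus forward aortic volume
(from 2D phase-contrast) — and therefore inherits the combined error of
three large measurements. 4D flow CMR measures the three-directional
velocity field itself, so the jet can be quantified directly by
integrating through-plane velocity over a cross-section of the jet at
every timeframe. This package implements that direct pipeline, the
indirect comparator, and the statistics used to compare methods and
observers.

## Direct jet tracking

Input: a preprocessed velocity field (cm/s) on a voxel grid with frame
times and VENC, plus an atrial region of interest.

1. **Frame detection.** Per frame, voxels inside the ROI with speed
   ≥ `speed_threshold` (default 15 cm/s) are grouped into 26-connected
   components; components smaller than `min_component_voxels` (default
   20) are discarded. Components in consecutive frames are linked into
   jets by centroid proximity (< 15 mm, ties broken by voxel overlap).
   The defaults are set relative to the expected noise floor: at 5 cm/s
   per-component velocity noise, the speed of a noise voxel is
   chi-distributed and exceeds 15 cm/s with probability ≈ 3%, and a
   26-connected cluster of 20 such voxels effectively never occurs,
   while even a weak (≈ 18 cm/s) jet cross-section supplies ~100
   connected suprathreshold voxels. A threshold low enough to catch the
   weak first and last frames of a jet matters because those frames
   anchor the time integral.
2. **Peak landmark and plane.** Within each jet component the
   highest-speed voxel is the landmark, skipping voxels flagged by the
   unwrapping step as alias-corrected (the automated analogue of placing
   the plane further into the jet, away from aliasing). The local jet
   direction is the mean velocity over the 3×3×3 neighborhood restricted
   to the component. An MPR plane (default 40 × 40 mm, 1 mm pixels) is
   placed at the landmark with its normal along the jet direction, so
   regurgitant flow is positive by construction. Planes are re-derived
   independently every frame and so adapt to a moving, curving jet.
3. **Through-plane sampling and segmentation.** Each velocity component
   is trilinearly interpolated at the pixel centers; the through-plane
   map is v·n̂. The jet cross-section is the 8-connected component,
   containing the plane origin, of pixels above `segment_rel_threshold`
   (default 0.25) times the in-plane maximum.
4. **Flow rate.** Q = Σ v·n̂ · pixel_area · 0.01 mL/s over the mask,
   negative pixels included as signed values. Two numerical choices
   improve the fidelity of this integral on voxelized data and are the
   package's own: (i) the integration mask is the segmented contour
   dilated by `flux_dilation_px` (default 2) pixels, which captures the
   partial-volume rim of the jet — velocity smeared below the relative
   threshold by voxel averaging carries ≈ 5–7% of the flux, while pixels
   beyond the rim are centered on zero and add no systematic flow; and
   (ii) the flow rate is averaged over a small slab of parallel planes
   (`slab_offsets_mm`, default ±3 mm along the jet axis), which is valid
   because the volumetric flow is the same through every cross-section
   of the jet and suppresses the ±7% voxel-scale jitter any single
   oblique reformat of ~2.5 mm voxels exhibits.
5. **Volume.** The per-frame (t, Q) samples are interpolated by a
   natural cubic spline, augmented with zero-flow anchors half a frame
   interval before the first and after the last jet frame (a boundary
   sample that is already zero is its own anchor), integrated between
   the anchors, and clamped at ≥ 0. A single-frame jet integrates a
   triangular pulse (Q · Δt/2). Per-jet volumes are summed; no detected
   jet yields exactly zero.

## Preprocessing

* **Aliasing.** Measured velocity components fold into [−VENC, +VENC].
  Unwrapping chooses k ∈ {−1, 0, +1} per voxel/frame/component so that
  v + 2k·VENC best matches the median of the 6-neighborhood of the
  current estimate, iterated to convergence; corrections are therefore
  always exact multiples of 2·VENC, and corrected voxels are flagged.
  Only single wraps are handled (|v| < 3·VENC), the dominant case at
  clinical VENC settings; a core aliased so widely that it has no
  unwrapped rim cannot be recovered by spatial consistency and is a
  declared limitation. Note that aliasing is per component: an oblique
  jet at 180 cm/s with VENC 150 need not alias at all unless one
  direction cosine is large.
* **Eddy-current offsets.** A first-order (planar, order configurable)
  spatial polynomial is fitted per frame and component over
  static-tissue voxels and subtracted. For 2D flow curves the mean rate
  over a declared diastasis window is subtracted instead.
* Maxwell-term correction is intentionally absent: it requires sequence
  gradient information outside the data contract.

## Indirect volumetric method

EDV and ESV are the extrema of the LV volume curve (frame labels are not
required), SV = EDV − ESV, EF = 100·SV/EDV. Forward aortic volume is the
trapezoidal integral of the positive part of the aortic flow-rate curve
— a documented convention; a net integral would differ in the presence
of diastolic backflow. MR volume = SV − forward volume, returned
unclipped (negative estimates signal measurement error and are preserved
for Bland–Altman behavior, with a warning). BSA = √(height·weight/3600).
`error_propagation_demo` quantifies why this subtraction is fragile:
with independent 5% errors on EDV, ESV and forward volume, the relative
spread of the MR estimate is several times any input's.

## Severity grading

Half-open intervals closed on the left: [0,10) none, [10,30) mild,
[30,60) moderate, [60,∞) severe — the printed grade boundaries overlap
at 10/30/60 and this resolution is consistent with the "< 10 mL" and
"≥ 60 mL" endpoints. Negative inputs are treated as zero.

## Agreement statistics

* **ICC(2,1)** from two-way ANOVA mean squares,
  (MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n); p-value from the F
  test MSR/MSE with (n−1, (n−1)(k−1)) df (the conventional choice; the
  clinical sources do not name their test).
* **Bland–Altman**: differences are always first argument minus second
  (surfaced as `direction` in results, since the same comparison is
  often reported with either sign); bias ± 1.96 · sample SD.
* **Cohen's kappa**, unweighted, over the fixed ordered grade set with
  empty rows/columns retained; p-value from the large-sample null SE
  √(p_e + p_e² − Σᵢ pᵢ₊p₊ᵢ(pᵢ₊+p₊ᵢ)) / ((1−p_e)√n).
* **Wilcoxon signed-rank**, two-sided, zeros dropped; for ≤ 25 nonzero
  differences the exact distribution of the positive-rank sum is
  computed by dynamic programming over doubled midranks (identical to
  enumerating all 2^m sign patterns), otherwise a normal approximation
  with tie and continuity correction.
* **Median [IQR]** uses linear-interpolation quantiles (affects even n).
* Interpretation bands — ICC: moderate [0.50, 0.71), good [0.71, 0.86),
  strong [0.86, 0.96), excellent [0.96, 1]; kappa: poor ≤ 0, slight
  (0, 0.21), fair [0.21, 0.41), moderate [0.41, 0.61), substantial
  [0.61, 0.81), excellent [0.81, 1] — applied as contiguous half-open
  intervals.

## The digital phantom

The phantom generates what the pipeline needs to be tested against a
known truth, at clinically plausible acquisition settings: 40³ voxels at
2.5 mm isotropic, 20 frames at 38 ms (mid-frame times (i+½)·38 ms), VENC
150 cm/s, additive Gaussian velocity noise of 5 cm/s per component.

The jet is a straight cylinder from the orifice along an oblique unit
axis (default (1,1,2)/√6, i.e. eccentric with respect to the grid),
carrying at every active frame a cross-sectional flux equal to the
half-sine orifice program Q(t) = Q_max sin(π(t−onset)/T) with
onset/offset 210/550 ms (active frames 6–13, a mid-to-late-systolic
window) and Q_max scaled so the closed-form integral 2·Q_max·T/π equals
the target volume (default 16 mL). The cross-sectional profile is a
top-hat of radius 4.4 mm (default) or a truncated Gaussian (σ = half the
core radius), both normalized to carry Q(t) exactly; the true radial
profile of clinical jets is not modeled — parameter recovery, not CFD,
is the goal. The generated core extends 6 mm beyond both ends of the
tracked segment so that a peak-velocity plane near a segment end still
samples fully developed flow rather than an artificial hard edge of the
simulation; the atrial ROI is the finite sleeve (core + 10 mm) of the
tracked segment, and the static-tissue mask keeps 20 mm clearance. A
second jet with its own axis, flow program and truth can be added. The
default per-volume batch generator widens the core (up to 9 mm) rather
than exceeding ~120 cm/s peak speed as volumes grow, and dilates the
digital ventricle (EDV = 134 mL + regurgitant volume, ESV fixed) so
severe-MR phantoms remain physiologic.

The matched indirect inputs are constructed to be exactly consistent:
the LV volume curve's sampled extrema are pinned to EDV and
ESV = EDV − (forward + regurgitant) volume, and the aortic half-sine is
rescaled so its positive-part trapezoidal integral equals the configured
forward volume exactly — the closed loop isolates the indirect method's
arithmetic from curve-sampling error.

What the phantom does **not** emulate — and hence what passing tests do
not show about clinical data: turbulence and intravoxel dephasing signal
loss near the valve, flow displacement artifacts, jet entrainment and
momentum decay, respiratory/ECG gating inconsistency, wall motion, and
realistic atrial anatomy. Recovery accuracy on the phantom bounds only
the numerical pipeline, not reader or physiology effects.

## Numerical choices and degenerate inputs

Trilinear interpolation for all resampling; natural spline boundary
conditions; jet-direction ties at a top-hat profile's equal-speed
plateau resolve to the first voxel in index order (with noise the argmax
is unique almost surely); a plane pixel out of the volume is excluded
from masks; a plane entirely outside the volume, an all-flagged
component, an empty ROI, zero total variance (ICC), a single-cell kappa
table and an empty sample (median) all raise explicit errors; an
all-zero difference vector returns Wilcoxon p = 1 by convention.

## Problem sizes

The default test and acceptance runs use 40³ × 20-frame phantoms and
cohorts of 12–20 phantoms; these sizes give sub-voxel-converged recovery
(≤ ~3% error against truth) while keeping the full suite and the
acceptance script each under a minute on one CPU. Larger grids change
nothing structurally.

## Known limitations

Single-wrap unwrapping only; no Maxwell correction; detection assumes
the jet is the dominant coherent high-speed structure in the ROI (mitral
inflow in diastole is outside the tracked window by construction of the
systolic flow program, but a clinical ROI must exclude pulmonary vein
inflow); the automated surrogates for visual frame inspection, plane
placement and contouring are parameter choices, not claims of
equivalence to any proprietary analysis software or human reader.
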