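# Methods

This note documents the models, defaults and numerical choices behind
`mechanomap`, and what the synthetic validation studies do and do not show.

## The measurement model

A deformable hydrogel microsensor (~70 µm alginate particle with embedded
magnetic nanoparticles) darkens a T2\*-weighted MR volume locally; under
compressive stress the particle deforms, expels water, and its relaxivity —
hence its dark-spot contrast — decreases. The package treats this
transduction **empirically**: no spin physics is simulated, the chain starts
at the image.

Per particle, the statistic is the inverse-intensity signal-to-background
ratio

    SBR = (1/I_roi − 1/I_bg) / (1/I_bg) = I_bg / I_roi − 1,

with `I_roi` the mean of a 3×3 in-plane window on the two axial slices
bracketing the spot center (18 voxels), and `I_bg` the mean of four 3×3
windows on the same slices, offset diagonally by 5 px (72 voxels). The
reciprocal makes the statistic proportional to relaxation rate. Measured
SBR is normalized by the cohort-mean SBR of unstressed sensors
(`reference_sbr0`) onto the calibration scale, where the stress–signal law
is the biexponential decay

    signal(S) = a₁ e^(−b₁ S) + a₂ e^(−b₂ S),
    (a₁, b₁, a₂, b₂) = (0.1344, 0.926 kPa⁻¹, 0.864, 0.0405 kPa⁻¹),

valid on S ∈ [0, 15] kPa (signal at zero stress: a₁+a₂ = 0.9984; the sum is
not constrained to one, indicating an unconstrained original fit). Stress
is recovered by solving `signal(S) = s` with Newton–Raphson.

### Error budget

With the default noise level (below), the per-measurement s.d. of the
normalized signal is ≈ 0.024. Error propagation gives a per-record stress
uncertainty `σ_S ≈ σ_signal / |signal′(S)|`: ≈ 0.15 kPa at S = 0, ≈ 0.6 kPa
at 3 kPa, ≈ 1 kPa at 10 kPa — the law flattens at high stress, so
single-record accuracy degrades with load. Sub-0.5 kPa per-record accuracy
is therefore a low-stress (≲ 1–2 kPa) property; cohort means converge as
1/√n at any stress. The inverse map is convex in the signal, so noise also
produces a small positive bias (~0.2–0.3 kPa at mid-range) in single-record
estimates.

## Aggregation filter

Clumped sensors violate the single-particle calibration. A detection is
excluded when `SBR > 2.5` **or** its contiguous dark area exceeds 9 px
(3×3) on the central slice. The two symptoms are combined with OR because
either alone indicates aggregation (an AND variant is available via
configuration). Contiguity uses 8-connectivity on pixels below
`I_bg − 0.5 (I_bg − I_min)`; the slice is median-filtered (3×3) and the
count taken on a 2× bilinear upsampling so the area does not depend on
voxel noise at the blob rim or on where the spot center falls within a
pixel. Values exactly at a threshold are retained.

## Detection

The volume is matched-filtered with a Gaussian at the nominal spot scale
(FWHM 0.3 mm, the resolved particle size). Local minima whose smoothed
fractional dip below the volume median exceeds `min_contrast` (default
0.02) are candidates; greedy non-maximum suppression runs at 0.75 ×
`min_separation` (default 0.9 mm = three spot widths) — the margin keeps
spots placed right at the separation limit from being lost to voxel-grid
quantization of their peaks. Sub-voxel centroids come from the center of
mass of the intensity deficit. A constant or empty volume yields an empty
detection list, and a pure-noise volume produces no candidates at the
default threshold (the matched filter suppresses voxel noise ~7-fold).

## Synthetic data: what it emulates

Generators produce every input with ground truth; all are pure functions of
(configuration, seed).

- **Spots.** Isotropic Gaussian dips (FWHM 300 µm) on a uniform background
  (default 100 intensity units), voxel grid 0.1 × 0.1 × 0.2 mm (z, y, x
  order, 0-based). Each spot's amplitude is calibrated so that the
  *measured* noiseless SBR equals `sbr0 · signal(S)/signal(0)` — i.e. the
  rendered contrast follows the stress–signal law exactly through the ROI
  statistic (a literal "scale the depth linearly" variant exists as
  `depth_model="linear"`; because SBR is a nonlinear function of depth it
  reproduces the law only approximately).
- **Noise.** Rician by default (Gaussian optional), per-voxel σ = 1.0
  against a zero-stress ROI contrast (`spot_depth`) of 9.5 — fixing the
  single-particle contrast-to-noise ratio at 9.5, the reported signal
  quality of the real sensor. The implied repeat-measurement CV of SBR is
  `√(1/18 + 1/72) / SNR ≈ 2.8 %` in the shallow-spot limit (ROI averaging
  over 18 voxels plus background noise over 72); measured values run
  2.8–3.2 %, near the reported 2.4 % — the residual gap is the
  background-window noise term, which ROI averaging cannot remove.
- **Aggregates.** Rendered as three merged lobes (0.25 mm spacing, below
  the resolved size) producing a single detection with a dark area well
  above 9 px; single spots stay below it.
- **Tumor time series.** Constellations scale about their centroid by
  (1 + growth_rate) per day; stresses follow a shared `LoadingProfile` or
  per-particle curves. Default regimens: *gradual* — steps every 6 h to a
  5 kPa peak at 48 h (max interval rate 2.5 kPa/day); *acute* — 0.5 kPa
  baseline for 48 h then a 1 h ramp to 5 kPa (108 kPa/day). A 5 kPa/day
  threshold cleanly separates the two despite the identical peak.
- **Registration scenes.** Tumor surfaces are ellipsoid point clouds; the
  MR→fluorescence warp is a similarity transform plus a Gaussian-kernel
  displacement mixture (default amplitude 0.4 mm, length scale 4 mm —
  smooth and invertible). "Vimentin-positive" regions are thresholded
  smoothed Gaussian random fields (patch scale 1.5 mm) occupying a
  prescribed volume fraction.
- **Two-region scenario.** Sensor stresses are drawn per region from
  N(3.5, 2.8²) (positive) and N(7.4, 2.8²) kPa (negative), **moment-matched**
  (each group standardized to its nominal mean and s.d.) and then clamped
  to [0, 15] kPa. Moment matching makes the scene realize the stated
  region parameters, so recovery error measures the pipeline, not the
  generator's finite-sample draw; clamping (rather than rejection
  resampling) keeps the realized positive-group mean near its nominal value
  (≈ 3.64 kPa after clamping at zero).
- **Optical arm.** Axial strain follows the saturating two-parameter law
  `ε(S) = ε_max S/(S + k)` with ε_max = 0.6 and k = 8 kPa, a stand-in
  calibrated only qualitatively to the measured single-particle
  compression curve (no functional form is published); readout noise is
  multiplicative Gaussian, 2 % by default.

What the generator does **not** emulate: MR sequence physics (k-space,
bias fields, motion), scanner intensity nonuniformity, particle-size
heterogeneity (the ~10 % particle-to-particle signal spread of real
sensors), irregular tumor shapes, and fluorescence imaging artifacts.
Passing tests therefore demonstrate correctness of the measurement chain
under the stated noise model, not robustness to scanner artifacts.

## Registration (coherent point drift)

Standard CPD: the source cloud parameterizes a Gaussian mixture fitted to
the target by EM with a uniform outlier component (weight w = 0.1).  Rigid
mode solves the closed-form similarity update (SVD with reflection guard);
non-rigid mode first runs the rigid stage, then fits a Gaussian-kernel
displacement field (width β = 2 mm, regularization λ = 3) anchored at the
rigidly aligned source points — both parts are stored in one result and
applied in sequence to arbitrary points (sensor coordinates included).
Clouds are centered to a common origin internally. Convergence: relative
σ² change < 1e−5, max 100 iterations; the penalized negative log-likelihood
is recorded per iteration and is non-increasing (asserted in tests).
Collinear source clouds are rejected as degenerate. On the default warp
scenario the sensor-transfer RMSD is ≈ 0.06 mm, well under the 0.3 mm
sampling radius used for region assignment (≈ one particle diameter;
majority label within the ball, mean fluorescence as the local intensity).

## Device mechanics

The compression device is modeled as homogeneous frictionless uniaxial
compression of a 10 mm × 10 mm cylinder of compressible Neo-Hookean
material, `W = G/2 (I₁ − 3) − G ln J + Λ/2 (ln J)²`,
`Λ = 2Gν/(1 − 2ν)`; the lateral stretch solves the traction-free condition
`G(λ_t² − 1) + Λ ln J = 0` by Brent's method and the axial Cauchy stress
follows in closed form. The small-strain limit reproduces E = 2G(1 + ν)
(checked to 2 %), and stress matches the numerical derivative of the
energy along the path to 1e−4 relative. Agarose constants: G = 0.4 / 1.5 /
4.7 kPa at 0.5 / 1.0 / 2.0 % w/v, ν = 0.31, log-linear interpolation in
between, extrapolation flagged. A full 2.2 mm compression of 2 % agarose
yields ≈ 2.6 kPa by this surrogate — the experimentally quoted ~5 kPa peak
for comparable protocols likely reflects stress concentration or a
different output measure in the original finite-element treatment, so the
figure is reported but not asserted.

## Tracking

Particle counts are small (tens), so linking is greedy mutual-nearest-
neighbor between consecutive sessions, gated at `max_displacement`
(default 1 mm), optionally after a similarity alignment (centroid +
RMS-radius scale) that absorbs bulk growth. Unmatched detections start or
terminate trajectories; nothing is force-linked. Δ-stress over a window is
`S(t_end) − S(t_start)` (later minus earlier); the "pre-induction" window
is the interval spanned by the two sessions immediately preceding a
declared induction day. Loading classification is `acute` iff any
inter-session rate exceeds the (always explicit) threshold.

## Problem sizes and seeds

Validation studies use: 31 noiseless grid points for calibration
self-recovery; 30-particle phantoms for SNR, CV (10 noise re-renderings of
one geometry) and detection metrics; 150 particles for the dual-readout
regression (pins the OLS slope s.e. near 0.01); 60 sensors per region for
the two-region scenario (~120 detections, ~400-point surface clouds for
CPD). All randomness flows from a single seed through
`numpy.random.SeedSequence`; identical configuration and seed reproduce
byte-identical outputs.

## Known limitations

- The strain–stress law of the particle is a qualitative surrogate; only
  its monotonicity, range and round-trip identity are load-bearing.
- Single-record stress accuracy above ~10 kPa is ≳1 kPa at the default
  SNR; applications there should average sensors or sessions.
- The aggregation filter's area criterion is resolution-dependent; the
  9 px default assumes the 0.1 mm in-plane grid.
- CPD here is desk-scale (≤ ~2000 points); no GPU path.
- The uniaxial surrogate ignores plate friction and barreling; it is a
  schedule-design tool, not a replacement for full FEM.
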